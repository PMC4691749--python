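"""Junction identification from loxPsym-containing reads.

A read that spans a loxPsym site is trisected into the site and its two
flanks; each flank is then located on the parental segment sequences by exact
matching (left flank -> a segment's R end, right flank -> a segment's L end,
in either strand sense).  Aggregated flank pairs become junction observations
classified as parental (a designed junction), novel (recombination between
two designed sites) or off-target candidates (one flank unmappable).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import HalfSite, Junction, ReferenceChromosome, junction_pair
from .simulate import default_loxpsym, reverse_complement

__all__ = [
    "JunctionObservation",
    "trisect_loxpsym_read",
    "map_flank",
    "call_junctions",
    "annotate_half_sites",
]

UNMAPPED = "unmapped"


@dataclass(frozen=True)
class JunctionObservation:
    """An observed half-site pair (or half-site + unmapped) with read support."""

    pair: tuple
    support: int
    klass: str  # parental | novel | off_target_candidate
    artifact: bool = False
    annotations: tuple[str, str] | None = None


def trisect_loxpsym_read(
    read: str, loxpsym_seq: str | None = None, min_flank: int = 15
):
    """Split a read into (left_flank, right_flank) around a unique loxPsym site.

    Returns ``(left, right)`` when the site occurs exactly once with at least
    ``min_flank`` bases on both sides; otherwise ``(None, reason)`` with
    reason in {"absent", "insufficient_flank", "multiple_occurrences"}.
    """
    if not read:
        raise ValueError("empty read")
    lox = loxpsym_seq if loxpsym_seq is not None else default_loxpsym()
    first = read.find(lox)
    if first < 0:
        return None, "absent"
    if read.find(lox, first + 1) >= 0:
        return None, "multiple_occurrences"
    left, right = read[:first], read[first + len(lox) :]
    if len(left) < min_flank or len(right) < min_flank:
        return None, "insufficient_flank"
    return left, right


def map_flank(
    flank: str, segment_sequences: dict[int, str], side: str
) -> HalfSite | str:
    """Exact-match a trisected flank to a segment half-site.

    A *left* flank (side="left") maps to iR when it is a suffix of segment i,
    or to iL when its reverse complement is a prefix (the read came from the
    other strand).  A *right* flank maps to iL when it is a prefix, or to iR
    when its reverse complement is a suffix.  No match, or matches to more
    than one half-site, returns "unmapped".
    """
    hits: set[HalfSite] = set()
    rc = reverse_complement(flank)
    for seg, seq in segment_sequences.items():
        if side == "left":
            if seq.endswith(flank):
                hits.add(HalfSite(seg, "R"))
            if seq.startswith(rc):
                hits.add(HalfSite(seg, "L"))
        elif side == "right":
            if seq.startswith(flank):
                hits.add(HalfSite(seg, "L"))
            if seq.endswith(rc):
                hits.add(HalfSite(seg, "R"))
        else:
            raise ValueError("side must be 'left' or 'right'")
    if len(hits) == 1:
        return hits.pop()
    return UNMAPPED


def call_junctions(
    reads: Iterable[str],
    reference: ReferenceChromosome,
    segment_sequences: dict[int, str],
    loxpsym_seq: str | None = None,
    min_flank: int = 15,
    min_support: int = 3,
    artifact_max: int = 2,
) -> list[JunctionObservation]:
    """Aggregate trisected reads into classified junction observations.

    Novel pairs need at least ``min_support`` reads; pairs with one unmapped
    flank are reported as off-target candidates regardless of support and
    flagged as likely ligation artifacts when support <= ``artifact_max``.
    """
    lox = loxpsym_seq if loxpsym_seq is not None else default_loxpsym()
    counts: Counter = Counter()
    for read in reads:
        left, right = trisect_loxpsym_read(read, lox, min_flank)
        if left is None:
            continue
        a = map_flank(left, segment_sequences, "left")
        b = map_flank(right, segment_sequences, "right")
        if a == UNMAPPED and b == UNMAPPED:
            continue
        if UNMAPPED in (a, b):
            hs = a if b == UNMAPPED else b
            counts[(hs, UNMAPPED)] += 1
        else:
            counts[junction_pair(a, b)] += 1
    parental = reference.parental_pairs
    annot = reference.half_site_annotation()
    obs: list[JunctionObservation] = []
    for pair, support in sorted(counts.items(), key=lambda kv: str(kv[0])):
        if UNMAPPED in pair:
            obs.append(
                JunctionObservation(
                    pair, support, "off_target_candidate", artifact=support <= artifact_max
                )
            )
            continue
        klass = "parental" if pair in parental else "novel"
        if klass == "novel" and support < min_support:
            continue
        obs.append(
            JunctionObservation(
                pair, support, klass, annotations=annotate_half_sites(pair, reference, annot)
            )
        )
    return obs


def annotate_half_sites(
    pair: Junction,
    reference: ReferenceChromosome,
    _annot: dict[HalfSite, str] | None = None,
) -> tuple[str, str]:
    """Functional annotation (CDS/UTR/NC) of each half-site of a junction.

    The unordered junction type is the multiset of the two labels, returned
    in sorted order (CDS before NC before UTR) for stable reporting.
    """
    annot = _annot if _annot is not None else reference.half_site_annotation()
    try:
        labels = (annot[pair[0]], annot[pair[1]])
    except KeyError as exc:
        raise KeyError(f"half-site {exc.args[0]} has no designed annotation") from exc
    return tuple(sorted(labels))


def write_junction_tsv(observations: Sequence[JunctionObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("half_site_1\thalf_site_2\tsupport\tclass\tartifact\tannotation\n")
        for o in observations:
            a, b = o.pair
            ann = "-".join(o.annotations) if o.annotations else ""
            fh.write(f"{a}\t{b}\t{o.support}\t{o.klass}\t{int(o.artifact)}\t{ann}\n")


def read_junction_tsv(path) -> list[JunctionObservation]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            parse = lambda t: t if t == UNMAPPED else HalfSite.parse(t)
            pair = (parse(row["half_site_1"]), parse(row["half_site_2"]))
            ann = tuple(row["annotation"].split("-")) if row.get("annotation") else None
            out.append(
                JunctionObservation(
                    pair, int(row["support"]), row["class"],
                    artifact=bool(int(row.get("artifact", "0") or 0)),
                    annotations=ann,
                )
            )
    return out
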