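"""Core representation of the parental chromosome and rearranged genomes.

A SCRaMbLE'd chromosome is modelled as a cyclic sequence of signed segment
identifiers relative to a parental reference that is partitioned into ``L``
segments by loxPsym sites.  The sign records orientation: ``-5`` is segment 5
read on the opposite strand.  Junctions between adjacent segments are named by
the two segment half-sites they join, e.g. the parental junction between
segments 1 and 2 is ``{1R, 2L}``.  Because the loxPsym site is palindromic a
junction is an *unordered* pair of half-sites.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "HalfSite",
    "Junction",
    "Segment",
    "ReferenceChromosome",
    "SignedCircularGenome",
    "synixr_like_reference",
]


class HalfSite(NamedTuple):
    """One physical end of a segment: ``(segment_id, side)`` with side L or R."""

    segment_id: int
    side: str

    def __str__(self) -> str:
        return f"{self.segment_id}{self.side}"

    @classmethod
    def parse(cls, text: str) -> "HalfSite":
        text = text.strip()
        if len(text) < 2 or text[-1] not in "LR":
            raise ValueError(f"malformed half-site {text!r}")
        return cls(int(text[:-1]), text[-1])


#: An unordered half-site pair, stored sorted so equal junctions compare equal.
Junction = tuple[HalfSite, HalfSite]


def junction_pair(a: HalfSite, b: HalfSite) -> Junction:
    """Canonical unordered pair of half-sites (loxPsym symmetry)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Segment:
    id: int
    length_bp: int
    essential: bool = False
    centromere: bool = False
    markers: frozenset[str] = frozenset()
    genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"segment {self.id}: length_bp must be positive")


@dataclass(frozen=True)
class ParentalJunction:
    left: HalfSite
    right: HalfSite
    left_annot: str = "CDS"
    right_annot: str = "UTR"

    def pair(self) -> Junction:
        return junction_pair(self.left, self.right)


class ReferenceChromosome:
    """The parental circular chromosome: ordered segments plus designed junctions.

    Parameters
    ----------
    segments : sequence of Segment
        Segments 1..L in parental order.
    junctions : sequence of ParentalJunction, optional
        The L designed loxPsym junctions; defaults to the canonical wiring
        (segment i's R end joined to segment i+1's L end, wrapping L -> 1)
        with CDS-UTR annotations.
    """

    def __init__(
        self,
        segments: Sequence[Segment],
        junctions: Sequence[ParentalJunction] | None = None,
        circular: bool = True,
    ):
        if len(segments) < 2:
            raise ValueError("a reference needs at least two segments")
        ids = [s.id for s in segments]
        if ids != list(range(1, len(segments) + 1)):
            raise ValueError("segments must be numbered consecutively from 1")
        if sum(s.centromere for s in segments) != 1:
            raise ValueError("exactly one segment must carry the centromere")
        self.segments = tuple(segments)
        self.circular = circular
        L = len(segments)
        if junctions is None:
            junctions = [
                ParentalJunction(HalfSite(i, "R"), HalfSite(i % L + 1, "L"))
                for i in range(1, L + 1)
            ]
        if circular and len(junctions) != L:
            raise ValueError("a circular reference has exactly L junctions")
        for j in junctions:
            for hs in (j.left, j.right):
                if not (1 <= hs.segment_id <= L) or hs.side not in "LR":
                    raise ValueError(f"junction references unknown half-site {hs}")
        self.junctions = tuple(junctions)

    # -- derived views -----------------------------------------------------

    @property
    def L(self) -> int:
        return len(self.segments)

    def segment(self, seg_id: int) -> Segment:
        return self.segments[seg_id - 1]

    @property
    def lengths(self) -> dict[int, int]:
        return {s.id: s.length_bp for s in self.segments}

    @property
    def essential_ids(self) -> frozenset[int]:
        return frozenset(s.id for s in self.segments if s.essential)

    @property
    def centromere_id(self) -> int:
        return next(s.id for s in self.segments if s.centromere)

    def marker_segment(self, marker: str) -> int:
        for s in self.segments:
            if marker in s.markers:
                return s.id
        raise KeyError(marker)

    @property
    def parental_pairs(self) -> frozenset[Junction]:
        return frozenset(j.pair() for j in self.junctions)

    def half_site_annotation(self) -> dict[HalfSite, str]:
        """Functional label (CDS / UTR / NC) of the sequence abutting each half-site."""
        annot: dict[HalfSite, str] = {}
        for j in self.junctions:
            annot[j.left] = j.left_annot
            annot[j.right] = j.right_annot
        return annot

    def parental_genome(self) -> "SignedCircularGenome":
        return SignedCircularGenome(range(1, self.L + 1))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, segment_path, junction_path) -> None:
        with open(segment_path, "w") as fh:
            fh.write("segment_id\tlength_bp\tessential\tcentromere\tmarkers\tgenes\n")
            for s in self.segments:
                fh.write(
                    f"{s.id}\t{s.length_bp}\t{int(s.essential)}\t{int(s.centromere)}\t"
                    f"{','.join(sorted(s.markers))}\t{','.join(s.genes)}\n"
                )
        with open(junction_path, "w") as fh:
            fh.write("left_half_site\tright_half_site\tleft_annot\tright_annot\n")
            for j in self.junctions:
                fh.write(f"{j.left}\t{j.right}\t{j.left_annot}\t{j.right_annot}\n")

    @classmethod
    def from_tsv(cls, segment_path, junction_path=None) -> "ReferenceChromosome":
        segments = []
        with open(segment_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                segments.append(
                    Segment(
                        id=int(row["segment_id"]),
                        length_bp=int(row["length_bp"]),
                        essential=bool(int(row.get("essential", "0") or 0)),
                        centromere=bool(int(row.get("centromere", "0") or 0)),
                        markers=frozenset(x for x in row.get("markers", "").split(",") if x),
                        genes=tuple(x for x in row.get("genes", "").split(",") if x),
                    )
                )
        junctions = None
        if junction_path is not None:
            junctions = []
            with open(junction_path) as fh:
                header = fh.readline().rstrip("\n").split("\t")
                for line in fh:
                    row = dict(zip(header, line.rstrip("\n").split("\t")))
                    junctions.append(
                        ParentalJunction(
                            HalfSite.parse(row["left_half_site"]),
                            HalfSite.parse(row["right_half_site"]),
                            row.get("left_annot", "CDS"),
                            row.get("right_annot", "UTR"),
                        )
                    )
        return cls(segments, junctions)

    def to_gff3(self, path, loxpsym_length: int = 34) -> None:
        """Export segments and loxPsym sites as GFF3 (1-based closed coordinates)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            pos = 0
            for s in self.segments:
                fh.write(
                    f"ref\tunscramble\tregion\t{pos + 1}\t{pos + s.length_bp}\t.\t+\t.\t"
                    f"ID=segment_{s.id}\n"
                )
                pos += s.length_bp
                fh.write(
                    f"ref\tunscramble\trecombination_feature\t{pos + 1}\t"
                    f"{pos + loxpsym_length}\t.\t+\t.\tID=loxPsym_{s.id}\n"
                )
                pos += loxpsym_length


class SignedCircularGenome:
    """A rearranged genome: a cyclic, non-empty sequence of signed segment ids."""

    __slots__ = ("sequence",)

    def __init__(self, sequence: Iterable[int]):
        seq = tuple(int(x) for x in sequence)
        if not seq:
            raise ValueError("a genome must contain at least one segment")
        if any(x == 0 for x in seq):
            raise ValueError("segment ids are signed non-zero integers")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:
        return isinstance(other, SignedCircularGenome) and self.sequence == other.sequence

    def __hash__(self) -> int:
        return hash(self.sequence)

    def __repr__(self) -> str:
        return f"SignedCircularGenome({list(self.sequence)})"

    # -- derived views -----------------------------------------------------

    def copy_numbers(self) -> Counter:
        """Per-segment occurrence counts (unsigned ids)."""
        return Counter(abs(x) for x in self.sequence)

    def adjacency_multiset(self) -> Counter:
        """Multiset of unordered half-site pairs over all adjacencies (with wrap).

        For consecutive elements (a, b) the joined ends are the right end of a
        (aR if a > 0 else |a|L) and the left end of b (bL if b > 0 else |b|R).
        """
        pairs: Counter = Counter()
        seq = self.sequence
        for i, a in enumerate(seq):
            b = seq[(i + 1) % len(seq)]
            end_a = HalfSite(abs(a), "R" if a > 0 else "L")
            end_b = HalfSite(abs(b), "L" if b > 0 else "R")
            pairs[junction_pair(end_a, end_b)] += 1
        return pairs

    def canonical(self) -> "SignedCircularGenome":
        """Deterministic representative under rotation and reflection.

        Reflection (reverse order, flip all signs) is the same molecule read
        from the other strand.  The representative is the lexicographically
        smallest rotation comparing (|id|, sign) with + before -.
        """
        return SignedCircularGenome(canonical_sequence(self.sequence))

    def dotplot_points(self) -> list[tuple[int, int, str]]:
        """(parental_segment_index, position_in_scrambled_order, orientation)."""
        return [
            (abs(x), i + 1, "+" if x > 0 else "-")
            for i, x in enumerate(self.sequence)
        ]

    # -- I/O ---------------------------------------------------------------

    def to_structure_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(" ".join(str(x) for x in self.sequence) + "\n")

    @classmethod
    def from_structure_file(cls, path) -> "SignedCircularGenome":
        with open(path) as fh:
            return cls(int(x) for x in fh.read().split())

    def to_json(self, path, **metadata) -> None:
        with open(path, "w") as fh:
            json.dump({"sequence": list(self.sequence), **metadata}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignedCircularGenome":
        with open(path) as fh:
            return cls(json.load(fh)["sequence"])


def _sort_key(seq: tuple[int, ...]) -> tuple:
    # + orientation sorts before - for the same segment id
    return tuple((abs(x), 0 if x > 0 else 1) for x in seq)


def canonical_sequence(seq: Sequence[int]) -> tuple[int, ...]:
    seq = tuple(seq)
    reflected = tuple(-x for x in reversed(seq))
    best = None
    for s in (seq, reflected):
        for r in range(len(s)):
            cand = s[r:] + s[:r]
            if best is None or _sort_key(cand) < _sort_key(best):
                best = cand
    return best


def synixr_like_reference(
    L: int = 43,
    centromere: int = 2,
    essential: Iterable[int] = (2, 9, 12, 20),
    slow_growth: Iterable[int] = (6, 9, 19, 24),
    markers: dict[str, int] | None = None,
    nc_nc_junctions: Iterable[int] = (28, 36, 43),
    length_range: tuple[int, int] = (135, 5000),
    seed: int = 0,
) -> ReferenceChromosome:
    """Build the default 43-segment circular reference emulating synIXR.

    Essential segments and the centromere (segment 2) are retained by every
    viable strain; the auxotrophic markers MET28 (segment 14) and LYS1
    (segment 32) drive the selection presets.  40 junctions are CDS-UTR (the
    loxPsym site sits 3 nt after each nonessential gene's stop codon) and
    three are NC-NC (LTR / tRNA / subtelomere replacements).  Segment lengths
    are not part of the design nomenclature, so they are drawn log-uniformly
    from ``length_range`` with a fixed seed.
    """
    if markers is None:
        markers = {"MET28": 14, "LYS1": 32}
    essential = frozenset(essential)
    slow = frozenset(slow_growth)
    nc_nc = frozenset(nc_nc_junctions)
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=L)).astype(int)
    lengths = np.clip(lengths, lo, hi)
    seg_markers = {v: k for k, v in markers.items()}
    segments = []
    for i in range(1, L + 1):
        genes = []
        if i in seg_markers:
            genes.append(seg_markers[i])
        if i in slow:
            genes.append(f"SLOW{i}")
        segments.append(
            Segment(
                id=i,
                length_bp=int(lengths[i - 1]),
                essential=i in essential,
                centromere=i == centromere,
                markers=frozenset({seg_markers[i]} if i in seg_markers else ()),
                genes=tuple(genes),
            )
        )
    junctions = []
    for i in range(1, L + 1):
        annot = ("NC", "NC") if i in nc_nc else ("CDS", "UTR")
        junctions.append(
            ParentalJunction(
                HalfSite(i, "R"), HalfSite(i % L + 1, "L"), annot[0], annot[1]
            )
        )
    return ReferenceChromosome(segments, junctions)
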