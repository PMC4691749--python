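"""Seeded generator of SCRaMbLE'd strains and their observable evidence.

Cre acting on a chromosome carrying loxPsym sites recombines pairs of sites;
because the site is symmetric, deletion and inversion of the intervening arc
are equally likely, and replication-coupled recombination additionally yields
tandem and inverted duplications.  The simulator draws recombination events on
the current genome, applies a viability filter (every essential segment
retained, exactly one centromere) and, optionally, an auxotrophic selection
rule (loss of named markers), then emits the observable evidence used by the
downstream stages: junction-spanning read pairs, per-segment read depths, and
long-insert pair tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import numpy as np

from .genome import ReferenceChromosome, SignedCircularGenome

__all__ = [
    "EventSpec",
    "SimulationConfig",
    "DepthModel",
    "ReadModel",
    "LongPair",
    "SimulationError",
    "apply_event",
    "simulate_scramble",
    "simulate_disjoint_events",
    "synthesize_segment_sequences",
    "chromosome_sequence",
    "simulate_depth_table",
    "simulate_read_pairs",
    "simulate_long_pairs",
    "default_loxpsym",
    "reverse_complement",
    "genome_layout",
    "write_paired_fasta",
    "read_paired_fasta",
]

EVENT_TYPES = ("deletion", "inversion", "tandem_duplication", "inverted_duplication")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_loxpsym() -> str:
    """A 34-bp perfect reverse-complement palindrome used as the loxPsym site."""
    half = "ATAACTTCGTATAATGT"
    site = half + reverse_complement(half)
    assert len(site) == 34 and reverse_complement(site) == site
    return site


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EventSpec:
    """One recombination event on the *current* genome.

    ``site_a``/``site_b`` index loxPsym junctions of the current cyclic
    sequence (junction j sits between elements j and j+1 mod n); the affected
    arc is the forward arc from site_a to site_b.
    """

    type: str
    site_a: int
    site_b: int
    mechanism: str = "cre_loxpsym"

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.site_a == self.site_b:
            raise ValueError("an event needs two distinct junctions")


def apply_event(genome: SignedCircularGenome, event: EventSpec) -> SignedCircularGenome:
    """Apply one recombination event and return the rearranged genome.

    Deletion removes the arc (one new adjacency); inversion reverses and
    sign-flips it (two new adjacencies); tandem duplication repeats it in the
    same orientation; inverted duplication appends its reflection.
    """
    n = len(genome)
    a, b = event.site_a % n, event.site_b % n
    if a == b:
        raise ValueError("event sites must index distinct adjacencies")
    rot = genome.sequence[a + 1 :] + genome.sequence[: a + 1]
    m = (b - a) % n
    arc, rest = rot[:m], rot[m:]
    if event.type == "deletion":
        if not rest:
            raise ValueError("deletion may not remove the whole genome")
        return SignedCircularGenome(rest)
    reflected = tuple(-x for x in reversed(arc))
    if event.type == "inversion":
        return SignedCircularGenome(reflected + rest)
    if event.type == "tandem_duplication":
        return SignedCircularGenome(arc + arc + rest)
    return SignedCircularGenome(arc + reflected + rest)  # inverted_duplication


@dataclass
class DepthModel:
    """Noise model for per-segment mean read depth.

    Sampling noise is drawn independently per ``unit_bp`` of sequence and the
    observed value is the segment average, so it shrinks with segment length;
    systematic per-segment bias (``bias_sigma``) is shared between the strain
    and reference libraries and cancels in depth ratios, emulating
    mappability/GC effects.  Correlation between neighbouring bases induced
    by read length is not modelled.
    """

    mean: float = 30.0
    noise: Literal["none", "poisson", "negative_binomial"] = "poisson"
    dispersion: float = 10.0  # NB size parameter per unit; larger = tighter
    bias_sigma: float = 0.0  # lognormal sd of the shared per-segment bias
    unit_bp: int = 1


@dataclass
class ReadModel:
    read_length: int = 100
    short_insert_mean: float = 500.0
    short_insert_sd: float = 50.0
    long_insert_mean: float = 10_000.0
    long_insert_sd: float = 1_000.0
    long_read_length: int = 90
    coverage: float = 30.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated SCRaMbLE induction."""

    n_events: int | tuple[str, float] = ("poisson", 6.2)
    event_probs: dict[str, float] = field(
        default_factory=lambda: {
            "deletion": 0.375,
            "inversion": 0.375,
            "tandem_duplication": 0.125,
            "inverted_duplication": 0.125,
        }
    )
    distance_model: Literal["uniform", "exponential"] = "exponential"
    distance_scale_bp: float = 10_000.0
    min_distance_bp: float = 82.0  # minimum loxP recombination distance
    viability: bool = True
    selection_markers: tuple[str, ...] = ()
    selection_mode: Literal["any", "all"] = "any"
    max_event_retries: int = 200
    max_lineage_retries: int = 500
    depth: DepthModel = field(default_factory=DepthModel)
    reads: ReadModel = field(default_factory=ReadModel)
    seed: int | None = None

    def __post_init__(self):
        total = sum(self.event_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("event type probabilities must sum to 1")
        for k in self.event_probs:
            if k not in EVENT_TYPES:
                raise ValueError(f"unknown event type {k!r}")


def _is_viable(genome: SignedCircularGenome, reference: ReferenceChromosome) -> bool:
    copies = genome.copy_numbers()
    if any(copies.get(e, 0) < 1 for e in reference.essential_ids):
        return False
    return copies.get(reference.centromere_id, 0) == 1


def _arc_length_bp(
    seq: Sequence[int], lengths: dict[int, int], a: int, b: int, lox_len: int
) -> float:
    n = len(seq)
    m = (b - a) % n
    total = 0
    for k in range(m):
        total += lengths[abs(seq[(a + 1 + k) % n])]
    return total + max(m - 1, 0) * lox_len


def _candidate_sites(genome, reference, config):
    """Eligible junction pairs and their distance weights on the current genome."""
    n = len(genome)
    lengths = reference.lengths
    pairs, weights = [], []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            d = _arc_length_bp(genome.sequence, lengths, a, b, 34)
            if d < config.min_distance_bp:
                continue
            pairs.append((a, b))
            if config.distance_model == "exponential":
                weights.append(np.exp(-d / config.distance_scale_bp))
            else:
                weights.append(1.0)
    if not pairs:
        return [], None
    w = np.asarray(weights)
    return pairs, w / w.sum()


def simulate_scramble(
    reference: ReferenceChromosome,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[SignedCircularGenome, list[EventSpec]]:
    """Simulate one SCRaMbLE lineage; fully reproducible given the seed.

    Inviable proposals (an essential segment lost, or the centromere copy
    number leaving 1) are rejected and resampled, emulating that inviable
    recombinants are never recovered.  If a selection rule is configured, the
    whole lineage is resampled until the marker-loss condition holds.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    for _ in range(max(config.max_lineage_retries, 1)):
        genome, log = _simulate_lineage(reference, config, rng)
        if not config.selection_markers:
            return genome, log
        copies = genome.copy_numbers()
        lost = [
            m
            for m in config.selection_markers
            if copies.get(reference.marker_segment(m), 0) == 0
        ]
        ok = (
            len(lost) == len(config.selection_markers)
            if config.selection_mode == "all"
            else len(lost) > 0
        )
        if ok:
            return genome, log
    raise SimulationError(
        f"selection {config.selection_markers} ({config.selection_mode}) not "
        f"satisfied within {config.max_lineage_retries} lineage attempts"
    )


def _simulate_lineage(reference, config, rng):
    if isinstance(config.n_events, tuple):
        dist, mean = config.n_events
        if dist != "poisson":
            raise ValueError(f"unknown event-count distribution {dist!r}")
        k = int(rng.poisson(mean))
    else:
        k = int(config.n_events)
    genome = reference.parental_genome()
    log: list[EventSpec] = []
    types = sorted(config.event_probs)
    probs = np.array([config.event_probs[t] for t in types])
    for _ in range(k):
        # the event type is drawn once and kept while inviable site pairs are
        # rejected and resampled, so viability filtering does not skew the
        # realized deletion/inversion balance away from the designed one
        etype = types[rng.choice(len(types), p=probs)]
        pairs, p = _candidate_sites(genome, reference, config)
        if not pairs:
            break
        placed = False
        for _attempt in range(max(config.max_event_retries, 1)):
            a, b = pairs[rng.choice(len(pairs), p=p)]
            event = EventSpec(etype, a, b)
            candidate = apply_event(genome, event)
            if not config.viability or _is_viable(candidate, reference):
                genome = candidate
                log.append(event)
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"no viable {etype} found in {config.max_event_retries} attempts"
            )
    return genome, log


def replay_events(
    reference: ReferenceChromosome, events: Iterable[EventSpec]
) -> SignedCircularGenome:
    """Re-apply a logged event sequence to the parent (exact reproduction)."""
    genome = reference.parental_genome()
    for e in events:
        genome = apply_event(genome, e)
    return genome


# ---------------------------------------------------------------------------
# disjoint-span preset (events whose parental footprints do not touch)


def simulate_disjoint_events(
    reference: ReferenceChromosome,
    n_events: int,
    seed: int,
    event_probs: dict[str, float] | None = None,
    max_span: int = 4,
) -> tuple[SignedCircularGenome, list[dict]]:
    """Sample events with pairwise disjoint, non-adjacent parental spans.

    Returns the rearranged genome together with ground-truth records
    ``{"type", "span": (start_seg, end_seg)}`` in parental coordinates;
    useful wherever unambiguous event-level truth is needed.
    """
    rng = np.random.default_rng(seed)
    if event_probs is None:
        event_probs = {t: 0.25 for t in EVENT_TYPES}
    types = sorted(event_probs)
    probs = np.array([event_probs[t] for t in types])
    L = reference.L
    protected = reference.essential_ids | {reference.centromere_id}
    free = [False] * (L + 1)  # 1-based; True once used (incl. 1-segment buffer)
    records: list[dict] = []
    attempts = 0
    while len(records) < n_events and attempts < 500 * n_events:
        attempts += 1
        etype = types[rng.choice(len(types), p=probs)]
        span = int(rng.integers(1, max_span + 1))
        # keep spans away from the wrap point so parental order is preserved
        start = int(rng.integers(2, L - span))
        segs = list(range(start, start + span))
        lo, hi = max(start - 1, 1), min(start + span, L)
        if any(free[s] for s in range(lo, hi + 1)):
            continue
        if etype == "deletion" and any(s in protected for s in segs):
            continue
        if etype in ("tandem_duplication", "inverted_duplication") and (
            reference.centromere_id in segs
        ):
            continue
        for s in range(lo, hi + 1):
            free[s] = True
        records.append({"type": etype, "span": (start, start + span - 1)})
    records.sort(key=lambda r: r["span"][0])
    seq: list[int] = []
    covered = {s for r in records for s in range(r["span"][0], r["span"][1] + 1)}
    by_start = {r["span"][0]: r for r in records}
    i = 1
    while i <= L:
        if i in by_start:
            r = by_start[i]
            s0, s1 = r["span"]
            arc = list(range(s0, s1 + 1))
            if r["type"] == "deletion":
                pass
            elif r["type"] == "inversion":
                seq.extend(-x for x in reversed(arc))
            elif r["type"] == "tandem_duplication":
                seq.extend(arc + arc)
            else:
                seq.extend(arc + [-x for x in reversed(arc)])
            i = s1 + 1
        else:
            if i not in covered:
                seq.append(i)
            i += 1
    return SignedCircularGenome(seq), records


# ---------------------------------------------------------------------------
# sequence-level evidence


def synthesize_segment_sequences(
    reference: ReferenceChromosome,
    loxpsym_seq: str | None = None,
    seed: int = 0,
) -> dict[int, str]:
    """Random nucleotide sequences per segment, free of internal loxPsym sites.

    The full parental chromosome (segments interleaved with the loxPsym site)
    is guaranteed to contain exactly L occurrences of the site.
    """
    lox = loxpsym_seq if loxpsym_seq is not None else default_loxpsym()
    if len(lox) != 34 or reverse_complement(lox) != lox:
        raise ValueError("loxPsym site must be a 34-bp reverse-complement palindrome")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[int, str] = {}
    for s in reference.segments:
        while True:
            seq = "".join(rng.choice(bases, size=s.length_bp))
            if lox not in seq and lox not in reverse_complement(seq):
                seqs[s.id] = seq
                break
    # guard against site occurrences spanning a segment/lox boundary
    for _ in range(10):
        full = chromosome_sequence(reference.parental_genome(), seqs, lox)
        if (full + full[: len(lox) - 1]).count(lox) == reference.L:
            return seqs
        bad = _first_bad_segment(reference, seqs, lox)
        seqs[bad] = "".join(rng.choice(bases, size=len(seqs[bad])))
    raise SimulationError("could not synthesize loxPsym-free segment sequences")


def _first_bad_segment(reference, seqs, lox):
    for s in reference.segments:
        flank = lox[-(len(lox) - 1) :]
        if lox in (flank + seqs[s.id] + flank):
            return s.id
    return reference.segments[0].id


def chromosome_sequence(
    genome: SignedCircularGenome, segment_sequences: dict[int, str], loxpsym_seq: str
) -> str:
    """Linearized circular sequence starting at element 0 (wraps implicitly)."""
    parts = []
    for x in genome.sequence:
        s = segment_sequences[abs(x)]
        parts.append(s if x > 0 else reverse_complement(s))
        parts.append(loxpsym_seq)
    return "".join(parts)


def genome_layout(
    genome: SignedCircularGenome, lengths: dict[int, int], lox_len: int = 34
) -> list[tuple[int, int, int]]:
    """Per-element layout on the circle: (signed_segment, body_start, body_len)."""
    out = []
    pos = 0
    for x in genome.sequence:
        ln = lengths[abs(x)]
        out.append((x, pos, ln))
        pos += ln + lox_len
    return out


def simulate_depth_table(
    genome: SignedCircularGenome,
    reference: ReferenceChromosome,
    depth_model: DepthModel | None = None,
    seed: int = 0,
):
    """Observed mean depths per segment for the strain and the reference run.

    Expected depth is copy number x mean x a per-segment bias factor shared
    between the strain and reference libraries (emulating mapping bias); the
    reference strain has copy number 1 everywhere.
    """
    from .copynumber import DepthTable

    dm = depth_model or DepthModel()
    rng = np.random.default_rng(seed)
    L = reference.L
    copies = genome.copy_numbers()
    n = np.array([copies.get(i, 0) for i in range(1, L + 1)], dtype=float)
    bias = (
        np.exp(rng.normal(0.0, dm.bias_sigma, size=L)) if dm.bias_sigma > 0 else np.ones(L)
    )
    mu_t = dm.mean * n * bias
    mu_r = dm.mean * np.ones(L) * bias
    # independent noise per unit_bp window; the observed value is the average
    units = np.maximum(
        np.array([reference.lengths[i] for i in range(1, L + 1)]) // dm.unit_bp, 1
    )
    if dm.noise == "none":
        d_t, d_r = mu_t, mu_r
    elif dm.noise == "poisson":
        d_t = rng.poisson(mu_t * units) / units
        d_r = rng.poisson(mu_r * units) / units
    elif dm.noise == "negative_binomial":
        # sum of per-window NB(mu, r) draws is NB(mu*units, r*units)
        r = dm.dispersion * units
        p_t = r / (r + mu_t * units)
        p_r = r / (r + mu_r * units)
        d_t = rng.negative_binomial(r, p_t) / units
        d_r = rng.negative_binomial(r, p_r) / units
    else:
        raise ValueError(f"unknown noise model {dm.noise!r}")
    d_r = np.maximum(d_r, 1.0)  # reference depths are strictly positive
    return DepthTable(
        segment_ids=np.arange(1, L + 1), depth_strain=d_t, depth_reference=d_r
    )


def simulate_read_pairs(
    genome: SignedCircularGenome,
    segment_sequences: dict[int, str],
    read_model: ReadModel | None = None,
    loxpsym_seq: str | None = None,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Short-insert paired reads (name, read1, read2) from the circular genome.

    Reads are error-free; read2 is the reverse complement of the far end of a
    Gaussian-length insert (convergent orientation).
    """
    rm = read_model or ReadModel()
    lox = loxpsym_seq if loxpsym_seq is not None else default_loxpsym()
    rng = np.random.default_rng(seed)
    circle = chromosome_sequence(genome, segment_sequences, lox)
    G = len(circle)
    rl = rm.read_length
    n_pairs = max(1, int(round(rm.coverage * G / (2 * rl))))
    doubled = circle + circle
    pairs = []
    for i in range(n_pairs):
        ins = int(round(rng.normal(rm.short_insert_mean, rm.short_insert_sd)))
        ins = max(2 * rl, min(ins, G))
        p = int(rng.integers(0, G))
        r1 = doubled[p : p + rl]
        r2 = reverse_complement(doubled[p + ins - rl : p + ins])
        pairs.append((f"pair_{i}", r1, r2))
    return pairs


@dataclass(frozen=True)
class LongPair:
    """Anchors of one long-insert read pair, in parental segment coordinates.

    ``pos`` is the leftmost base of the read in segment-forward coordinates;
    ``strand`` is the read's orientation in the segment frame (+1/-1).
    """

    seg_a: int
    pos_a: int
    strand_a: int
    seg_b: int
    pos_b: int
    strand_b: int


def simulate_long_pairs(
    genome: SignedCircularGenome,
    reference: ReferenceChromosome,
    read_model: ReadModel | None = None,
    n_pairs: int = 200,
    seed: int = 0,
    lox_len: int = 34,
) -> list[LongPair]:
    """Long-insert (~10 kb) pairs as segment-anchored flanks.

    Reads falling in a loxPsym site or crossing a segment boundary are
    resampled, so every emitted pair has both flanks anchored unambiguously
    inside single parental segments (matching the aligner behaviour the real
    long-insert filter relies on).
    """
    rm = read_model or ReadModel()
    rng = np.random.default_rng(seed)
    layout = genome_layout(genome, reference.lengths, lox_len)
    total = sum(ln + lox_len for _, _, ln in layout)
    rl = rm.long_read_length

    def locate(pos: int):
        pos %= total
        for x, start, ln in layout:
            if start <= pos and pos + rl <= start + ln:
                off = pos - start
                if x > 0:
                    return abs(x), off, 1
                return abs(x), ln - rl - off, -1
        return None

    pairs: list[LongPair] = []
    guard = 0
    while len(pairs) < n_pairs and guard < 100 * n_pairs:
        guard += 1
        ins = int(round(rng.normal(rm.long_insert_mean, rm.long_insert_sd)))
        if ins >= total or ins < 2 * rl:
            continue
        p = int(rng.integers(0, total))
        a = locate(p)
        b = locate(p + ins - rl)
        if a is None or b is None:
            continue
        sa, pa, oa = a
        sb, pb, ob = b
        # read1 forward on the genome, read2 reverse
        pairs.append(LongPair(sa, pa, oa, sb, pb, -ob))
    if len(pairs) < n_pairs:
        raise SimulationError("could not place the requested number of long pairs")
    return pairs


# ---------------------------------------------------------------------------
# plain-text I/O


def write_paired_fasta(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, r1, r2 in pairs:
            f1.write(f">{name}/1\n{r1}\n")
            f2.write(f">{name}/2\n{r2}\n")


def read_paired_fasta(path1, path2) -> list[tuple[str, str, str]]:
    def _read(path):
        names, seqs = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    names.append(line[1:].split("/")[0])
                    seqs.append("")
                elif line:
                    seqs[-1] += line
        return names, seqs

    n1, s1 = _read(path1)
    n2, s2 = _read(path2)
    if n1 != n2:
        raise ValueError("mate files out of sync")
    return list(zip(n1, s1, s2))


def write_long_pairs_tsv(pairs: Iterable[LongPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("seg_a\tpos_a\tstrand_a\tseg_b\tpos_b\tstrand_b\n")
        for p in pairs:
            fh.write(
                f"{p.seg_a}\t{p.pos_a}\t{p.strand_a}\t{p.seg_b}\t{p.pos_b}\t{p.strand_b}\n"
            )


def read_long_pairs_tsv(path) -> list[LongPair]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                LongPair(
                    int(row["seg_a"]), int(row["pos_a"]), int(row["strand_a"]),
                    int(row["seg_b"]), int(row["pos_b"]), int(row["strand_b"]),
                )
            )
    return out


def write_event_log(events: Iterable[EventSpec], path, **metadata) -> None:
    with open(path, "w") as fh:
        json.dump({"events": [asdict(e) for e in events], **metadata}, fh, indent=1)


def read_event_log(path) -> list[EventSpec]:
    with open(path) as fh:
        data = json.load(fh)
    return [EventSpec(**e) for e in data["events"]]
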