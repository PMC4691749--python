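"""Genome reconstruction from junction evidence and copy numbers.

The evidence is encoded as an undirected multigraph on segment half-sites:
segment i with copy number N_i contributes N_i parallel "segment" edges
iL--iR, and every observed junction contributes a "junction" edge between the
two half-sites it joins (with multiplicity).  A rearranged circular genome is
exactly an alternating Eulerian circuit of this bicolored graph: traversals
of segment edges decode to signed segment ids, junction edges to the loxPsym
adjacencies between them.  Feasibility (balanced bicolored degrees plus
connectivity) is checked in linear time; circuits are enumerated by
deterministic backtracking and deduplicated up to rotation and reflection.

Candidates that survive short-insert evidence can be ranked and filtered with
long-insert (~10 kb) pairs: a pair is PE on a candidate when some placement
of its two anchors is convergent with an implied span inside the insert
window, otherwise SE; candidates retaining irregular SE clusters or novel
junctions spanned by no long pair are rejected, and the lexicographically
smallest canonical survivor is reported.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome import (
    HalfSite,
    Junction,
    ReferenceChromosome,
    SignedCircularGenome,
    junction_pair,
)
from .simulate import LongPair, genome_layout

__all__ = [
    "JunctionGraph",
    "ReconstructionSet",
    "LongInsertCheck",
    "InfeasibleEvidenceError",
    "build_junction_graph",
    "infer_junction_multiplicities",
    "is_feasible",
    "enumerate_genomes",
    "count_genomes",
    "long_insert_consistency",
    "filter_and_select",
]


class InfeasibleEvidenceError(ValueError):
    pass


@dataclass
class JunctionGraph:
    """Junction-edge multiset plus per-segment copy numbers (segment edges)."""

    junction_edges: Counter  # Junction -> multiplicity
    copy_numbers: dict[int, int]  # segment -> N_i (> 0 only)

    @property
    def vertices(self) -> list[HalfSite]:
        return [
            HalfSite(i, s) for i in sorted(self.copy_numbers) for s in ("L", "R")
        ]

    def junction_degree(self, hs: HalfSite) -> int:
        deg = 0
        for (a, b), mult in self.junction_edges.items():
            if a == hs:
                deg += mult
            if b == hs:
                deg += mult
        return deg


def build_junction_graph(
    junctions: Iterable,
    copy_numbers: Mapping[int, int],
    parental_pairs: frozenset[Junction] | None = None,
    multiplicities: Mapping[Junction, int] | None = None,
) -> JunctionGraph:
    """Assemble the evidence graph.

    ``junctions`` may be half-site pairs, ``(pair, multiplicity)`` tuples, or
    JunctionObservation objects.  When a multiplicity is not given
    explicitly, a parental junction defaults to the minimum of its flanking
    copy numbers and a novel junction to 1.
    """
    copies = {int(k): int(v) for k, v in copy_numbers.items() if int(v) > 0}
    edges: Counter = Counter()
    for item in junctions:
        mult = None
        if hasattr(item, "pair"):  # JunctionObservation
            pair = item.pair
        elif (
            isinstance(item, tuple)
            and len(item) == 2
            and isinstance(item[1], int)
            and isinstance(item[0], tuple)
            and isinstance(item[0][0], HalfSite)
        ):
            pair, mult = item
        else:
            pair = item
        a, b = pair
        pair = junction_pair(a, b)
        for hs in pair:
            if hs.segment_id not in copies:
                raise InfeasibleEvidenceError(
                    f"junction {pair[0]}-{pair[1]} touches zero-copy segment "
                    f"{hs.segment_id}"
                )
        if mult is None and multiplicities is not None:
            mult = multiplicities.get(pair)
        if mult is None:
            if parental_pairs is not None and pair in parental_pairs:
                mult = min(copies[pair[0].segment_id], copies[pair[1].segment_id])
            else:
                mult = 1
        edges[pair] += mult
    return JunctionGraph(edges, copies)


def infer_junction_multiplicities(
    observations: Iterable,
    parental_pairs: frozenset[Junction],
    copy_numbers: Mapping[int, int],
) -> dict[Junction, int]:
    """Estimate junction edge multiplicities from degree balance.

    Every half-site of segment i must carry exactly N_i junction-edge ends in
    a feasible evidence graph.  Starting from multiplicity 1 everywhere,
    junctions whose two half-sites both have a degree deficit are incremented
    (read support, relative to the current multiplicity, breaks ties), which
    resolves adjacencies reused by duplications.  If the observations cannot
    be balanced the partial assignment is returned and feasibility checking
    reports the defect.
    """
    copies = {int(k): int(v) for k, v in copy_numbers.items()}
    support: dict[Junction, int] = {}
    for o in observations:
        pair = junction_pair(*o.pair)
        support[pair] = support.get(pair, 0) + getattr(o, "support", 1)
    mults = {pair: 1 for pair in support}

    def residuals():
        deg: Counter = Counter()
        for pair, m in mults.items():
            deg[pair[0]] += m
            deg[pair[1]] += m
        return {
            HalfSite(i, s): copies.get(i, 0) - deg[HalfSite(i, s)]
            for i in copies
            for s in ("L", "R")
        }

    for _ in range(2 * sum(copies.values()) + 1):
        res = residuals()
        candidates = []
        for pair in mults:
            a, b = pair
            if a == b:
                if res.get(a, 0) >= 2:
                    candidates.append(pair)
            elif res.get(a, 0) > 0 and res.get(b, 0) > 0:
                candidates.append(pair)
        if not candidates:
            break
        best = max(candidates, key=lambda p: (support[p] / mults[p], p))
        mults[best] += 1
    return mults


def is_feasible(graph: JunctionGraph) -> tuple[bool, list[str]]:
    """Linear-time existence check for an alternating Eulerian circuit.

    Requires junction-degree(iL) = junction-degree(iR) = N_i for every
    retained segment (so segment and junction edges can alternate) and a
    single connected component over all edges.
    """
    problems: list[str] = []
    if not graph.copy_numbers:
        return False, ["no retained segments"]
    deg: Counter = Counter()
    for (a, b), mult in graph.junction_edges.items():
        deg[a] += mult
        deg[b] += mult
    for i, n in sorted(graph.copy_numbers.items()):
        for side in ("L", "R"):
            d = deg[HalfSite(i, side)]
            if d != n:
                problems.append(
                    f"half-site {i}{side}: junction degree {d} != copy number {n}"
                )
    # connectivity via union-find over half-sites
    parent: dict[HalfSite, HalfSite] = {v: v for v in graph.vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for i in graph.copy_numbers:
        union(HalfSite(i, "L"), HalfSite(i, "R"))
    for (a, b) in graph.junction_edges:
        union(a, b)
    roots = {find(v) for v in parent}
    if len(roots) > 1:
        problems.append(f"evidence graph has {len(roots)} connected components")
    return not problems, problems


@dataclass
class ReconstructionSet:
    candidates: list[SignedCircularGenome]
    total_count: int
    truncated: bool = False
    selected: SignedCircularGenome | None = None
    diagnostics: dict = field(default_factory=dict)


def _other_side(side: str) -> str:
    return "L" if side == "R" else "R"


def _alternating_circuits(graph: JunctionGraph):
    """Yield decoded signed sequences of all alternating Eulerian circuits.

    The walk is anchored in the smallest retained segment traversed in +
    orientation, so every rotation/reflection class is generated at least
    once and each distinct anchored linear decoding exactly once.
    """
    anchor = min(graph.copy_numbers)
    remaining = dict(graph.junction_edges)
    incident: dict[HalfSite, list[Junction]] = defaultdict(list)
    for pair in sorted(remaining):
        a, b = pair
        incident[a].append(pair)
        if b != a:
            incident[b].append(pair)
    total_edges = sum(remaining.values())
    close_at = HalfSite(anchor, "L")
    seq = [anchor]
    out: list[list[int]] = []

    def walk(current: HalfSite, left: int):
        for pair in incident[current]:
            if remaining[pair] == 0:
                continue
            a, b = pair
            arrive = b if a == current else a
            remaining[pair] -= 1
            if left == 1:
                if arrive == close_at:
                    yield list(seq)
            else:
                j = arrive.segment_id
                seq.append(j if arrive.side == "L" else -j)
                yield from walk(HalfSite(j, _other_side(arrive.side)), left - 1)
                seq.pop()
            remaining[pair] += 1

    yield from walk(HalfSite(anchor, "R"), total_edges)


def enumerate_genomes(
    graph: JunctionGraph, limit: int | None = None
) -> ReconstructionSet:
    """Enumerate all circular signed genomes consistent with the evidence.

    Solutions are deduplicated by canonical form (one molecule: rotations and
    reflections identified).  With a ``limit``, enumeration stops after
    materializing that many distinct solutions and ``truncated`` is set;
    ``total_count`` is then a lower bound.
    """
    ok, problems = is_feasible(graph)
    if not ok:
        raise InfeasibleEvidenceError("; ".join(problems))
    seen: set[tuple[int, ...]] = set()
    candidates: list[SignedCircularGenome] = []
    truncated = False
    for decoded in _alternating_circuits(graph):
        g = SignedCircularGenome(decoded).canonical()
        if g.sequence not in seen:
            seen.add(g.sequence)
            candidates.append(g)
            if limit is not None and len(candidates) >= limit:
                truncated = True
                break
    candidates.sort(key=lambda g: g.sequence)
    selected = candidates[0] if candidates else None
    return ReconstructionSet(
        candidates=candidates,
        total_count=len(candidates),
        truncated=truncated,
        selected=selected,
    )


def count_genomes(graph: JunctionGraph, convention: str = "canonical") -> int:
    """Exact solution count without storing genomes (hashes only).

    ``convention="canonical"`` counts one per rotation+reflection class;
    ``convention="rotations-fixed"`` counts every distinct linear sequence
    (all rotations, both strand readings) as separate solutions.
    """
    if convention not in ("canonical", "rotations-fixed"):
        raise ValueError("convention must be 'canonical' or 'rotations-fixed'")
    ok, problems = is_feasible(graph)
    if not ok:
        raise InfeasibleEvidenceError("; ".join(problems))
    seen: set[int] = set()
    total = 0
    for decoded in _alternating_circuits(graph):
        canon = SignedCircularGenome(decoded).canonical().sequence
        h = hash(canon)
        if h in seen:
            continue
        seen.add(h)
        if convention == "canonical":
            total += 1
        else:
            orbit = set()
            for s in (canon, tuple(-x for x in reversed(canon))):
                for r in range(len(s)):
                    orbit.add(s[r:] + s[:r])
            total += len(orbit)
    return total


@dataclass
class LongInsertCheck:
    PE: int
    SE: int
    unmapped: int
    irregular_clusters: list
    uncovered_junctions: list

    @property
    def rate(self) -> float:
        return self.PE / (self.PE + self.SE) if (self.PE + self.SE) else 1.0


def long_insert_consistency(
    candidate: SignedCircularGenome,
    long_pairs: Sequence[LongPair],
    reference: ReferenceChromosome,
    min_insert: int = 7500,
    max_insert: int = 12500,
    cluster_min: int = 3,
    read_length: int = 90,
    lox_len: int = 34,
) -> LongInsertCheck:
    """Score a candidate genome against long-insert pair evidence.

    A pair is PE when some placement of its two segment anchors on the
    candidate is convergent with an implied span inside
    ``[min_insert, max_insert]`` (computed on the circle); pairs whose anchors
    both place but never properly are SE; pairs anchored in segments absent
    from the candidate are unmapped.  SE pairs co-located in 1-kb bins form
    irregular clusters; candidate novel junctions spanned by no PE pair are
    reported as uncovered.
    """
    layout = genome_layout(candidate, reference.lengths, lox_len)
    total = sum(ln + lox_len for _, _, ln in layout)
    occ: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
    for x, start, ln in layout:
        occ[abs(x)].append((1 if x > 0 else -1, start, ln))
    # candidate junction (loxPsym) midpoints, novel ones only
    parental = reference.parental_pairs
    pairs_at = list(candidate.adjacency_multiset().elements())
    novel_positions: list[tuple[Junction, int]] = []
    pos_iter = 0
    for idx, (x, start, ln) in enumerate(layout):
        nxt = candidate.sequence[(idx + 1) % len(layout)]
        end_a = HalfSite(abs(x), "R" if x > 0 else "L")
        end_b = HalfSite(abs(nxt), "L" if nxt > 0 else "R")
        pair = junction_pair(end_a, end_b)
        if pair not in parental:
            novel_positions.append((pair, (start + ln + lox_len // 2) % total, idx))
    pe = se = unmapped = 0
    se_anchor_bins: Counter = Counter()
    covered: set[int] = set()
    for lp in long_pairs:
        if lp.seg_a not in occ or lp.seg_b not in occ:
            unmapped += 1
            continue
        best_pe_intervals = []
        placed = False
        for oa, ga, la in occ[lp.seg_a]:
            pa = ga + (lp.pos_a if oa > 0 else la - read_length - lp.pos_a)
            stra = lp.strand_a * oa
            for ob, gb, lb in occ[lp.seg_b]:
                pb = gb + (lp.pos_b if ob > 0 else lb - read_length - lp.pos_b)
                strb = lp.strand_b * ob
                placed = True
                if stra == strb:
                    continue
                fwd, rev = (pa, pb) if stra > 0 else (pb, pa)
                span = (rev + read_length - fwd) % total
                if min_insert <= span <= max_insert:
                    best_pe_intervals.append((fwd, span))
        if not placed:
            unmapped += 1
        elif best_pe_intervals:
            pe += 1
            for fwd, span in best_pe_intervals:
                for pair, jpos, idx in novel_positions:
                    if (jpos - fwd) % total < span:
                        covered.add(idx)
        else:
            se += 1
            se_anchor_bins[(lp.seg_a, lp.pos_a // 1000)] += 1
    clusters = [k for k, v in se_anchor_bins.items() if v >= cluster_min]
    uncovered = [
        pair for pair, _, idx in novel_positions if idx not in covered
    ]
    return LongInsertCheck(
        PE=pe, SE=se, unmapped=unmapped,
        irregular_clusters=clusters, uncovered_junctions=uncovered,
    )


def filter_and_select(
    candidates: Sequence[SignedCircularGenome],
    long_pairs: Sequence[LongPair] | None,
    reference: ReferenceChromosome,
    **check_kwargs,
) -> ReconstructionSet:
    """Filter candidates by long-insert consistency and pick the reported one.

    Survivors must have zero irregular clusters, zero uncovered novel
    junctions, and the maximal regular mapping rate PE/(PE+SE); the selected
    solution is the lowest canonical form in numerical sort order.  Without
    long pairs, all candidates survive.
    """
    if not candidates:
        raise ValueError("no candidates to filter")
    cands = sorted((c.canonical() for c in candidates), key=lambda g: g.sequence)
    if not long_pairs:
        return ReconstructionSet(
            candidates=cands, total_count=len(cands), selected=cands[0]
        )
    checks = [
        long_insert_consistency(c, long_pairs, reference, **check_kwargs)
        for c in cands
    ]
    eligible = [
        (c, chk)
        for c, chk in zip(cands, checks)
        if not chk.irregular_clusters and not chk.uncovered_junctions
    ]
    diagnostics = {
        " ".join(map(str, c.sequence)): {
            "PE": chk.PE, "SE": chk.SE, "rate": chk.rate,
            "clusters": len(chk.irregular_clusters),
            "uncovered": len(chk.uncovered_junctions),
        }
        for c, chk in zip(cands, checks)
    }
    if not eligible:
        return ReconstructionSet(
            candidates=[], total_count=0, selected=None, diagnostics=diagnostics
        )
    best = max(chk.rate for _, chk in eligible)
    survivors = [c for c, chk in eligible if chk.rate >= best - 1e-12]
    return ReconstructionSet(
        candidates=survivors,
        total_count=len(survivors),
        selected=survivors[0],
        diagnostics=diagnostics,
    )
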