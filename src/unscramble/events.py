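"""Decompose a reconstructed genome into classified recombination events.

Relative to the parental segment order, a deletion is a maximal parental run
at copy number zero; a duplicated region is a maximal parental run at copy
number >= 2, tandem when its genome occurrences share one direction and
inverted when directions alternate; runs of minority-orientation elements
that read as a reversed parental interval are inversions.  Every junction of
the genome is then labelled by the event(s) whose endpoints created it:
parental, deletion, inversion, duplication, multiple (>= 2 events) or
complex, with contiguous complex junctions merged into one complex event.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .genome import (
    HalfSite,
    Junction,
    ReferenceChromosome,
    SignedCircularGenome,
    junction_pair,
)

__all__ = [
    "EventRecord",
    "classify_events",
    "classify_junctions",
    "event_distance",
    "strain_event_summary",
]

EVENT_LABEL = {
    "deletion": "deletion",
    "inversion": "inversion",
    "tandem_duplication": "duplication",
    "inverted_duplication": "duplication",
}


@dataclass(frozen=True)
class EventRecord:
    type: str  # deletion | inversion | tandem_duplication | inverted_duplication | complex
    span: tuple[int, int] | None  # (start_seg, end_seg) in parental order, circular
    novel_junctions: tuple[Junction, ...] = ()
    copies: int = 1  # occurrence count for duplications
    orientation_pattern: tuple[int, ...] = ()


def _circular_runs(ids: list[int], L: int) -> list[tuple[int, int]]:
    """Group sorted parental ids into maximal circular consecutive runs."""
    if not ids:
        return []
    member = set(ids)
    if len(member) == L:
        return [(1, L)]
    runs = []
    for s in sorted(member):
        prev = L if s == 1 else s - 1
        if prev not in member:  # run start
            e = s
            while (1 if e == L else e + 1) in member:
                e = 1 if e == L else e + 1
            runs.append((s, e))
    return runs


def _span_segments(span: tuple[int, int], L: int) -> list[int]:
    s, e = span
    out = [s]
    while out[-1] != e:
        out.append(1 if out[-1] == L else out[-1] + 1)
    return out


def _prev(i: int, L: int) -> int:
    return L if i == 1 else i - 1


def _next(i: int, L: int) -> int:
    return 1 if i == L else i + 1


def classify_events(
    genome: SignedCircularGenome, reference: ReferenceChromosome
) -> list[EventRecord]:
    """Classify the recombination events separating genome from parent."""
    L = reference.L
    copies = genome.copy_numbers()
    for x in genome.sequence:
        if not 1 <= abs(x) <= L:
            raise ValueError(f"segment {abs(x)} is not in the reference")
    seq = list(genome.sequence)
    # read the molecule in its dominant direction; an exact tie is ambiguous
    # and everything non-parental will fall through to complex
    n_plus = sum(1 for x in seq if x > 0)
    n_minus = len(seq) - n_plus
    if n_minus > n_plus:
        seq = [-x for x in reversed(seq)]
    n = len(seq)

    records: list[EventRecord] = []
    # deletions: parental runs at copy zero
    for span in _circular_runs([i for i in range(1, L + 1) if copies.get(i, 0) == 0], L):
        s, e = span
        records.append(
            EventRecord(
                "deletion",
                span,
                novel_junctions=(
                    junction_pair(HalfSite(_prev(s, L), "R"), HalfSite(_next(e, L), "L")),
                ),
            )
        )

    # duplications: parental runs at copy >= 2, matched to genome occurrences
    dup_positions: set[int] = set()
    ambiguous = n_plus == n_minus
    for span in _circular_runs([i for i in range(1, L + 1) if copies.get(i, 0) >= 2], L):
        segs = _span_segments(span, L)
        k = {copies[i] for i in segs}
        occs = _find_occurrences(seq, segs)
        covered = {p % n for p0, _o in occs for p in range(p0, p0 + len(segs))}
        if len(k) != 1 or len(occs) != k.pop() or len(covered) != len(occs) * len(segs):
            continue  # interleaved / non-uniform repeats: left to complex handling
        dup_positions |= covered
        orients = tuple(o for _p, o in occs)
        if len(set(orients)) == 1:
            etype = "tandem_duplication"
        elif all(orients[i] != orients[i + 1] for i in range(len(orients) - 1)):
            etype = "inverted_duplication"
        else:
            continue
        s, e = span
        novel = _duplication_junctions(etype, span, orients, L)
        records.append(
            EventRecord(etype, span, novel_junctions=novel, copies=len(occs),
                        orientation_pattern=orients)
        )

    # inversions: minority-direction runs outside duplicated regions
    if not ambiguous:
        p = 0
        visited = set()
        for p in range(n):
            if p in visited or p in dup_positions or seq[p] >= 0:
                continue
            q = p
            run = []
            while seq[q] < 0 and q not in dup_positions and q not in visited:
                visited.add(q)
                run.append(q)
                q = (q + 1) % n
                if q == p:
                    break
            ids = [abs(seq[i]) for i in run]
            # a clean inversion reads as a descending consecutive parental run
            if all(_prev(ids[i], L) == ids[i + 1] for i in range(len(ids) - 1)) and all(
                copies[i] == 1 for i in ids
            ):
                s, e = ids[-1], ids[0]
                records.append(
                    EventRecord(
                        "inversion",
                        (s, e),
                        novel_junctions=(
                            junction_pair(HalfSite(_prev(s, L), "R"), HalfSite(e, "R")),
                            junction_pair(HalfSite(s, "L"), HalfSite(_next(e, L), "L")),
                        ),
                    )
                )

    # complex: novel junctions not explained by any event endpoint
    explained = {j for r in records for j in r.novel_junctions}
    parental = reference.parental_pairs
    positions = _complex_positions(genome, parental, explained)
    for run in _contiguous_runs(positions, len(genome)):
        pairs = tuple(_adjacency_at(genome, p) for p in run)
        records.append(EventRecord("complex", None, novel_junctions=pairs))
    return records


def _find_occurrences(seq: list[int], segs: list[int]) -> list[tuple[int, int]]:
    """(start_position, orientation) of contiguous matches of the parental run."""
    n, m = len(seq), len(segs)
    occs = []
    if m > n:
        return occs
    fwd = segs
    rev = [-s for s in reversed(segs)]
    for p in range(n):
        window = [seq[(p + i) % n] for i in range(m)]
        if window == fwd:
            occs.append((p, 1))
        elif window == rev and m > 1:
            occs.append((p, -1))
        elif m == 1 and window[0] == -segs[0]:
            occs.append((p, -1))
    return occs


def _duplication_junctions(
    etype: str, span: tuple[int, int], orients: tuple[int, ...], L: int
) -> tuple[Junction, ...]:
    s, e = span
    if etype == "tandem_duplication":
        if orients[0] > 0:
            return (junction_pair(HalfSite(e, "R"), HalfSite(s, "L")),)
        return (junction_pair(HalfSite(s, "L"), HalfSite(e, "R")),)
    novel = []
    if orients[0] > 0:  # X then -X: {eR,eR} and {sL,(e+1)L}
        novel.append(junction_pair(HalfSite(e, "R"), HalfSite(e, "R")))
        novel.append(junction_pair(HalfSite(s, "L"), HalfSite(_next(e, L), "L")))
    else:  # -X then X: {sL,sL} and {(s-1)R,eR}
        novel.append(junction_pair(HalfSite(s, "L"), HalfSite(s, "L")))
        novel.append(junction_pair(HalfSite(_prev(s, L), "R"), HalfSite(e, "R")))
    return tuple(novel)


def _adjacency_at(genome: SignedCircularGenome, p: int) -> Junction:
    seq = genome.sequence
    a, b = seq[p], seq[(p + 1) % len(seq)]
    return junction_pair(
        HalfSite(abs(a), "R" if a > 0 else "L"),
        HalfSite(abs(b), "L" if b > 0 else "R"),
    )


def _complex_positions(genome, parental, explained) -> list[int]:
    out = []
    for p in range(len(genome)):
        pair = _adjacency_at(genome, p)
        if pair not in parental and pair not in explained:
            out.append(p)
    return out


def _contiguous_runs(positions: list[int], n: int) -> list[list[int]]:
    if not positions:
        return []
    member = set(positions)
    runs = []
    for p in sorted(member):
        if (p - 1) % n not in member:
            run = [p]
            while (run[-1] + 1) % n in member and len(run) < len(member):
                run.append((run[-1] + 1) % n)
            runs.append(run)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]  # wrap-around merge
    return runs


def classify_junctions(
    genome: SignedCircularGenome,
    reference: ReferenceChromosome,
    events: list[EventRecord] | None = None,
) -> dict[Junction, str]:
    """Label every distinct junction of the genome by its origin.

    Labels: parental, deletion, inversion, duplication, multiple (endpoint of
    two or more events) or complex.  The partition is exhaustive and
    exclusive: each junction receives exactly one label.
    """
    if events is None:
        events = classify_events(genome, reference)
    parental = reference.parental_pairs
    by_junction: dict[Junction, list[EventRecord]] = defaultdict(list)
    endpoint_owner: dict[HalfSite, set[int]] = defaultdict(set)
    for k, r in enumerate(events):
        if r.type == "complex":
            continue
        for j in r.novel_junctions:
            by_junction[j].append(r)
            for hs in j:
                endpoint_owner[hs].add(k)
    labels: dict[Junction, str] = {}
    for pair in genome.adjacency_multiset():
        if pair in parental:
            labels[pair] = "parental"
        elif len(by_junction.get(pair, [])) == 1:
            labels[pair] = EVENT_LABEL[by_junction[pair][0].type]
        elif len(by_junction.get(pair, [])) >= 2:
            labels[pair] = "multiple"
        else:
            owners = endpoint_owner.get(pair[0], set()) | endpoint_owner.get(pair[1], set())
            labels[pair] = "multiple" if len(owners) >= 2 else "complex"
    return labels


def event_distance(event: EventRecord, reference: ReferenceChromosome) -> int | None:
    """Parental bp span of the affected arc; undefined for complex events."""
    if event.span is None:
        return None
    lengths = reference.lengths
    return sum(lengths[i] for i in _span_segments(event.span, reference.L))


def strain_event_summary(
    events: list[EventRecord], junction_labels: dict[Junction, str]
) -> dict:
    """Per-strain tabulation of event types and junction origin labels."""
    ev = Counter(r.type for r in events)
    jn = Counter(junction_labels.values())
    return {
        "events": dict(ev),
        "junctions": dict(jn),
        "deletion_vs_inversion": (ev.get("deletion", 0), ev.get("inversion", 0)),
        "tandem_vs_inverted_duplication": (
            ev.get("tandem_duplication", 0),
            ev.get("inverted_duplication", 0),
        ),
    }
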