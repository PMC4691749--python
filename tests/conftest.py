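"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter

import pytest

from unscramble.genome import (
    ReferenceChromosome,
    Segment,
    SignedCircularGenome,
    synixr_like_reference,
)


@pytest.fixture(scope="session")
def synixr():
    """The default 43-segment circular reference."""
    return synixr_like_reference()


@pytest.fixture(scope="session")
def synixr_sequences(synixr):
    from unscramble.simulate import synthesize_segment_sequences

    return synthesize_segment_sequences(synixr, seed=11)


def small_reference(L: int, lengths: int | list[int] = 1000) -> ReferenceChromosome:
    if isinstance(lengths, int):
        lengths = [lengths] * L
    segs = [
        Segment(id=i, length_bp=lengths[i - 1], centromere=(i == 1))
        for i in range(1, L + 1)
    ]
    return ReferenceChromosome(segs)


@pytest.fixture
def ref4():
    return small_reference(4)


@pytest.fixture
def ref6():
    return small_reference(6)


# ---------------------------------------------------------------------------
# brute-force oracles


def all_signed_circular_genomes(copy_vector: dict[int, int]):
    """Every canonical signed circular sequence with the given copy numbers.

    Exhausts all orderings of the segment multiset and all sign patterns,
    deduplicated up to rotation and reflection.
    """
    multiset = [s for s, n in sorted(copy_vector.items()) for _ in range(n)]
    if not multiset:
        return set()
    out = set()
    # fix the first element to kill most rotations cheaply; canonical() handles the rest
    first = multiset[0]
    rest = multiset[1:]
    for perm in set(itertools.permutations(rest)):
        for signs in itertools.product((1, -1), repeat=len(rest) + 1):
            seq = [first * signs[0]] + [p * s for p, s in zip(perm, signs[1:])]
            out.add(SignedCircularGenome(seq).canonical())
    return out


def brute_force_solutions(evidence: Counter, copy_vector: dict[int, int]):
    """All canonical genomes whose adjacency multiset equals the evidence."""
    return {
        g
        for g in all_signed_circular_genomes(copy_vector)
        if g.adjacency_multiset() == evidence
    }
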