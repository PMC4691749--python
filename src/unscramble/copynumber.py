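"""Integer copy-number inference from strain-vs-reference read depth.

The observed depth of segment i in strain t is D_ti, and D_ri in the
(unrearranged) reference strain.  Segments with depth below a threshold are
marked deleted and fixed at copy 0.  For the remainder, copy numbers are
refined iteratively: using any other retained segment j as an internal
calibrator,

    M_ij = (N_tj * D_rj / D_tj) * (D_ti / D_ri)

so the overall depth ratio between the two libraries cancels.  Each row of
candidate estimates EM_i is summarized by its most frequent rounded value
(ties to the larger value), and the per-segment coefficient of variation
CV_i = stdev(EM_i)/mean(EM_i), computed on the unrounded estimates, serves as
the convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DepthTable", "CopyNumberEstimate", "mark_deleted", "estimate_copy_numbers"]


@dataclass
class DepthTable:
    segment_ids: np.ndarray
    depth_strain: np.ndarray
    depth_reference: np.ndarray

    def __post_init__(self):
        self.segment_ids = np.asarray(self.segment_ids, dtype=int)
        self.depth_strain = np.asarray(self.depth_strain, dtype=float)
        self.depth_reference = np.asarray(self.depth_reference, dtype=float)
        if not (
            len(self.segment_ids) == len(self.depth_strain) == len(self.depth_reference)
        ):
            raise ValueError("depth table columns must have equal length")
        if np.any(self.depth_strain < 0):
            raise ValueError("strain depths must be non-negative")
        if np.any(self.depth_reference <= 0):
            raise ValueError("reference depths must be strictly positive")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("segment_id\tdepth_strain\tdepth_reference\n")
            for i, dt, dr in zip(self.segment_ids, self.depth_strain, self.depth_reference):
                fh.write(f"{i}\t{dt:.6g}\t{dr:.6g}\n")

    @classmethod
    def from_tsv(cls, path) -> "DepthTable":
        ids, dt, dr = [], [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                ids.append(int(row["segment_id"]))
                dt.append(float(row["depth_strain"]))
                dr.append(float(row["depth_reference"]))
        return cls(np.array(ids), np.array(dt), np.array(dr))


@dataclass
class CopyNumberEstimate:
    segment_ids: np.ndarray
    copy_numbers: np.ndarray  # integer, 0 for deleted
    cv: np.ndarray  # per-segment CV of the final estimate vector (nan if deleted)
    deleted: np.ndarray  # boolean mask
    converged: bool
    iterations: int

    def as_dict(self) -> dict[int, int]:
        return {int(i): int(n) for i, n in zip(self.segment_ids, self.copy_numbers)}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("segment_id\tcopy_number\tcv\tdeleted\n")
            for i, n, cv, d in zip(self.segment_ids, self.copy_numbers, self.cv, self.deleted):
                fh.write(f"{i}\t{n}\t{'' if np.isnan(cv) else f'{cv:.6g}'}\t{int(d)}\n")


def mark_deleted(depths: DepthTable, threshold: float = 5.0) -> np.ndarray:
    """Deletion mask: True where the strain depth is strictly below threshold."""
    return depths.depth_strain < threshold


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def estimate_copy_numbers(
    depths: DepthTable,
    epsilon: float = 0.25,
    max_iter: int = 100,
    deletion_threshold: float = 5.0,
    deleted_mask: np.ndarray | None = None,
    update: str = "mode",
) -> CopyNumberEstimate:
    """Iterative self-consistent integer copy-number estimation.

    ``update="mode"`` takes the most frequent rounded candidate per row (ties
    to the larger value); ``update="max"`` takes the row maximum.  Estimates
    are invariant under a global rescaling of the strain depths.
    """
    if update not in ("mode", "max"):
        raise ValueError("update must be 'mode' or 'max'")
    deleted = (
        np.asarray(deleted_mask, dtype=bool)
        if deleted_mask is not None
        else mark_deleted(depths, deletion_threshold)
    )
    retained = ~deleted
    if retained.sum() < 2:
        raise ValueError("need at least two retained segments")
    dt = depths.depth_strain[retained]
    dr = depths.depth_reference[retained]
    if np.any(dt <= 0):
        raise ValueError("zero strain depth on a retained segment")
    m = retained.sum()
    n = np.ones(m, dtype=int)
    cv = np.full(m, np.inf)
    converged = False
    it = 0
    off_diag = ~np.eye(m, dtype=bool)
    for it in range(1, max_iter + 1):
        # M[i, j] = (N_j * Dr_j / Dt_j) * (Dt_i / Dr_i), j used as calibrator
        col = n * dr / dt
        row = dt / dr
        M = row[:, None] * col[None, :]
        cv_new = np.empty(m)
        n_new = np.empty(m, dtype=int)
        for i in range(m):
            # a zero-copy calibrator carries no information about the depth
            # ratio k, so only currently-positive segments vote
            use = off_diag[i] & (n > 0)
            em = M[i, use] if use.any() else M[i, off_diag[i]]
            mean = em.mean()
            cv_new[i] = em.std() / mean if mean > 0 else np.inf
            # retained segments are present: depth above the deletion
            # threshold implies at least one copy
            cand = np.maximum(_round_half_up(em), 1)
            if update == "max":
                n_new[i] = cand.max()
            else:
                values, counts = np.unique(cand, return_counts=True)
                best = counts.max()
                n_new[i] = values[counts == best].max()  # ties -> larger value
        done = bool(np.all(cv_new < epsilon))
        stable = bool(np.all(n_new == n) and np.allclose(cv_new, cv))
        n, cv = n_new, cv_new
        if done:
            converged = True
            break
        if stable:
            break
    full_n = np.zeros(len(depths.segment_ids), dtype=int)
    full_n[retained] = n
    full_cv = np.full(len(depths.segment_ids), np.nan)
    full_cv[retained] = cv
    return CopyNumberEstimate(
        segment_ids=depths.segment_ids,
        copy_numbers=full_n,
        cv=full_cv,
        deleted=deleted,
        converged=converged,
        iterations=it,
    )
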