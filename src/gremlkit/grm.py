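"""Genomic relationship matrix construction and relatedness-ceiling pruning.

The GRM estimator is the per-SNP standardized form used by GCTA
(Yang-style), averaging over pairwise-complete SNPs with allele
frequencies re-estimated from the sample:

* off-diagonal (j, k):  mean over SNPs i non-missing in both of
  ``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
* diagonal (j):  ``1 + mean_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2]
  / (2 p_i (1 - p_i))``

Monomorphic SNPs contribute to no entry.  Pruning enforces a relatedness
ceiling by greedy max-degree elimination: repeatedly remove the
individual in the largest number of above-ceiling pairs (ties broken by
removing the later individual in input order) until no pair exceeds the
ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GRM, GenotypeMatrix, IdPair
from .errors import DegenerateDataError, ValidationError


def compute_grm(gm: GenotypeMatrix) -> GRM:
    """Build the GRM from a genotype matrix (see module docstring)."""
    if gm.n_individuals < 2:
        raise ValidationError("GRM needs at least 2 individuals")
    x = gm.dosages_float()  # n x m, NaN at missing
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DegenerateDataError("no polymorphic SNPs: GRM undefined")
    x = x[:, poly]
    p = p[poly]
    denom = 2.0 * p * (1.0 - p)

    called = np.isfinite(x)
    w = np.where(called, (x - 2.0 * p) / np.sqrt(denom), 0.0)
    num = w @ w.T
    counts = called.astype(np.float64) @ called.astype(np.float64).T
    counts = np.rint(counts).astype(np.int64)
    n = gm.n_individuals
    off_undefined = (counts == 0) & ~np.eye(n, dtype=bool)
    if off_undefined.any():
        j, k = np.argwhere(off_undefined)[0]
        raise DegenerateDataError(
            f"individuals {gm.individual_ids[j]} and {gm.individual_ids[k]} "
            "share no non-missing SNPs; their relatedness is undefined")

    values = num / np.maximum(counts, 1)
    # diagonal uses the distinct formula (captures inbreeding, not just
    # the squared standardized dosage)
    diag_terms = np.where(
        called, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, 0.0)
    diag_counts = called.sum(axis=1)
    if (diag_counts == 0).any():
        j = int(np.argmax(diag_counts == 0))
        raise DegenerateDataError(
            f"individual {gm.individual_ids[j]} has no called polymorphic SNPs")
    np.fill_diagonal(values, 1.0 + diag_terms.sum(axis=1) / diag_counts)
    np.fill_diagonal(counts, diag_counts)
    # enforce exact symmetry against BLAS rounding asymmetry
    values = np.tril(values) + np.tril(values, -1).T
    return GRM(list(gm.individual_ids), values, counts)


@dataclass
class PruneResult:
    """Outcome of relatedness-ceiling pruning.

    ``removed_ids`` lists ``(id_pair, step)`` in removal order, step
    counting from 0.  Among retained individuals no off-diagonal GRM
    value exceeds ``cutoff``.
    """

    retained_ids: list[IdPair]
    removed_ids: list[tuple[IdPair, int]]
    cutoff: float

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def prune_by_relatedness(grm: GRM, cutoff: float) -> PruneResult:
    """Greedy max-degree elimination until no pair exceeds ``cutoff``."""
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be > 0, got {cutoff}")
    n = grm.n
    over = grm.values > cutoff
    np.fill_diagonal(over, False)
    active = np.ones(n, dtype=bool)
    degree = over.sum(axis=1)
    removed: list[tuple[IdPair, int]] = []
    step = 0
    while True:
        dmax = degree[active].max() if active.any() else 0
        if dmax == 0:
            break
        candidates = np.flatnonzero(active & (degree == dmax))
        victim = int(candidates[-1])  # tie: later input index goes
        active[victim] = False
        degree[over[victim]] -= 1
        degree[victim] = 0
        over[victim, :] = False
        over[:, victim] = False
        removed.append((grm.individual_ids[victim], step))
        step += 1
    retained = [grm.individual_ids[i] for i in np.flatnonzero(active)]
    return PruneResult(retained, removed, float(cutoff))
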