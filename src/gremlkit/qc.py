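"""SNP and individual quality control.

Filters mirror the conventional PLINK pipeline for SNP-array data:
individual missingness first, then — with per-SNP statistics recomputed
on the surviving individuals — SNP call rate, minor allele frequency,
and a Hardy-Weinberg exact test.  Defaults are the usual array-QC
thresholds (MAF >= 5%, HWE p >= 1e-3, SNP call rate >= 90%, individual
missingness <= 10%); all comparisons that remove an item are strict.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

from .data import MISSING, GenotypeMatrix
from .errors import DegenerateDataError, ValidationError

Counts = tuple[int, int, int]


@dataclass
class SNPStats:
    """Per-SNP QC statistics on non-missing calls."""

    snp_id: str
    allele_freq_a2: float
    call_rate: float
    hwe_p: float
    counts: Counts


@dataclass
class QCReport:
    """Bookkeeping for one :func:`apply_qc` run.

    ``removal_reasons`` maps a removed individual's ``"fid:iid"`` or a
    removed SNP's id to its single primary reason tag
    (``mind | geno | maf | hwe``).
    """

    n_snps_in: int
    n_snps_out: int
    n_individuals_in: int
    n_individuals_out: int
    removal_reasons: dict[str, str] = field(default_factory=dict)

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tag in self.removal_reasons.values():
            out[tag] = out.get(tag, 0) + 1
        return out


def _validate_counts(counts: Counts) -> Counts:
    a, b, c = (int(v) for v in counts)
    if a < 0 or b < 0 or c < 0:
        raise ValidationError(f"negative genotype counts {counts}")
    return a, b, c


def allele_frequency(counts: Counts) -> float:
    """Frequency of allele a2 from (hom_a1, het, hom_a2) counts."""
    a, b, c = _validate_counts(counts)
    total = a + b + c
    if total == 0:
        raise DegenerateDataError("allele frequency undefined: no calls")
    return (b + 2 * c) / (2 * total)


@functools.lru_cache(maxsize=4096)
def _hwe_weights(n: int, n_rare: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Integer weights proportional to P(het = h | n, allele counts).

    Conditional on the allele counts, P(h) is proportional to the
    multinomial coefficient n! / (x! h! z!) times 2^h, with
    x = (n_rare - h)/2 rare homozygotes and z = (n_common - h)/2 common
    homozygotes.  Integer weights keep the <=-comparison of the exact
    test free of rounding.
    """
    n_common = 2 * n - n_rare
    hs, ws = [], []
    for h in range(n_rare % 2, n_rare + 1, 2):
        x = (n_rare - h) // 2
        z = (n_common - h) // 2
        if z < 0:
            continue
        w = (math.factorial(n) // (math.factorial(x) * math.factorial(h)
                                   * math.factorial(z))) * (1 << h)
        hs.append(h)
        ws.append(w)
    return tuple(hs), tuple(ws)


def hwe_exact_test(counts: Counts) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote count whose probability does not exceed that of
    the observed configuration (the standard exact test; no mid-p).
    Exact integer arithmetic is used up to n = 500; beyond that a
    log-space evaluation with a tiny tie tolerance takes over.
    """
    a, b, c = _validate_counts(counts)
    n = a + b + c
    if n == 0:
        raise ValidationError("HWE test undefined: no calls")
    n_rare = min(2 * a + b, 2 * c + b)
    if n_rare <= 1:
        return 1.0  # a single configuration (or one rare allele copy only)
    if n <= 500:
        hs, ws = _hwe_weights(n, n_rare)
        w_obs = ws[hs.index(b)]
        total = sum(ws)
        tail = sum(w for w in ws if w <= w_obs)
        return float(min(Fraction(tail, total), 1))
    # large-n path: log multinomial weights, tolerant tie comparison
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    x = (n_rare - hs) // 2
    z = (2 * n - n_rare - hs) // 2
    logw = (gammaln(n + 1) - gammaln(x + 1) - gammaln(hs + 1)
            - gammaln(z + 1) + hs * math.log(2.0))
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[list(hs).index(b)]
    p = w[w <= w_obs * (1 + 1e-12)].sum() / w.sum()
    return float(min(p, 1.0))


def genotype_counts(dosage_column: np.ndarray) -> Counts:
    """(hom_a1, het, hom_a2) counts, ignoring missing calls."""
    d = np.asarray(dosage_column)
    return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def snp_stats(gm: GenotypeMatrix) -> list[SNPStats]:
    """Per-SNP statistics for every SNP of the matrix."""
    out = []
    n = gm.n_individuals
    for i, snp in enumerate(gm.snps):
        counts = genotype_counts(gm.dosages[:, i])
        called = sum(counts)
        if called == 0:
            out.append(SNPStats(snp.snp_id, np.nan, 0.0, 1.0, counts))
            continue
        out.append(SNPStats(
            snp.snp_id,
            allele_frequency(counts),
            called / n,
            hwe_exact_test(counts),
            counts,
        ))
    return out


def apply_qc(gm: GenotypeMatrix, maf_min: float = 0.05,
             hwe_p_min: float = 1e-3, snp_call_rate_min: float = 0.90,
             ind_missing_max: float = 0.10
             ) -> tuple[GenotypeMatrix, QCReport]:
    """Filter individuals then SNPs; returns the surviving matrix and report.

    Order: individuals with missing fraction > ``ind_missing_max`` are
    dropped first; per-SNP statistics are recomputed on the survivors;
    SNPs are then removed for call rate < ``snp_call_rate_min``, else
    MAF < ``maf_min`` (MAF folded as min(f, 1-f)), else HWE
    p < ``hwe_p_min``.  Each removed item carries exactly one reason tag.
    """
    if gm.n_individuals == 0 or gm.n_snps == 0:
        raise ValidationError("empty genotype matrix")
    report = QCReport(gm.n_snps, 0, gm.n_individuals, 0)

    miss_frac = gm.missing_mask().mean(axis=1)
    keep_ind = miss_frac <= ind_missing_max
    for j in np.flatnonzero(~keep_ind):
        fid, iid = gm.individual_ids[j]
        report.removal_reasons[f"{fid}:{iid}"] = "mind"
    if not keep_ind.any():
        raise DegenerateDataError("all individuals removed by missingness filter")
    sub = gm.subset(individuals=np.flatnonzero(keep_ind))

    keep_snp = np.ones(sub.n_snps, dtype=bool)
    for i, st in enumerate(snp_stats(sub)):
        if st.call_rate < snp_call_rate_min:
            keep_snp[i] = False
            report.removal_reasons[st.snp_id] = "geno"
        elif not np.isnan(st.allele_freq_a2) and \
                min(st.allele_freq_a2, 1 - st.allele_freq_a2) < maf_min:
            keep_snp[i] = False
            report.removal_reasons[st.snp_id] = "maf"
        elif st.hwe_p < hwe_p_min:
            keep_snp[i] = False
            report.removal_reasons[st.snp_id] = "hwe"
    if not keep_snp.any():
        raise DegenerateDataError("all SNPs removed by QC")
    out = sub.subset(snps=np.flatnonzero(keep_snp))
    report.n_snps_out = out.n_snps
    report.n_individuals_out = out.n_individuals
    return out, report
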