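"""Relatedness-ceiling sensitivity sweep.

For each ceiling the GRM is pruned so that no retained pair exceeds the
ceiling, phenotypes are subset by ID intersection, and univariate GREML
is fitted per trait plus bivariate GREML per trait pair.  A ``None``
ceiling runs the full data.  Rows that retain fewer than ``min_n``
individuals are flagged skipped (small sub-populations do not support
REML); fit failures are recorded per cell, never fatal to the sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .bivariate import fit_greml_bivariate
from .data import GRM, PhenotypeTable
from .errors import GremlkitError, ValidationError
from .grm import prune_by_relatedness
from .univariate import RemlSettings, fit_greml_univariate

logger = logging.getLogger(__name__)


@dataclass
class FitCell:
    estimate: float
    se: float
    converged: bool
    note: str = ""


@dataclass
class SweepRow:
    cutoff: float | None  # None = full data
    n_retained: int
    h2: dict[str, FitCell] = field(default_factory=dict)
    r_g: dict[tuple[str, str], FitCell] = field(default_factory=dict)
    r_p: dict[tuple[str, str], FitCell] = field(default_factory=dict)
    skipped: bool = False
    note: str = ""


@dataclass
class SweepResult:
    rows: list[SweepRow]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (cutoff, quantity)."""
        records = []
        for row in self.rows:
            base = {"cutoff": np.inf if row.cutoff is None else row.cutoff,
                    "n_retained": row.n_retained, "skipped": row.skipped}
            if row.skipped:
                records.append({**base, "quantity": "n", "item": "",
                                "estimate": np.nan, "se": np.nan,
                                "converged": False, "note": row.note})
                continue
            for trait, cell in row.h2.items():
                records.append({**base, "quantity": "h2", "item": trait,
                                "estimate": cell.estimate, "se": cell.se,
                                "converged": cell.converged, "note": cell.note})
            for pair, cell in row.r_g.items():
                records.append({**base, "quantity": "rG",
                                "item": f"{pair[0]}-{pair[1]}",
                                "estimate": cell.estimate, "se": cell.se,
                                "converged": cell.converged, "note": cell.note})
            for pair, cell in row.r_p.items():
                records.append({**base, "quantity": "rP",
                                "item": f"{pair[0]}-{pair[1]}",
                                "estimate": cell.estimate, "se": cell.se,
                                "converged": cell.converged, "note": cell.note})
        return pd.DataFrame.from_records(records)


def _sort_key(cutoff: float | None) -> float:
    return np.inf if cutoff is None else float(cutoff)


def _fit_row(grm_sub: GRM, phen: PhenotypeTable, traits: list[str],
             pairs: list[tuple[str, str]], settings: RemlSettings,
             cutoff: float | None) -> SweepRow:
    row = SweepRow(cutoff=cutoff, n_retained=grm_sub.n)
    common = [p for p in grm_sub.individual_ids
              if p in set(phen.individual_ids)]
    phen_lookup = {p: i for i, p in enumerate(phen.individual_ids)}
    n_unmatched = grm_sub.n - len(common)
    if n_unmatched:
        logger.info("cutoff %s: %d GRM individuals lack phenotype records",
                    cutoff, n_unmatched)
    for trait in traits:
        idx_p = np.array([phen_lookup[p] for p in common], dtype=np.int64)
        y = phen.values[idx_p, phen.trait_names.index(trait)]
        ok = np.isfinite(y)
        ids_t = [common[i] for i in np.flatnonzero(ok)]
        try:
            g = grm_sub.subset(grm_sub.index_of(ids_t))
            fit = fit_greml_univariate(y[ok], g, settings=settings)
            row.h2[trait] = FitCell(fit.h2, fit.se_h2, fit.converged)
            logger.info("cutoff %s trait %s: h2=%.4f (%.4f) logL=%.4f it=%d",
                        cutoff, trait, fit.h2, fit.se_h2, fit.loglik,
                        fit.n_iterations)
            for it, ll in enumerate(fit.loglik_trace):
                logger.debug("cutoff %s trait %s iter %d logL %.6f",
                             cutoff, trait, it, ll)
        except (GremlkitError, np.linalg.LinAlgError) as e:
            row.h2[trait] = FitCell(np.nan, np.nan, False, note=str(e))
            logger.warning("cutoff %s trait %s failed: %s", cutoff, trait, e)
    for t1, t2 in pairs:
        idx_p = np.array([phen_lookup[p] for p in common], dtype=np.int64)
        y1 = phen.values[idx_p, phen.trait_names.index(t1)]
        y2 = phen.values[idx_p, phen.trait_names.index(t2)]
        ok = np.isfinite(y1) & np.isfinite(y2)  # complete-case pair analysis
        ids_t = [common[i] for i in np.flatnonzero(ok)]
        try:
            g = grm_sub.subset(grm_sub.index_of(ids_t))
            fit = fit_greml_bivariate(y1[ok], y2[ok], g, settings=settings)
            row.r_g[(t1, t2)] = FitCell(fit.r_g, fit.se_r_g, fit.converged)
            row.r_p[(t1, t2)] = FitCell(fit.r_p, fit.se_r_p, fit.converged)
            logger.info("cutoff %s pair %s-%s: rG=%.4f (%.4f) rP=%.4f it=%d",
                        cutoff, t1, t2, fit.r_g, fit.se_r_g, fit.r_p,
                        fit.n_iterations)
            for it, ll in enumerate(fit.loglik_trace):
                logger.debug("cutoff %s pair %s-%s iter %d logL %.6f",
                             cutoff, t1, t2, it, ll)
        except (GremlkitError, np.linalg.LinAlgError) as e:
            row.r_g[(t1, t2)] = FitCell(np.nan, np.nan, False, note=str(e))
            row.r_p[(t1, t2)] = FitCell(np.nan, np.nan, False, note=str(e))
            logger.warning("cutoff %s pair %s-%s failed: %s", cutoff, t1, t2, e)
    return row


def run_sweep(grm: GRM, phenotypes: PhenotypeTable,
              cutoffs: list[float | None], traits: list[str] | None = None,
              pairs: list[tuple[str, str]] | None = None,
              settings: RemlSettings | None = None,
              min_n: int = 50) -> SweepResult:
    """Prune-and-fit across relatedness ceilings (``None`` = full data)."""
    if not cutoffs:
        raise ValidationError("cutoffs must be non-empty")
    settings = settings or RemlSettings()
    if traits is None:
        traits = list(phenotypes.trait_names)
    unknown = set(traits) - set(phenotypes.trait_names)
    if unknown:
        raise ValidationError(f"unknown traits {sorted(unknown)}")
    if pairs is None:
        pairs = list(combinations(traits, 2))
    for t1, t2 in pairs:
        if t1 not in phenotypes.trait_names or t2 not in phenotypes.trait_names:
            raise ValidationError(f"unknown trait pair ({t1}, {t2})")

    rows = []
    for cutoff in sorted(cutoffs, key=_sort_key):
        if cutoff is None:
            grm_sub = grm
        else:
            pruned = prune_by_relatedness(grm, cutoff)
            grm_sub = grm.subset(grm.index_of(pruned.retained_ids))
        if grm_sub.n < min_n:
            rows.append(SweepRow(cutoff=cutoff, n_retained=grm_sub.n,
                                 skipped=True,
                                 note=f"retained {grm_sub.n} < min_n {min_n}"))
            logger.warning("cutoff %s skipped: retained %d < %d",
                           cutoff, grm_sub.n, min_n)
            continue
        rows.append(_fit_row(grm_sub, phenotypes, traits, pairs, settings,
                             cutoff))
    return SweepResult(rows)


def summarize_grm(grm: GRM) -> dict:
    """Quantiles and histograms of the diagonal and off-diagonal values."""
    diag = np.diag(grm.values)
    off = grm.offdiagonal()
    qs = [0.0, 0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99, 1.0]

    def _summary(x: np.ndarray) -> dict:
        if x.size == 0:
            return {"n": 0}
        hist, edges = np.histogram(x, bins=50)
        return {"n": int(x.size), "mean": float(x.mean()),
                "sd": float(x.std()),
                "min": float(x.min()), "max": float(x.max()),
                "quantiles": dict(zip(qs, np.quantile(x, qs).tolist())),
                "histogram": {"counts": hist.tolist(),
                              "edges": edges.tolist()}}

    return {"diagonal": _summary(diag), "offdiagonal": _summary(off)}


def plot_sweep(result: SweepResult, path: str) -> None:
    """Two-panel plot: h2 per trait vs ceiling, and retained n vs ceiling."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.to_frame()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    h2 = frame[(frame.quantity == "h2") & np.isfinite(frame.cutoff)]
    for trait, sub in h2.groupby("item"):
        ax1.errorbar(sub.cutoff, sub.estimate, yerr=sub.se, marker="o",
                     label=trait, capsize=2)
    ax1.set_xlabel("relatedness ceiling")
    ax1.set_ylabel("$h^2$")
    ax1.legend(fontsize=7)
    sizes = frame[np.isfinite(frame.cutoff)].groupby("cutoff")[
        "n_retained"].first()
    ax2.plot(sizes.index, sizes.values, marker="s")
    ax2.set_xlabel("relatedness ceiling")
    ax2.set_ylabel("retained individuals")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
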