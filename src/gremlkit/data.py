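"""Core containers: genotype matrices, phenotype tables, and genomic
relationship matrices (GRMs).

Dosages count copies of allele ``a2`` and live in ``{0, 1, 2, MISSING}``.
The missing sentinel is a dedicated code (never 0, which is a valid
dosage).  Individuals are identified by ``(family_id, individual_id)``
string pairs throughout, matching the PLINK/GCTA file dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Sentinel for a missing dosage call.
MISSING = -1

IdPair = tuple[str, str]


def _check_unique_ids(ids: list[IdPair], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} IDs")


@dataclass
class SNPInfo:
    """Marker metadata mirroring the PLINK .map columns plus alleles."""

    snp_id: str
    chromosome: str = "0"
    position: int = 0
    allele_a1: str = "A"
    allele_a2: str = "B"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"SNP {self.snp_id}: negative position")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosage matrix.

    ``dosages[j, i]`` is the number of copies of ``snps[i].allele_a2``
    carried by individual ``j``, or :data:`MISSING`.
    """

    individual_ids: list[IdPair]
    snps: list[SNPInfo]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [tuple(p) for p in self.individual_ids]
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValidationError(
                f"{len(self.individual_ids)} IDs but {n} dosage rows")
        if m != len(self.snps):
            raise ValidationError(f"{len(self.snps)} SNPs but {m} dosage columns")
        _check_unique_ids(self.individual_ids, "individual")
        snp_ids = [s.snp_id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("duplicate SNP IDs")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            j, i = np.argwhere(~ok)[0]
            raise ValidationError(
                f"invalid dosage {self.dosages[j, i]} at individual {j}, SNP {i}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with NaN at missing calls."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        return x

    def subset(self, individuals: np.ndarray | list[int] | None = None,
               snps: np.ndarray | list[int] | None = None) -> "GenotypeMatrix":
        """Positional subset along either axis (order preserved)."""
        ind = np.arange(self.n_individuals) if individuals is None \
            else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in ind],
            [self.snps[i] for i in snp],
            self.dosages[np.ix_(ind, snp)],
        )


@dataclass
class PhenotypeTable:
    """Trait records (and optional fixed-effect covariates) per individual.

    ``values`` is n x t with NaN for missing records; ``covariates`` is an
    optional n x c fixed-effects design (an intercept is always added by
    the REML fitters, so it holds covariates only).
    """

    individual_ids: list[IdPair]
    trait_names: list[str]
    values: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [tuple(p) for p in self.individual_ids]
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        n = len(self.individual_ids)
        if self.values.shape[0] != n:
            raise ValidationError(
                f"{n} IDs but {self.values.shape[0]} phenotype rows")
        if self.values.shape[1] != len(self.trait_names):
            raise ValidationError("trait count does not match value columns")
        _check_unique_ids(self.individual_ids, "individual")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(
                np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != n:
                raise ValidationError("covariate rows do not match IDs")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def trait(self, name: str) -> np.ndarray:
        try:
            i = self.trait_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown trait {name!r}") from None
        return self.values[:, i]

    def subset(self, indices: np.ndarray | list[int]) -> "PhenotypeTable":
        idx = np.asarray(indices)
        return PhenotypeTable(
            [self.individual_ids[i] for i in idx],
            list(self.trait_names),
            self.values[idx],
            None if self.covariates is None else self.covariates[idx],
        )


@dataclass
class GRM:
    """Genomic relationship matrix with per-pair SNP support counts.

    Diagonal entries estimate 1 + genomic inbreeding; off-diagonals
    estimate twice the kinship between the pair.  ``pair_snp_counts``
    records how many SNPs contributed to each entry.
    """

    individual_ids: list[IdPair]
    values: np.ndarray
    pair_snp_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.individual_ids = [tuple(p) for p in self.individual_ids]
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"GRM shape {self.values.shape} != ({n},{n})")
        _check_unique_ids(self.individual_ids, "individual")
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("GRM values are not symmetric")
        if self.pair_snp_counts is None:
            self.pair_snp_counts = np.zeros((n, n), dtype=np.int64)
        else:
            self.pair_snp_counts = np.ascontiguousarray(
                self.pair_snp_counts, dtype=np.int64)
            if self.pair_snp_counts.shape != (n, n):
                raise ValidationError("pair_snp_counts shape mismatch")
            if not np.array_equal(self.pair_snp_counts, self.pair_snp_counts.T):
                raise ValidationError("pair_snp_counts not symmetric")
            if (self.pair_snp_counts < 0).any():
                raise ValidationError("negative pair_snp_counts")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal values as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def index_of(self, ids: list[IdPair]) -> np.ndarray:
        """Positions of the given IDs in this GRM's ordering."""
        lookup = {p: i for i, p in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[tuple(p)] for p in ids], dtype=np.int64)
        except KeyError as e:
            raise ValidationError(f"ID {e.args[0]} absent from GRM") from None

    def subset(self, indices: np.ndarray | list[int]) -> "GRM":
        idx = np.asarray(indices)
        return GRM(
            [self.individual_ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.pair_snp_counts[np.ix_(idx, idx)],
        )
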