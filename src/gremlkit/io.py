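"""Readers and writers for the field's text and binary formats.

Supported formats
-----------------
* PLINK text ``.ped``/``.map`` pairs (whitespace-delimited, ``0 0`` =
  missing genotype).
* A simple dosage TSV: header ``FID IID snp1 snp2 ...``; body values in
  ``{0, 1, 2}`` or ``NA`` for missing.
* The GCTA binary GRM triplet ``prefix.grm.bin`` / ``prefix.grm.N.bin`` /
  ``prefix.grm.id``: little-endian float32, lower triangle including the
  diagonal, row-major — entry order (0,0), (1,0), (1,1), (2,0), ...
* ``.phen``-style phenotype tables: ``FID IID trait1 [trait2 ...]`` with
  ``NA`` or ``-9`` for missing.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .data import GRM, MISSING, GenotypeMatrix, PhenotypeTable, SNPInfo
from .errors import FormatError, ParseError, ValidationError

_MISSING_TOKENS = {"NA", "na", "NaN", "nan", "-9", str(MISSING)}


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | os.PathLike, format: str | None = None
                   ) -> GenotypeMatrix:
    """Read genotypes from a ``.ped``/``.map`` pair or a dosage TSV.

    ``format`` is ``"ped"`` or ``"dosage_tsv"``; when omitted it is
    inferred from the file suffix (``.ped`` vs anything else).
    """
    path = Path(path)
    if format is None:
        format = "ped" if path.suffix == ".ped" else "dosage_tsv"
    if format == "ped":
        return _read_ped(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[0].upper() != "FID":
            raise ParseError(f"{path}: line 1: expected header 'FID IID snp...'")
        snp_ids = header[2:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != len(snp_ids) + 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(snp_ids) + 2} "
                    f"fields, got {len(fields)}")
            ids.append((fields[0], fields[1]))
            row = []
            for tok in fields[2:]:
                if tok in _MISSING_TOKENS:
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise ParseError(
                        f"{path}: line {lineno}: invalid dosage {tok!r}")
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no genotype rows")
    snps = [SNPInfo(s) for s in snp_ids]
    return GenotypeMatrix(ids, snps, np.array(rows, dtype=np.int8))


def _read_map(path: Path) -> list[SNPInfo]:
    snps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise ParseError(f"{path}: line {lineno}: expected 3 or 4 fields")
            chrom, snp_id = fields[0], fields[1]
            pos = int(fields[-1])
            snps.append(SNPInfo(snp_id, chrom, max(pos, 0)))
    return snps


def _read_ped(path: Path) -> GenotypeMatrix:
    """Read a .ped with its companion .map.

    Alleles per SNP are taken from the data: the two observed alleles
    sorted ascending become (a1, a2) and dosages count copies of a2.  A
    SNP where only one allele is observed gets a2 = that allele (all
    called dosages 2).
    """
    map_path = path.with_suffix(".map")
    snps = _read_map(map_path)
    m = len(snps)
    ids, allele_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"for {m} SNPs, got {len(fields)}")
            ids.append((fields[0], fields[1]))
            allele_rows.append(fields[6:])
    if not ids:
        raise ParseError(f"{path}: no individuals")
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), m, 2)
    dosages = np.full((len(ids), m), MISSING, dtype=np.int8)
    for i in range(m):
        col = alleles[:, i, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ParseError(
                f"{path}: SNP {snps[i].snp_id}: more than two alleles "
                f"{observed}")
        if len(observed) == 2:
            snps[i].allele_a1, snps[i].allele_a2 = observed
        elif len(observed) == 1:
            snps[i].allele_a1, snps[i].allele_a2 = "0", observed[0]
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        a2 = snps[i].allele_a2
        dosages[called, i] = ((col[called, 0] == a2).astype(np.int8)
                              + (col[called, 1] == a2).astype(np.int8))
    return GenotypeMatrix(ids, snps, dosages)


def write_genotypes(gm: GenotypeMatrix, path: str | os.PathLike,
                    format: str | None = None) -> None:
    """Write genotypes as a dosage TSV or a ``.ped``/``.map`` pair."""
    path = Path(path)
    if format is None:
        format = "ped" if path.suffix == ".ped" else "dosage_tsv"
    if format == "dosage_tsv":
        with open(path, "w") as fh:
            fh.write("FID\tIID\t" + "\t".join(gm.snp_ids) + "\n")
            for (fid, iid), row in zip(gm.individual_ids, gm.dosages):
                toks = ["NA" if d == MISSING else str(int(d)) for d in row]
                fh.write(f"{fid}\t{iid}\t" + "\t".join(toks) + "\n")
        return
    if format != "ped":
        raise ValidationError(f"unknown genotype format {format!r}")
    with open(path.with_suffix(".map"), "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(path, "w") as fh:
        for (fid, iid), row in zip(gm.individual_ids, gm.dosages):
            toks = [fid, iid, "0", "0", "0", "-9"]
            for s, d in zip(gm.snps, row):
                a1 = s.allele_a1 if s.allele_a1 != "0" else "A"
                if d == MISSING:
                    toks += ["0", "0"]
                elif d == 0:
                    toks += [a1, a1]
                elif d == 1:
                    toks += [a1, s.allele_a2]
                else:
                    toks += [s.allele_a2, s.allele_a2]
            fh.write(" ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet


def _grm_paths(prefix: str | os.PathLike) -> tuple[Path, Path, Path]:
    prefix = str(prefix)
    return (Path(prefix + ".grm.bin"), Path(prefix + ".grm.N.bin"),
            Path(prefix + ".grm.id"))


def read_grm_gcta(prefix: str | os.PathLike) -> GRM:
    """Read a GCTA binary GRM triplet (``.grm.bin/.grm.N.bin/.grm.id``)."""
    bin_path, n_path, id_path = _grm_paths(prefix)
    for p in (bin_path, n_path, id_path):
        if not p.exists():
            raise FileNotFoundError(f"missing GRM companion file {p}")
    ids = []
    with open(id_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ParseError(f"{id_path}: line {lineno}: expected FID IID")
            ids.append((fields[0], fields[1]))
    n = len(ids)
    n_elem = n * (n + 1) // 2
    raw = np.fromfile(bin_path, dtype="<f4")
    if raw.size != n_elem:
        raise FormatError(
            f"{bin_path}: {raw.size} float32 values but .grm.id lists "
            f"{n} individuals (expected {n_elem})")
    raw_n = np.fromfile(n_path, dtype="<f4")
    if raw_n.size != n_elem:
        raise FormatError(
            f"{n_path}: {raw_n.size} float32 values, expected {n_elem}")
    il = np.tril_indices(n)
    values = np.zeros((n, n))
    values[il] = raw.astype(np.float64)
    values[(il[1], il[0])] = values[il]
    counts = np.zeros((n, n))
    counts[il] = raw_n.astype(np.float64)
    counts[(il[1], il[0])] = counts[il]
    return GRM(ids, values, np.rint(counts).astype(np.int64))


def write_grm_gcta(grm: GRM, prefix: str | os.PathLike) -> None:
    """Write the GCTA triplet; values are quantized to float32 on disk."""
    bin_path, n_path, id_path = _grm_paths(prefix)
    il = np.tril_indices(grm.n)
    grm.values[il].astype("<f4").tofile(bin_path)
    grm.pair_snp_counts[il].astype("<f4").tofile(n_path)
    with open(id_path, "w") as fh:
        for fid, iid in grm.individual_ids:
            fh.write(f"{fid}\t{iid}\n")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | os.PathLike,
                    trait_names: list[str] | None = None) -> PhenotypeTable:
    """Read a .phen-style table: ``FID IID trait1 [trait2 ...]``."""
    ids, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected FID IID and >=1 trait")
            ids.append((fields[0], fields[1]))
            row = []
            for tok in fields[2:]:
                if tok in _MISSING_TOKENS:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(tok))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: invalid value {tok!r}"
                        ) from None
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no phenotype rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: inconsistent column counts {sorted(widths)}")
    t = widths.pop()
    if trait_names is None:
        trait_names = [f"trait{i + 1}" for i in range(t)]
    elif len(trait_names) != t:
        raise ValidationError(
            f"{len(trait_names)} trait names for {t} columns")
    return PhenotypeTable(ids, trait_names, np.array(rows))


def write_phenotypes(table: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for (fid, iid), row in zip(table.individual_ids, table.values):
            toks = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(f"{fid}\t{iid}\t" + "\t".join(toks) + "\n")
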