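"""Readers and writers for genotype, phenotype, posterior and score files.

Supported genotype formats: VCF (biallelic SNPs, additive coding = count of
the ALT allele), PLINK ``.raw`` (additive coding as exported by
``plink --recode A``), and a delimited matrix with samples as rows and SNPs
as columns. The coding convention is fixed: the score of a genotype is the
count of the VCF ALT (or PLINK counted) allele, so flipping REF/ALT at a
SNP maps its column x to 2 - x. No minor-allele re-polarization is
performed: the LASSO-based methods are sign-symmetric, so polarity does not
affect RMIPs.

Coordinates are 1-based, as in VCF; SNP order always follows file order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CaseControlResponse, GenotypeMatrix, GenotypePosterior, ScoreTable

logger = logging.getLogger("llarrma")

PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeMatrix:
    """Read an additive-coded genotype matrix.

    Parameters
    ----------
    path : file path
    format : {"vcf", "plink_raw", "csv"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "csv":
        return _read_csv_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, positions = [], [], []
    for idx, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at record {idx + 1} ({variant.CHROM}:{variant.POS}); "
                "split multi-allelic sites first (e.g. `bcftools norm -m-`)"
            )
        # count of ALT alleles; any missing allele makes the genotype missing
        col = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a = gt[:-1]  # last element is the phased flag
            col[i] = np.nan if min(a) < 0 else float(sum(1 for x in a if x > 0))
        cols.append(col)
        ids.append(variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}")
        positions.append(variant.POS)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(np.column_stack(cols), ids, samples, np.asarray(positions))


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed PLINK .raw file {path}: {exc}") from exc
    missing_meta = [c for c in PLINK_META_COLS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"PLINK .raw file {path} lacks header columns {missing_meta}")
    snp_cols = [c for c in df.columns if c not in PLINK_META_COLS]
    if not snp_cols:
        raise ValueError(f"no SNP columns in {path}")
    values = df[snp_cols].to_numpy(dtype=float)
    # strip the _allele suffix plink appends (rs123_A -> rs123)
    ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return GenotypeMatrix(values, ids, df["IID"].astype(str).tolist())


def _read_csv_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"no SNP columns in {path}")
    return GenotypeMatrix(
        df.to_numpy(dtype=float), [str(c) for c in df.columns], df.index.astype(str).tolist()
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as CSV (samples x SNPs); NaN marks missing."""
    pd.DataFrame(gm.values, index=gm.sample_ids, columns=gm.snp_ids).to_csv(path)


def read_phenotypes(path: str | Path, genotypes: GenotypeMatrix | None = None):
    """Read a two-column sample_id,status file with status in {0, 1}.

    Returns (response, kept_row_indices). When ``genotypes`` is given the
    statuses are aligned to its sample order; samples with missing status
    are dropped with a warning and their row indices excluded.
    """
    df = pd.read_csv(path, header=None, names=["sample_id", "status"], skipinitialspace=True)
    if df.iloc[0, 0] in ("sample_id", "id", "sample"):  # tolerate a header line
        df = df.iloc[1:]
    df["sample_id"] = df["sample_id"].astype(str)
    df["status"] = pd.to_numeric(df["status"], errors="coerce")
    status = df.set_index("sample_id")["status"]
    if genotypes is not None:
        status = status.reindex(genotypes.sample_ids)
    keep = status.notna()
    if not keep.all():
        logger.warning("dropping %d samples with missing phenotype", int((~keep).sum()))
    y = status[keep].to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("phenotype status values must be 0 or 1")
    return CaseControlResponse(y.astype(int)), np.flatnonzero(keep.to_numpy())


def write_scores(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as tab-delimited snp_id, position, score, method,
    rank (rank 1 = best score; ties share the minimum rank)."""
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_posteriors(
    path: str | Path,
    format: str = "triple_table",
    genotypes: GenotypeMatrix | None = None,
):
    """Read genotype posteriors.

    ``triple_table``: tab/comma-delimited columns (sample, snp, p0, p1, p2)
    where sample/snp are 0-based row/column indices, or sample/SNP ids when
    ``genotypes`` is supplied. Each triple is renormalized to sum to 1;
    zero-sum or negative triples are errors. Returns a GenotypePosterior.

    ``fastphase_samples``: an ensemble of sampled complete genotype
    matrices, one per posterior draw, as blocks of n rows of m
    space-separated genotypes, each block preceded by a line starting with
    ``#``. Returns a list of complete GenotypeMatrix.
    """
    path = Path(path)
    if format == "triple_table":
        df = pd.read_csv(path, sep=None, engine="python",
                         names=["sample", "snp", "p0", "p1", "p2"], comment="#")
        if genotypes is not None:
            sample_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
            snp_pos = {s: j for j, s in enumerate(genotypes.snp_ids)}
            rows = df["sample"].astype(str).map(sample_pos)
            cols = df["snp"].astype(str).map(snp_pos)
            if rows.isna().any() or cols.isna().any():
                raise ValueError("posterior table refers to unknown sample or SNP ids")
            rows, cols = rows.astype(int), cols.astype(int)
        else:
            rows = df["sample"].astype(int)
            cols = df["snp"].astype(int)
        probs = df[["p0", "p1", "p2"]].to_numpy(dtype=float)
        return GenotypePosterior(rows.to_numpy(), cols.to_numpy(), probs)
    if format == "fastphase_samples":
        return _read_sampled_matrices(path)
    raise ValueError(f"unknown posterior format {format!r}")


def _read_sampled_matrices(path: Path) -> list[GenotypeMatrix]:
    blocks: list[list[list[float]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                blocks.append([])
                continue
            if not blocks:
                raise ValueError(f"{path}:{lineno}: data before the first '#' block header")
            try:
                blocks[-1].append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not blocks:
        raise ValueError(f"no sampled-genotype blocks in {path}")
    out = []
    for d, rows in enumerate(blocks):
        values = np.asarray(rows, dtype=float)
        if np.isnan(values).any():
            raise ValueError(f"sampled matrix {d} contains missing entries")
        n, m = values.shape
        out.append(GenotypeMatrix(
            values,
            [f"snp{j:04d}" for j in range(m)],
            [f"ind{i:05d}" for i in range(n)],
        ))
    return out
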