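"""Readers and writers for the plain-text formats the toolkit touches.

Supported formats:

* genotypes — PLINK ``.raw`` additive-dosage dialect (``plink-raw``:
  space-separated, header ``FID IID PAT MAT SEX PHENOTYPE`` then one column
  per marker, ``NA`` = missing) and a transposed ``simple-tsv`` dialect
  (marker rows by sample columns);
* expression — TSV, genes as rows, first column the gene ID, header row of
  sample IDs; orientation is normalized to samples-by-genes in memory;
* phenotypes/covariates — CSV with a header, first column the sample ID;
* relationship matrices — TSV with sample IDs as both header and first
  column, full float precision.

Every reader/writer pair is a lossless round trip; readers never impute.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AlignedBundle,
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    RelationshipMatrix,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
    "align_samples",
]

_PLINK_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ParseError(ValueError):
    """A file violated the expected format; the message names the location."""


def _parse_dosage(token: str, row: str, col: str) -> float:
    if token == "NA":
        return np.nan
    if token in ("0", "1", "2"):
        return float(token)
    raise ParseError(
        f"malformed dosage {token!r} at sample/marker row {row!r}, column {col!r}"
        " (expected 0, 1, 2 or NA)"
    )


def read_genotypes(path: str | Path, dialect: str = "plink-raw") -> GenotypeMatrix:
    """Read an additive-dosage genotype table.

    ``dialect`` is ``plink-raw`` (samples as rows) or ``simple-tsv``
    (markers as rows, samples as columns). Missing entries stay missing.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty genotype file")
    lines = text.splitlines()
    if dialect == "plink-raw":
        header = lines[0].split()
        if header[: len(_PLINK_META_COLS)] != _PLINK_META_COLS:
            raise ParseError(
                f"{path}: plink-raw header must start with {' '.join(_PLINK_META_COLS)}"
            )
        marker_ids = header[len(_PLINK_META_COLS):]
        if not marker_ids:
            raise ParseError(f"{path}: no marker columns")
        sample_ids, rows = [], []
        for ln in lines[1:]:
            if not ln.strip():
                continue
            parts = ln.split()
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: row for sample {parts[1] if len(parts) > 1 else '?'!r}"
                    f" has {len(parts)} fields, expected {len(header)}"
                )
            iid = parts[1]
            sample_ids.append(iid)
            rows.append([_parse_dosage(t, iid, m)
                         for t, m in zip(parts[len(_PLINK_META_COLS):], marker_ids)])
        dosages = np.array(rows, dtype=float).reshape(len(sample_ids), len(marker_ids))
    elif dialect == "simple-tsv":
        header = lines[0].rstrip("\n").split("\t")
        if header[0] != "marker":
            raise ParseError(f"{path}: simple-tsv header must start with 'marker'")
        sample_ids = header[1:]
        marker_ids, cols = [], []
        for ln in lines[1:]:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}: marker row {parts[0]!r} has {len(parts)} fields,"
                    f" expected {len(header)}"
                )
            marker_ids.append(parts[0])
            cols.append([_parse_dosage(t, s, parts[0])
                         for t, s in zip(parts[1:], sample_ids)])
        dosages = np.array(cols, dtype=float).T.reshape(len(sample_ids), len(marker_ids))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    return GenotypeMatrix(sample_ids, marker_ids, dosages)


def _fmt_dosage(v: float) -> str:
    return "NA" if np.isnan(v) else str(int(v))


def write_genotypes(path: str | Path, geno: GenotypeMatrix,
                    dialect: str = "plink-raw") -> None:
    path = Path(path)
    buf = _io.StringIO()
    if dialect == "plink-raw":
        buf.write(" ".join(_PLINK_META_COLS + geno.marker_ids) + "\n")
        for i, sid in enumerate(geno.sample_ids):
            meta = [sid, sid, "0", "0", "0", "-9"]
            row = [_fmt_dosage(v) for v in geno.dosages[i]]
            buf.write(" ".join(meta + row) + "\n")
    elif dialect == "simple-tsv":
        buf.write("\t".join(["marker"] + geno.sample_ids) + "\n")
        for j, mid in enumerate(geno.marker_ids):
            col = [_fmt_dosage(v) for v in geno.dosages[:, j]]
            buf.write("\t".join([mid] + col) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    path.write_text(buf.getvalue())


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples FPKM TSV; returns samples-by-genes in memory."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty expression file") from None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene IDs {dups[:5]}")
    for gene in df.index:
        row = df.loc[gene]
        bad = row[pd.to_numeric(row, errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric abundance {bad.iloc[0]!r} for gene "
                f"{gene!r}, sample {bad.index[0]!r}"
            )
    values = df.to_numpy(dtype=float).T  # to samples x genes
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"{path}: negative abundance for gene {df.index[j]!r}, "
            f"sample {df.columns[i]!r}"
        )
    return ExpressionMatrix([str(c) for c in df.columns],
                            [str(g) for g in df.index], values)


def write_expression(path: str | Path, expr: ExpressionMatrix) -> None:
    df = pd.DataFrame(expr.abundances.T, index=expr.gene_ids,
                      columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path, trait: str,
                    covariate_spec: dict[str, str] | None = None) -> PhenotypeTable:
    """Read a phenotype + covariate CSV (first column = sample ID).

    ``covariate_spec`` maps covariate column names to ``categorical`` or
    ``continuous``. Samples with a missing trait value are retained and
    flagged (``PhenotypeTable.missing_trait_ids``), never dropped silently.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty phenotype file") from None
    df.index = df.index.astype(str)
    if trait not in df.columns:
        raise ParseError(f"{path}: trait column {trait!r} not found "
                         f"(columns: {list(df.columns)})")
    spec = dict(covariate_spec or {})
    for c, kind in spec.items():
        if c not in df.columns:
            raise ParseError(f"{path}: covariate column {c!r} not found")
        if kind == "categorical":
            df[c] = df[c].astype(str)
    return PhenotypeTable(df, trait, spec)


def write_phenotypes(path: str | Path, pheno: PhenotypeTable) -> None:
    df = pheno.data.copy()
    df.index.name = "sample"
    df.to_csv(path)


def read_kernel(path: str | Path) -> RelationshipMatrix:
    """Read a relationship-matrix TSV (IDs as header and first column)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: kernel is not square ({df.shape[0]}x{df.shape[1]})")
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: kernel row IDs do not match column IDs")
    values = df.to_numpy(dtype=float)
    if values.size and np.abs(values - values.T).max() > 1e-10:
        raise ParseError(f"{path}: kernel is not symmetric")
    return RelationshipMatrix(ids, values, provenance="file")


def write_kernel(path: str | Path, K: RelationshipMatrix) -> None:
    df = pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids)
    df.index.name = "sample"
    # repr-precision floats so the round trip is lossless
    df.to_csv(path, sep="\t", float_format=None)


def align_samples(geno: GenotypeMatrix,
                  expr: ExpressionMatrix | None,
                  pheno: PhenotypeTable) -> AlignedBundle:
    """Align genotype, expression and phenotype sources on shared sample IDs.

    The bundle keeps the genotype file's sample order within blocks but
    places non-transcribed samples first and transcribed samples last, the
    convention the hybrid-matrix constructors rely on. Every transcribed
    (expression) sample must be genotyped; expression for an ungenotyped
    sample is an error, matching a design where the transcribed animals are
    a subset of the genotyped population.
    """
    pheno_ids = set(pheno.sample_ids)
    kept = [s for s in geno.sample_ids if s in pheno_ids]
    if not kept:
        raise ValueError("no shared sample IDs between genotypes and phenotypes")
    if expr is not None:
        geno_ids = set(geno.sample_ids)
        orphans = [s for s in expr.sample_ids if s not in geno_ids]
        if orphans:
            raise ValueError(
                f"expression samples absent from genotypes: {orphans[:5]}"
            )
        transcribed = set(expr.sample_ids) & set(kept)
        ordered = ([s for s in kept if s not in transcribed]
                   + [s for s in kept if s in transcribed])
        n_t = len(transcribed)
        bundle_expr = expr.subset_samples(ordered[len(ordered) - n_t:]) if n_t else None
        tidx = np.arange(len(ordered) - n_t, len(ordered), dtype=int)
    else:
        ordered = kept
        bundle_expr = None
        tidx = np.array([], dtype=int)
    return AlignedBundle(
        geno=geno.subset_samples(ordered),
        pheno=pheno.subset_samples(ordered),
        expr=bundle_expr,
        transcribed_idx=tidx,
    )
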