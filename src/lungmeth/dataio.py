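"""Tabular I/O and validation for every artifact the pipeline touches.

Canonical on-disk dialect is TSV: tab-delimited, UTF-8, '.' decimal point,
missing value = empty cell. All containers are pandas objects:

* beta matrix        — DataFrame, rows = CpG ids, columns = sample ids,
                       methylation fractions in [0, 1]
* probe manifest     — DataFrame indexed by CpG id with columns
                       ``gene`` (symbol), ``dist_tss`` (signed bp, negative =
                       upstream of the TSS), ``island`` (bool)
* expression matrix  — :class:`ExpressionMatrix` (log2 values + probe→gene map)
* sample sheet       — DataFrame indexed by sample id with clinical columns

Every reader validates; every writer round-trips through its reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LungmethError",
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "AlignedView",
    "SAMPLE_SHEET_COLUMNS",
    "validate_beta",
    "read_beta",
    "write_beta",
    "validate_manifest",
    "read_manifest",
    "write_manifest",
    "write_manifest_bed",
    "read_expression",
    "write_expression",
    "validate_sample_sheet",
    "read_sample_sheet",
    "write_sample_sheet",
    "align_datasets",
    "drop_duplicate_replicates",
    "FLOAT_FORMAT",
]

#: decimals written by every numeric writer; round-trip identity holds at this precision
FLOAT_FORMAT = "%.6g"

SAMPLE_SHEET_COLUMNS = [
    "tissue",
    "histology",
    "survival_months",
    "event",
    "pack_years",
    "smoker",
    "replicate_group",
]


class LungmethError(Exception):
    """Base error; ``code`` is a stable machine-readable identifier."""

    code = "error"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ValidationError(LungmethError):
    code = "invalid"


class ParseError(LungmethError):
    """Malformed input file; carries the offending 1-based line number."""

    code = "parse"

    def __init__(self, message: str, line: int | None = None, code: str | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message, code=code)
        self.line = line


# ---------------------------------------------------------------------------
# beta matrix


def validate_beta(values: pd.DataFrame, allow_missing: bool = True) -> pd.DataFrame:
    """Validate a probes x samples beta matrix and return it as float64.

    Raises :class:`ValidationError` on duplicate probe/sample ids or values
    outside [0, 1]; NaN is allowed only when *allow_missing*.
    """
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValidationError(f"duplicate probe id {dup!r}", code="dup-probe")
    if values.columns.has_duplicates:
        dup = values.columns[values.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}", code="dup-sample")
    try:
        out = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric beta value: {exc}", code="non-numeric") from exc
    arr = out.to_numpy()
    if np.isinf(arr).any():
        raise ValidationError("infinite beta value", code="non-finite")
    nan = np.isnan(arr)
    if nan.any() and not allow_missing:
        i, j = np.argwhere(nan)[0]
        raise ValidationError(
            f"missing beta at probe {out.index[i]!r}, sample {out.columns[j]!r}",
            code="missing",
        )
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {arr[i, j]!r} outside [0, 1] at probe {out.index[i]!r}, "
            f"sample {out.columns[j]!r}",
            code="range",
        )
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    out.index.name = "cpg_id"
    return out


def read_beta(path: str | Path, allow_missing: bool = True) -> pd.DataFrame:
    """Read a beta-matrix TSV (header = sample ids, first column = CpG id)."""
    df = _read_tsv_matrix(path)
    try:
        return validate_beta(df, allow_missing=allow_missing)
    except ValidationError as exc:
        raise _locate(exc, df, path) from exc


def write_beta(values: pd.DataFrame, path: str | Path) -> None:
    validate_beta(values).to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width:
                raise ParseError(
                    f"expected {width} fields, found {len(parts)}",
                    line=lineno,
                    code="ragged",
                )
            index.append(parts[0])
            rows.append([np.nan if p == "" else p for p in parts[1:]])
    df = pd.DataFrame(rows, index=index, columns=header[1:])
    df.index.name = header[0] or "cpg_id"
    return df


def _locate(exc: ValidationError, df: pd.DataFrame, path: str | Path) -> ParseError:
    """Re-raise a matrix validation failure with the file line of the probe."""
    msg = str(exc)
    for pos, probe in enumerate(df.index):
        if repr(str(probe)) in msg:
            return ParseError(f"{path}: {msg}", line=pos + 2, code=exc.code)
    return ParseError(f"{path}: {msg}", code=exc.code)


# ---------------------------------------------------------------------------
# probe manifest

_MANIFEST_COLS = ["gene", "dist_tss", "island"]

#: spec'd promoter window of the 27K design; distances beyond this only warn
TSS_WINDOW = (-1500, 1000)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    import warnings

    missing = [c for c in _MANIFEST_COLS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest lacks columns {missing}", code="columns")
    if manifest.index.has_duplicates:
        dup = manifest.index[manifest.index.duplicated()][0]
        raise ValidationError(f"duplicate cpg id {dup!r}", code="dup-probe")
    out = manifest.copy()
    out.index = out.index.astype(str)
    out.index.name = "cpg_id"
    out["dist_tss"] = out["dist_tss"].astype(int)
    out["island"] = out["island"].astype(int).astype(bool)
    lo, hi = TSS_WINDOW
    if ((out["dist_tss"] < lo) | (out["dist_tss"] > hi)).any():
        warnings.warn(
            f"manifest has TSS distances outside the 27K window [{lo}, {hi}]",
            stacklevel=2,
        )
    return out[_MANIFEST_COLS]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = validate_manifest(manifest).copy()
    out["island"] = out["island"].astype(int)
    out.to_csv(path, sep="\t")


def write_manifest_bed(
    manifest: pd.DataFrame, path: str | Path, tss_pos: int = 100_000
) -> None:
    """Optional BED4 export (chrom, start, end, cpg_id), 0-based half-open.

    Probes have no real genomic coordinates in a simulated manifest, so each
    gene is laid on its own synthetic contig with the TSS at *tss_pos*.
    """
    man = validate_manifest(manifest)
    start = tss_pos + man["dist_tss"].to_numpy()
    with open(path, "w", encoding="utf-8") as fh:
        for cpg, gene, s in zip(man.index, man["gene"], start):
            fh.write(f"{gene}\t{s}\t{s + 2}\t{cpg}\n")


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values plus the expression-probe → gene map.

    ``values`` rows are expression probe ids, columns sample ids;
    ``probe_gene`` maps each expression probe to exactly one gene symbol.
    """

    values: pd.DataFrame
    probe_gene: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate expression probe id", code="dup-probe")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample id", code="dup-sample")
        self.values = self.values.astype(float)
        self.probe_gene = self.probe_gene.astype(str)
        unmapped = self.values.index.difference(self.probe_gene.index)
        if len(unmapped):
            raise ValidationError(
                f"expression probe {unmapped[0]!r} has no gene mapping", code="unmapped"
            )
        self.probe_gene = self.probe_gene.reindex(self.values.index)

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def gene_probes(self, gene: str) -> pd.Index:
        return self.probe_gene.index[self.probe_gene == gene]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV whose second column is the gene symbol."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if "gene" not in df.columns:
        raise ParseError(f"{path}: expression file lacks a 'gene' column", code="columns")
    return ExpressionMatrix(values=df.drop(columns="gene"), probe_gene=df["gene"])


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.insert(0, "gene", expr.probe_gene)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet lacks columns {missing}", code="columns")
    if sheet.index.has_duplicates:
        dup = sheet.index[sheet.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}", code="dup-sample")
    out = sheet.copy()
    out.index = out.index.astype(str)
    out.index.name = "sample_id"
    bad_tissue = ~out["tissue"].isin(["tumor", "normal"])
    if bad_tissue.any():
        raise ValidationError(
            f"tissue must be tumor/normal, got {out['tissue'][bad_tissue].iloc[0]!r}",
            code="tissue",
        )
    # histology is NA exactly for normals
    hist = out["histology"].where(out["histology"].notna(), None)
    normals = out["tissue"] == "normal"
    if (hist[normals].notna()).any():
        raise ValidationError("normal samples must have histology NA", code="histology")
    bad_hist = ~out.loc[~normals, "histology"].isin(["SCC", "AC"])
    if bad_hist.any():
        raise ValidationError(
            "tumor histology must be SCC or AC", code="histology"
        )
    surv = pd.to_numeric(out["survival_months"], errors="coerce")
    if (surv[~normals].isna()).any():
        raise ValidationError("tumor samples must carry survival_months", code="survival")
    if (surv.dropna() < 0).any():
        raise ValidationError("negative survival_months", code="survival")
    out["survival_months"] = surv
    out["event"] = out["event"].map(_to_bool)
    out["smoker"] = out["smoker"].map(_to_bool)
    out["pack_years"] = pd.to_numeric(out["pack_years"], errors="coerce")
    if (out["pack_years"].dropna() < 0).any():
        raise ValidationError("negative pack_years", code="pack-years")
    return out[SAMPLE_SHEET_COLUMNS]


def _to_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float, np.integer, np.floating)):
        if v == 1:
            return True
        if v == 0:
            return False
        raise ValidationError(f"cannot interpret {v!r} as boolean", code="bool")
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    if s in ("", "nan", "na", "none"):
        return None
    raise ValidationError(f"cannot interpret {v!r} as boolean", code="bool")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return validate_sample_sheet(df)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = validate_sample_sheet(sheet).copy()
    for col in ("event", "smoker"):
        out[col] = out[col].map(lambda b: "" if b is None else int(b))
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def drop_duplicate_replicates(sheet: pd.DataFrame) -> pd.DataFrame:
    """Keep one member per technical-replicate group (the first listed).

    Replicate pairs are internal assay controls; analyses of patients must
    not count them twice.
    """
    grp = sheet["replicate_group"]
    has_group = grp.notna() & (grp.astype(str) != "")
    first = ~sheet.loc[has_group].duplicated(subset="replicate_group", keep="first")
    keep = pd.Series(True, index=sheet.index)
    keep.loc[has_group] = first
    return sheet.loc[keep].copy()


# ---------------------------------------------------------------------------
# dataset alignment


@dataclass
class AlignedView:
    """Sample intersection of beta/expression/sheet plus a drop report."""

    samples: list[str]
    beta: pd.DataFrame
    expression: ExpressionMatrix | None
    sheet: pd.DataFrame
    dropped: dict[str, list[str]] = field(default_factory=dict)


def align_datasets(
    beta: pd.DataFrame,
    expr: ExpressionMatrix | None,
    sheet: pd.DataFrame,
) -> AlignedView:
    """Restrict all inputs to their common samples, reporting what was dropped.

    Order follows the beta matrix. Raises :class:`ValidationError` when the
    intersection is empty.
    """
    ids = [set(beta.columns), set(sheet.index)]
    names = ["beta", "sheet"]
    if expr is not None:
        ids.insert(1, set(expr.samples))
        names.insert(1, "expression")
    common = set.intersection(*ids)
    if not common:
        raise ValidationError("no samples shared across inputs", code="empty-join")
    keep = [s for s in beta.columns if s in common]
    dropped = {
        name: sorted(idset - common) for name, idset in zip(names, ids) if idset - common
    }
    return AlignedView(
        samples=keep,
        beta=beta[keep],
        expression=(
            ExpressionMatrix(expr.values[keep], expr.probe_gene) if expr is not None else None
        ),
        sheet=sheet.loc[keep],
        dropped=dropped,
    )
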