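"""Reading, writing and quality control of methylation-array data.

The central container is :class:`BetaMatrix`, a probes x samples table of
beta values (fraction of methylated signal at a CpG, in [0, 1], NaN for
missing).  Sample sheets, probe annotations and homology tables are plain
:class:`pandas.DataFrame` objects with validated columns, which keeps them
directly usable with the pandas ecosystem.

QC follows array-processing practice for Infinium BeadChips: probes with
poor detection p-values or too many missing calls are removed first, then
samples with too many missing calls, then (optionally) probes on the sex
chromosomes.  All thresholds are parameters with the conventional defaults
(detection p > 0.01, >10% missing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BetaParseError,
    EmptyCohortError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("muriclock")

#: Tokens treated as missing in any numeric cell (matched case-insensitively).
MISSING_TOKENS = frozenset({"na", "nan", ""})

#: Recognised genomic-context categories (distance classes around CpG islands).
VALID_CONTEXTS = ("island", "shore", "shelf", "open_sea")

#: Chromosome labels counted as sex chromosomes (with/without "chr" prefix).
XY_CHROMS = frozenset({"x", "y", "chrx", "chry"})

SAMPLE_SHEET_COLUMNS = ("sample_id", "strain", "sex", "age_weeks")
ANNOTATION_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "context",
    "gene",
    "is_snp",
    "is_cross_reactive",
)
HOMOLOGY_COLUMNS = (
    "mouse_probe_id",
    "mouse_chrom",
    "mouse_pos",
    "human_chrom",
    "human_start",
    "human_end",
    "strand_flip",
)


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns; missing calls are NaN.  All non-missing entries must lie in
    [0, 1] and both axes must carry unique labels.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BetaParseError(
                f"beta value {arr[i, j]!r} out of [0, 1] at probe "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        self.values = v.astype(float)

    # -- basic accessors ----------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        probes: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "BetaMatrix":
        """Return a sub-matrix restricted to the given probes/samples (order kept)."""
        v = self.values
        if probes is not None:
            probes = [p for p in v.index if p in set(probes)]
            v = v.loc[probes]
        if samples is not None:
            samples = [s for s in v.columns if s in set(samples)]
            v = v[samples]
        return BetaMatrix(v.copy())

    def probe_missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def sample_missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=0)


def read_beta_matrix(path: str | Path, dialect: str = "probes_in_rows") -> BetaMatrix:
    """Read a TSV/CSV beta matrix.

    Parameters
    ----------
    path:
        Delimited text file with a header row and an id column; ``.csv`` is
        comma-separated, anything else tab-separated.
    dialect:
        ``"probes_in_rows"`` (default) or ``"samples_in_rows"`` (transposed
        on read so the returned matrix is always probes x samples).

    Missing-value tokens ``NA``, ``NaN`` and the empty string (any case)
    become NaN.  Any other non-numeric cell, or a value outside [0, 1],
    raises :class:`BetaParseError` naming the offending row and column.
    """
    if dialect not in ("probes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    stripped = raw.apply(lambda col: col.str.strip())
    is_missing = stripped.apply(lambda col: col.str.lower().isin(MISSING_TOKENS))
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    unparsed = numeric.isna() & ~is_missing
    if unparsed.to_numpy().any():
        i, j = np.argwhere(unparsed.to_numpy())[0]
        raise BetaParseError(
            f"cannot parse {stripped.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}"
        )
    if dialect == "samples_in_rows":
        numeric = numeric.T
    return BetaMatrix(numeric)


def write_beta_matrix(
    matrix: BetaMatrix, path: str | Path, dialect: str = "probes_in_rows"
) -> None:
    """Write a beta matrix as delimited text (6 decimals, ``NA`` for missing)."""
    path = Path(path)
    v = matrix.values if dialect == "probes_in_rows" else matrix.values.T
    v.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format="%.6f")


# ---------------------------------------------------------------------------
# Sample sheets, probe annotations, homology tables
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing required column(s): {', '.join(missing)}")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a cohort sample sheet (columns sample_id, strain, sex, age_weeks).

    Extra columns are preserved untouched.  ``sex`` must be M or F and ages
    strictly positive.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    _require_columns(df, SAMPLE_SHEET_COLUMNS, "sample sheet")
    df["sample_id"] = df["sample_id"].astype(str)
    df["strain"] = df["strain"].astype(str)
    df["sex"] = df["sex"].astype(str)
    try:
        df["age_weeks"] = pd.to_numeric(df["age_weeks"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-numeric age_weeks in sample sheet: {exc}") from exc
    validate_sample_sheet(df)
    return df


def validate_sample_sheet(df: pd.DataFrame) -> None:
    _require_columns(df, SAMPLE_SHEET_COLUMNS, "sample sheet")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r} in sample sheet")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"sex must be M or F, got {sorted(bad_sex)}")
    if (df["age_weeks"] <= 0).any():
        raise ValidationError("age_weeks must be > 0 for every sample")


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation table.

    Required columns: probe_id, chrom, pos, context, gene, is_snp,
    is_cross_reactive.  ``context`` must be one of island/shore/shelf/
    open_sea; coordinates are 1-based.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"probe_id": str, "chrom": str})
    _require_columns(df, ANNOTATION_COLUMNS, "probe annotation")
    df["probe_id"] = df["probe_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    df["gene"] = df["gene"].fillna("").astype(str)
    for col in ("is_snp", "is_cross_reactive"):
        df[col] = _parse_bool(df[col], col)
    validate_probe_annotation(df)
    return df


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise SchemaError(f"cannot parse boolean {bad!r} in column {name!r}")
    return out.astype(bool)


def validate_probe_annotation(df: pd.DataFrame) -> None:
    _require_columns(df, ANNOTATION_COLUMNS, "probe annotation")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id {dup!r} in annotation")
    bad = set(df["context"]) - set(VALID_CONTEXTS)
    if bad:
        raise ValidationError(
            f"unknown context label(s) {sorted(bad)}; expected one of {VALID_CONTEXTS}"
        )
    if (df["pos"] < 1).any():
        raise ValidationError("probe positions are 1-based and must be >= 1")


def read_homology_table(path: str | Path) -> pd.DataFrame:
    """Read a mouse-to-human homology-region table (one alignment window per row)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        dtype={"mouse_probe_id": str, "mouse_chrom": str, "human_chrom": str},
    )
    _require_columns(df, HOMOLOGY_COLUMNS, "homology table")
    for col in ("mouse_pos", "human_start", "human_end"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    df["strand_flip"] = _parse_bool(df["strand_flip"], "strand_flip")
    if (df["human_start"] > df["human_end"]).any():
        raise ValidationError("homology regions need human_start <= human_end")
    return df


def is_xy(chrom: pd.Series | Sequence[str]) -> pd.Series:
    """Boolean mask for sex-chromosome labels (case and 'chr'-prefix tolerant)."""
    s = pd.Series(chrom, copy=False).astype(str).str.lower()
    return s.isin(XY_CHROMS)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Counts of what the QC filter removed, serialisable to JSON."""

    probes_removed_detection: int = 0
    probes_removed_missing: int = 0
    samples_removed: list[str] = field(default_factory=list)
    probes_removed_xy: int = 0
    n_probes_in: int = 0
    n_samples_in: int = 0
    n_probes_out: int = 0
    n_samples_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def qc_filter(
    matrix: BetaMatrix,
    annotation: pd.DataFrame | None = None,
    detection_p: pd.DataFrame | pd.Series | None = None,
    detection_p_threshold: float = 0.01,
    max_probe_missing: float = 0.10,
    max_sample_missing: float = 0.10,
    drop_xy: bool = False,
) -> tuple[BetaMatrix, QCReport]:
    """Apply probe- and sample-level QC to a beta matrix.

    Steps, in fixed order:

    1. drop probes with any detection p-value above ``detection_p_threshold``
       (skipped with a warning when ``detection_p`` is None — processed beta
       exports usually no longer carry IDAT-level detection p-values);
    2. drop probes whose missing fraction exceeds ``max_probe_missing``;
    3. drop samples whose missing fraction (over surviving probes) exceeds
       ``max_sample_missing``;
    4. drop X/Y-chromosome probes when ``drop_xy`` (requires ``annotation``).

    Probe filtering precedes sample filtering so that bad probes do not
    inflate sample missingness.  Surviving cell values are never altered.
    """
    report = QCReport(n_probes_in=matrix.n_probes, n_samples_in=matrix.n_samples)
    v = matrix.values

    if detection_p is None:
        logger.warning("no detection p-values supplied; detection filter skipped")
    else:
        if isinstance(detection_p, pd.Series):
            worst = detection_p.reindex(v.index)
        else:
            worst = detection_p.reindex(index=v.index, columns=v.columns).max(axis=1)
        fail = worst > detection_p_threshold
        report.probes_removed_detection = int(fail.sum())
        v = v.loc[~fail.fillna(False)]

    frac = v.isna().mean(axis=1)
    fail = frac > max_probe_missing
    report.probes_removed_missing = int(fail.sum())
    v = v.loc[~fail]

    sfrac = v.isna().mean(axis=0)
    sfail = sfrac > max_sample_missing
    report.samples_removed = list(v.columns[sfail])
    v = v.loc[:, ~sfail]
    if v.shape[1] == 0:
        raise EmptyCohortError("QC removed every sample")

    if drop_xy:
        if annotation is None:
            raise ValidationError("drop_xy requires a probe annotation")
        ann = annotation.set_index("probe_id")["chrom"].reindex(v.index)
        xy = is_xy(ann).to_numpy()
        report.probes_removed_xy = int(xy.sum())
        v = v.loc[~xy]

    report.n_probes_out, report.n_samples_out = v.shape
    return BetaMatrix(v.copy()), report


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a DataFrame as TSV/CSV chosen by extension (NA for missing)."""
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), na_rep="NA", index=index)
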