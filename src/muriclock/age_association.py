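"""Per-CpG age association and cross-strain candidate selection.

The selection statistic is the least-squares slope of beta versus
*normalized* age,

    slope_CpG = sum((x_i - x_bar) * (y_i - y_bar)) / sum((x_i - x_bar)^2),

where x_i is the sample's age scaled to [0, 1] within its (strain, sex)
group and y_i the beta value.  With both axes on [0, 1] a slope of 0.3
reads as a 30% absolute change in methylation over the observed lifespan,
which is why the statistic — rather than a correlation coefficient — is
used to screen for CpGs with large absolute methylation change.  B6 and
DBA/2J mice have different life expectancies (2.42 vs 1.87 years), so ages
are normalized per strain (and sex) before slopes are compared across
strains; candidates are those exceeding the threshold in *both* strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGroupError,
    DegeneratePredictorError,
    UndefinedCorrelationError,
    ValidationError,
)
from .methylome_io import BetaMatrix, VALID_CONTEXTS

#: Reported life expectancies used by the "lifespan" normalization variant.
STRAIN_LIFESPAN_YEARS: dict[str, float] = {"B6": 2.42, "DBA": 1.87}
WEEKS_PER_YEAR = 365.25 / 7.0


@dataclass
class NormalizedAges:
    """Normalized ages plus the per-group ranges needed to invert the scaling.

    ``x`` maps sample_id -> normalized age; ``group_of`` maps sample_id ->
    (strain, sex); ``ranges`` maps (strain, sex) -> (min_age, max_age) in
    weeks (for ``method="lifespan"`` the range is (0, lifespan_weeks)).
    """

    x: pd.Series
    group_of: pd.Series
    ranges: dict[tuple[str, str], tuple[float, float]]
    method: str = "minmax"

    def for_samples(self, sample_ids: Iterable[str]) -> pd.Series:
        return self.x.reindex(list(sample_ids))


def normalize_ages(sheet: pd.DataFrame, method: str = "minmax") -> NormalizedAges:
    """Scale chronological ages to [0, 1] within each (strain, sex) group.

    ``method="minmax"`` (default) maps each group's observed age range onto
    [0, 1].  ``method="lifespan"`` instead divides age by the strain's life
    expectancy in weeks, an alternative reading of "normalized by strain"
    that does not depend on the sampled ages.
    """
    if method not in ("minmax", "lifespan"):
        raise ValueError(f"unknown normalization method {method!r}")
    x = pd.Series(index=sheet["sample_id"].to_numpy(), dtype=float)
    group_of = pd.Series(index=x.index, dtype=object)
    ranges: dict[tuple[str, str], tuple[float, float]] = {}
    for (strain, sex), grp in sheet.groupby(["strain", "sex"], sort=False):
        ids = grp["sample_id"].to_numpy()
        ages = grp["age_weeks"].to_numpy(dtype=float)
        if method == "minmax":
            lo, hi = float(ages.min()), float(ages.max())
            if len(ids) < 2 or hi == lo:
                raise DegenerateGroupError(
                    f"group ({strain}, {sex}) needs >=2 samples with distinct "
                    f"ages for min-max normalization"
                )
            x[ids] = (ages - lo) / (hi - lo)
        else:
            if strain not in STRAIN_LIFESPAN_YEARS:
                raise ValidationError(
                    f"no lifespan on record for strain {strain!r}; "
                    f"known: {sorted(STRAIN_LIFESPAN_YEARS)}"
                )
            lo, hi = 0.0, STRAIN_LIFESPAN_YEARS[strain] * WEEKS_PER_YEAR
            x[ids] = ages / hi
        group_of[ids] = [(strain, sex)] * len(ids)
        ranges[(strain, sex)] = (lo, hi)
    return NormalizedAges(x=x, group_of=group_of, ranges=ranges, method=method)


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def slope_cpg(x, y) -> float:
    """Least-squares slope of y (beta) on x (normalized age), pairwise-complete.

    Requires at least 3 complete pairs and non-constant x.
    """
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValidationError(f"slope_cpg needs >=3 complete pairs, got {len(x)}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegeneratePredictorError("normalized ages are constant; slope undefined")
    return float(xc @ (y - y.mean()) / sxx)


def pearson_age_r(x, y) -> float:
    """Pearson correlation of beta with age, pairwise-complete (>=3 pairs)."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValidationError(f"pearson_age_r needs >=3 complete pairs, got {len(x)}")
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = float(xc @ xc), float(yc @ yc)
    if sxx <= 0.0 or syy <= 0.0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    return float(xc @ yc / math.sqrt(sxx * syy))


# ---------------------------------------------------------------------------
# Matrix-level screen
# ---------------------------------------------------------------------------


def slope_table(matrix: BetaMatrix, ages: NormalizedAges) -> pd.DataFrame:
    """Per-probe slope_CpG, Pearson r and pair count for a whole matrix.

    Vectorised pairwise-complete computation over all probes; probes with
    fewer than 3 complete pairs or zero beta variance get NaN statistics
    (slope is still defined for zero beta variance: it is 0).
    Columns: ``slope``, ``pearson_r``, ``n``; index: probe_id.
    """
    x = ages.for_samples(matrix.sample_ids).to_numpy(dtype=float)
    if np.isnan(x).any():
        missing = [s for s, v in zip(matrix.sample_ids, x) if np.isnan(v)]
        raise ValidationError(f"samples missing from normalized ages: {missing[:5]}")
    Y = matrix.values.to_numpy(dtype=float)
    M = ~np.isnan(Y)
    n = M.sum(axis=1)
    Xm = np.where(M, x, 0.0)
    Y0 = np.where(M, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = Xm.sum(axis=1)
        sy = Y0.sum(axis=1)
        sxx = (Xm * Xm).sum(axis=1)
        syy = (Y0 * Y0).sum(axis=1)
        sxy = (Xm * Y0).sum(axis=1)
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        slope = cov / varx
        r = cov / np.sqrt(varx * vary)
    ok = (n >= 3) & (varx > 0)
    slope[~ok] = np.nan
    # tiny negative vary from cancellation => constant probe
    r[~ok | (vary <= 0)] = np.nan
    slope[ok & (vary <= 0)] = 0.0
    return pd.DataFrame(
        {"slope": slope, "pearson_r": r, "n": n.astype(int)}, index=matrix.values.index
    )


@dataclass
class CandidateSet:
    """Probes whose |slope_CpG| exceeds the threshold in one strain."""

    strain: str
    threshold: float
    probe_ids: frozenset[str]
    table: pd.DataFrame = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.probe_ids)


def select_candidates(
    matrix: BetaMatrix,
    ages: NormalizedAges,
    threshold: float = 0.3,
    strain: str = "",
) -> CandidateSet:
    """Select probes with |slope_CpG| strictly greater than ``threshold``.

    ``matrix`` should already be QC-filtered, restricted to one strain's
    samples and free of X/Y probes.
    """
    tab = slope_table(matrix, ages)
    sel = tab.index[tab["slope"].abs() > threshold]
    return CandidateSet(
        strain=strain, threshold=threshold, probe_ids=frozenset(sel), table=tab
    )


@dataclass
class VennResult:
    """Intersection of two strains' candidate sets with per-strain exclusives."""

    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    strain_a: str = ""
    strain_b: str = ""

    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            f"only_{self.strain_a or 'a'}": len(self.only_a),
            f"only_{self.strain_b or 'b'}": len(self.only_b),
        }


def intersect_candidates(a: CandidateSet, b: CandidateSet) -> VennResult:
    """Intersect two candidate sets (the cross-strain consensus of the screen)."""
    shared = a.probe_ids & b.probe_ids
    return VennResult(
        shared=frozenset(shared),
        only_a=frozenset(a.probe_ids - shared),
        only_b=frozenset(b.probe_ids - shared),
        strain_a=a.strain,
        strain_b=b.strain,
    )


# ---------------------------------------------------------------------------
# Genomic-context summaries
# ---------------------------------------------------------------------------


def context_summary(r_per_probe: pd.Series, annotation: pd.DataFrame) -> pd.DataFrame:
    """Median age correlation per genomic-context category.

    ``r_per_probe`` maps probe_id -> Pearson r (NaN entries are dropped).
    Returns one row per context present, with columns ``context``,
    ``n_probes``, ``median_r``.
    """
    ctx = annotation.set_index("probe_id")["context"].reindex(r_per_probe.index)
    if ctx.isna().any():
        missing = list(r_per_probe.index[ctx.isna()])[:5]
        raise ValidationError(f"probes absent from annotation: {missing}")
    bad = set(ctx) - set(VALID_CONTEXTS)
    if bad:
        raise ValidationError(f"unknown context label(s): {sorted(bad)}")
    df = pd.DataFrame({"r": r_per_probe, "context": ctx}).dropna(subset=["r"])
    rows = [
        {"context": c, "n_probes": len(g), "median_r": float(g["r"].median())}
        for c, g in df.groupby("context", sort=False)
    ]
    return pd.DataFrame(rows, columns=["context", "n_probes", "median_r"])


def context_histograms(
    r_per_probe: pd.Series,
    annotation: pd.DataFrame,
    bins: np.ndarray | int = 40,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Histogram of age correlations per context: {context: (counts, edges)}."""
    ctx = annotation.set_index("probe_id")["context"].reindex(r_per_probe.index)
    edges = np.histogram_bin_edges(
        r_per_probe.dropna().to_numpy(), bins=bins, range=(-1.0, 1.0)
    )
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in VALID_CONTEXTS:
        vals = r_per_probe[(ctx == c).to_numpy()].dropna().to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        out[c] = (counts, edges)
    return out
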