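"""Strain-level methylome comparisons.

Covers the pairwise sample correlation matrix (computed over *all* CpGs,
sex chromosomes included — unlike the clock analyses), the per-CpG
two-group Wilcoxon rank-sum screen for differential methylation with
Bonferroni control, the Mann-Whitney sex-effect test on prediction errors,
and the global methylated-fraction-versus-age trend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .age_association import pearson_age_r
from .errors import (
    UnderpoweredDesignError,
    ValidationError,
)
from .methylome_io import BetaMatrix

#: Largest per-group size at which the exact rank-sum null is used (when the
#: probe has no ties); cohorts of 11-12 animals per strain sit below this.
EXACT_MAX_N = 12


def sample_correlation_matrix(matrix: BetaMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples over shared probes.

    Pairwise-complete: each sample pair is correlated over the probes
    non-missing in both.  A pair sharing fewer than ``min_shared`` probes
    (or with a constant profile over the shared probes) is an error naming
    the pair.  Returns a symmetric DataFrame with unit diagonal.
    """
    if matrix.n_samples < 2:
        raise ValidationError("correlation matrix needs >=2 samples")
    r = matrix.values.corr(method="pearson", min_periods=min_shared)
    np.fill_diagonal(r.to_numpy(), 1.0)
    if r.isna().to_numpy().any():
        mask = r.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ValidationError(
            f"correlation undefined for sample pair "
            f"({r.index[i]!r}, {r.columns[j]!r}): fewer than {min_shared} "
            f"shared probes or zero variance"
        )
    return r


def _rank_sum_pvalues(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum per row of A (group 1) vs B (group 2).

    Uses the exact null distribution when both groups are small enough and
    the row has no ties; otherwise the normal approximation with continuity
    and tie correction.  Rows with NaN are handled individually.
    """
    n_probes = A.shape[0]
    stat = np.full(n_probes, np.nan)
    p = np.full(n_probes, np.nan)

    row_nan = np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1)
    both = np.concatenate([A, B], axis=1)
    # a row has ties iff sorting the pooled values yields an equal neighbour
    srt = np.sort(both, axis=1)
    has_ties = (np.diff(srt, axis=1) == 0).any(axis=1)

    small = A.shape[1] <= EXACT_MAX_N and B.shape[1] <= EXACT_MAX_N
    exact_rows = ~row_nan & ~has_ties & small
    approx_rows = ~row_nan & ~exact_rows

    if exact_rows.any():
        res = stats.mannwhitneyu(
            A[exact_rows], B[exact_rows], alternative="two-sided",
            method="exact", axis=1,
        )
        stat[exact_rows] = res.statistic
        p[exact_rows] = res.pvalue
    if approx_rows.any():
        res = stats.mannwhitneyu(
            A[approx_rows], B[approx_rows], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        stat[approx_rows] = res.statistic
        p[approx_rows] = res.pvalue
    for i in np.flatnonzero(row_nan):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if len(a) == 0 or len(b) == 0:
            continue
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = (
            "exact"
            if len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N and not ties
            else "asymptotic"
        )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat[i], p[i] = res.statistic, res.pvalue
    return stat, p


def differential_methylation(
    matrix: BetaMatrix,
    sheet: pd.DataFrame,
    group_by: str = "strain",
    alpha: float = 0.01,
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Per-CpG two-group Wilcoxon rank-sum screen with Bonferroni control.

    ``matrix`` should already exclude X/Y, SNP-overlapping and
    cross-reactive probes.  ``group_by`` names a sample-sheet column with
    exactly two levels of >=4 samples each.  ``bonferroni_m`` overrides the
    correction divisor (default: the number of probes actually tested);
    the fixed-divisor option exists because "the total amount of CpGs on
    the array" is an equally defensible reading.

    Returns a DataFrame (index probe_id) with columns ``stat`` (the
    Mann-Whitney U of the first group), ``p_raw``, ``p_adj`` and
    ``significant`` (p_adj < alpha).
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    groups = sheet.set_index("sample_id")[group_by].reindex(matrix.sample_ids)
    if groups.isna().any():
        raise ValidationError("every sample in the matrix needs group metadata")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    ids_a = [s for s in matrix.sample_ids if groups[s] == levels[0]]
    ids_b = [s for s in matrix.sample_ids if groups[s] == levels[1]]
    if min(len(ids_a), len(ids_b)) < 4:
        raise UnderpoweredDesignError(
            f"rank-sum screen needs >=4 samples per group "
            f"({levels[0]}: {len(ids_a)}, {levels[1]}: {len(ids_b)})"
        )
    A = matrix.values[ids_a].to_numpy(dtype=float)
    B = matrix.values[ids_b].to_numpy(dtype=float)
    stat, p_raw = _rank_sum_pvalues(A, B)
    m = bonferroni_m if bonferroni_m is not None else int(np.sum(~np.isnan(p_raw)))
    p_adj = np.minimum(p_raw * m, 1.0)
    return pd.DataFrame(
        {
            "stat": stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=matrix.values.index,
    )


def sex_effect_test(delta_ages, sexes) -> float:
    """Two-sided Mann-Whitney U p-value for a sex effect on prediction errors.

    ``delta_ages`` are predicted minus chronological ages; ``sexes`` the
    matching M/F labels.  Both sexes need >=3 samples.
    """
    delta = np.asarray(delta_ages, dtype=float)
    sexes = np.asarray(sexes)
    if delta.shape != sexes.shape:
        raise ValueError("delta_ages and sexes must align")
    m = delta[sexes == "M"]
    f = delta[sexes == "F"]
    if len(m) < 3 or len(f) < 3:
        raise UnderpoweredDesignError(
            f"sex-effect test needs >=3 per sex (M: {len(m)}, F: {len(f)})"
        )
    ties = len(np.unique(delta)) < len(delta)
    method = (
        "exact"
        if len(m) <= EXACT_MAX_N and len(f) <= EXACT_MAX_N and not ties
        else "asymptotic"
    )
    return float(
        stats.mannwhitneyu(m, f, alternative="two-sided", method=method).pvalue
    )


def global_methylation_trend(
    matrix: BetaMatrix,
    sheet: pd.DataFrame,
    call_threshold: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Fraction of methylated CpG calls per sample and its correlation with age.

    A probe is called methylated in a sample when beta > ``call_threshold``
    (fraction computed over non-missing probes).  Returns the per-sample
    table (sample_id, fraction_methylated, age_weeks) and the Pearson r of
    fraction versus age; a constant fraction vector makes the correlation
    undefined and raises.
    """
    v = matrix.values
    frac = (v > call_threshold).sum(axis=0) / v.notna().sum(axis=0)
    ages = sheet.set_index("sample_id")["age_weeks"].reindex(v.columns)
    if ages.isna().any():
        raise ValidationError("every sample needs an age for the global trend")
    table = pd.DataFrame(
        {
            "sample_id": v.columns,
            "fraction_methylated": frac.to_numpy(),
            "age_weeks": ages.to_numpy(),
        }
    )
    r = pearson_age_r(table["age_weeks"], table["fraction_methylated"])
    return table, r
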