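"""Epigenetic age predictors: the single-CpG ensemble and the 4-CpG clock.

Two model classes are implemented.

*Ensemble clock.*  With only 12 training animals, a multivariable model on
~100 CpGs would be hopelessly under-determined, so each candidate CpG gets
its own univariate linear model (normalized age regressed on beta) and the
final prediction is the arithmetic mean of the per-CpG age estimates,
mapped back to weeks with the training cohort's (strain, sex) age range.

*Multivariate pyrosequencing clock.*  For targeted assays, an exhaustive
search over all combinations of k CpGs drawn from k distinct PCR amplicons
fits ordinary least squares of age (weeks) on methylation (%) and keeps the
combination with the smallest training MAD (mean absolute deviation).  The
published blood clock for C57BL/6 mice,

    age_weeks = 167.4533 + 1.2421*alpha + 0.9824*beta
                         - 1.3110*gamma - 1.6088*delta,

with alpha = Aspa pos1 (cg29748675), beta = Hsf4 pos3, gamma = Wnt3a pos2
and delta = Prima1 pos1 (cg31044702) methylation in percent, is shipped as
a frozen model.

Evaluation follows the convention used throughout: MAE is the MEDIAN
absolute error and MAD the MEAN absolute deviation of predicted minus
chronological age, both in weeks; r2 is the squared Pearson correlation of
predicted versus chronological age.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .age_association import NormalizedAges, pearson_age_r
from .errors import ConfigurationError, PredictionError, ValidationError
from .methylome_io import BetaMatrix

logger = logging.getLogger("muriclock")


# ---------------------------------------------------------------------------
# Ensemble clock
# ---------------------------------------------------------------------------


@dataclass
class SingleCpGModel:
    probe_id: str
    slope: float
    intercept: float

    def estimate(self, beta: float) -> float:
        """Normalized-age estimate from one beta value."""
        return self.slope * beta + self.intercept


@dataclass
class EnsembleClock:
    """Average-of-univariate-models age predictor.

    ``ranges`` stores the training cohort's (strain, sex) -> (min, max) age
    in weeks, used to denormalize the mean normalized-age estimate.
    ``skipped`` lists training probes excluded for zero beta variance.
    """

    models: list[SingleCpGModel]
    ranges: dict[tuple[str, str], tuple[float, float]]
    mode: str = "direct"
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("ensemble clock needs at least one CpG model")
        for (lo, hi) in self.ranges.values():
            if not (hi > lo):
                raise ValidationError("degenerate age range in ensemble clock")

    @property
    def probe_ids(self) -> list[str]:
        return [m.probe_id for m in self.models]

    # -- JSON round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "type": "ensemble",
            "mode": self.mode,
            "models": [
                {"probe_id": m.probe_id, "slope": m.slope, "intercept": m.intercept}
                for m in self.models
            ],
            "ranges": [
                {"strain": k[0], "sex": k[1], "min_weeks": v[0], "max_weeks": v[1]}
                for k, v in self.ranges.items()
            ],
            "skipped": list(self.skipped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleClock":
        return cls(
            models=[SingleCpGModel(**m) for m in d["models"]],
            ranges={
                (r["strain"], r["sex"]): (r["min_weeks"], r["max_weeks"])
                for r in d["ranges"]
            },
            mode=d.get("mode", "direct"),
            skipped=list(d.get("skipped", [])),
        )


def fit_ensemble(
    matrix: BetaMatrix, ages: NormalizedAges, mode: str = "direct"
) -> EnsembleClock:
    """Fit one univariate linear model per probe.

    ``mode="direct"`` (default) regresses normalized age on beta, so each
    CpG directly yields an age estimate.  ``mode="inverse"`` fits beta on
    age (classical calibration) and inverts the line; it is exposed because
    either reading of "linear models using the normalized beta values" is
    defensible, and the two coincide only for perfectly correlated data.

    Probes with zero beta variance (or <3 complete pairs) cannot estimate
    age and are skipped with a warning, recorded in ``skipped``.
    """
    if mode not in ("direct", "inverse"):
        raise ValueError(f"unknown ensemble mode {mode!r}")
    if matrix.n_samples < 3:
        raise ValidationError("ensemble fitting needs >=3 samples")
    x = ages.for_samples(matrix.sample_ids).to_numpy(dtype=float)
    models: list[SingleCpGModel] = []
    skipped: list[str] = []
    Y = matrix.values.to_numpy(dtype=float)
    for pid, y in zip(matrix.values.index, Y):
        keep = ~(np.isnan(y) | np.isnan(x))
        if keep.sum() < 3:
            skipped.append(pid)
            continue
        xi, yi = x[keep], y[keep]
        vy = float(np.var(yi))
        if vy == 0.0:
            skipped.append(pid)
            continue
        if mode == "direct":
            slope = float(np.cov(yi, xi, bias=True)[0, 1] / vy)
            intercept = float(xi.mean() - slope * yi.mean())
        else:
            b = float(np.cov(xi, yi, bias=True)[0, 1] / np.var(xi))
            a = float(yi.mean() - b * xi.mean())
            if b == 0.0:
                skipped.append(pid)
                continue
            slope, intercept = 1.0 / b, -a / b
        models.append(SingleCpGModel(pid, slope, intercept))
    if skipped:
        logger.warning("ensemble fit skipped %d zero-information probes", len(skipped))
    if not models:
        raise ValidationError("no probe produced a usable univariate model")
    return EnsembleClock(models=models, ranges=dict(ages.ranges), mode=mode,
                         skipped=skipped)


def _denormalize(clock: EnsembleClock, value: float, group: tuple[str, str]) -> float:
    if group in clock.ranges:
        lo, hi = clock.ranges[group]
    else:
        # strain/sex absent from training: fall back to the union of training
        # ranges (the cross-strain transfer setting)
        lo = min(r[0] for r in clock.ranges.values())
        hi = max(r[1] for r in clock.ranges.values())
        logger.warning(
            "group %s not in training ranges; reusing training range (%g, %g)",
            group, lo, hi,
        )
    return lo + value * (hi - lo)


def predict_ensemble(
    clock: EnsembleClock,
    betas: Mapping[str, float] | pd.Series,
    target_group: tuple[str, str],
) -> float:
    """Predict one sample's age in weeks.

    Each clock CpG present (and non-missing) in ``betas`` contributes a
    normalized-age estimate; their mean is denormalized with the target
    group's training age range.  Missing clock CpGs are skipped; if none
    overlap, prediction is impossible.
    """
    betas = pd.Series(betas)
    estimates = [
        m.estimate(float(betas[m.probe_id]))
        for m in clock.models
        if m.probe_id in betas.index and not math.isnan(float(betas[m.probe_id]))
    ]
    if not estimates:
        raise PredictionError("no clock CpG present in the sample")
    return _denormalize(clock, float(np.mean(estimates)), target_group)


def predict_ensemble_matrix(
    clock: EnsembleClock, matrix: BetaMatrix, sheet: pd.DataFrame
) -> pd.Series:
    """Vector of predictions for every sample in a cohort (weeks)."""
    groups = sheet.set_index("sample_id")[["strain", "sex"]]
    out = {}
    for sid in matrix.sample_ids:
        grp = (groups.at[sid, "strain"], groups.at[sid, "sex"])
        out[sid] = predict_ensemble(clock, matrix.values[sid], grp)
    return pd.Series(out, name="predicted_weeks")


# ---------------------------------------------------------------------------
# Multivariate pyrosequencing clock
# ---------------------------------------------------------------------------


@dataclass
class MultivariateClock:
    """Affine age model on k CpG methylation percentages.

    ``terms`` is an ordered list of (cpg_label, coefficient in weeks per
    %DNAm); ``provenance`` records whether the coefficients were fitted
    here or are the published ones.
    """

    intercept: float
    terms: list[tuple[str, float]]
    provenance: str = "fitted"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [t[0] for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValidationError("multivariate clock term labels must be unique")
        coeffs = [self.intercept, *[t[1] for t in self.terms]]
        if not all(math.isfinite(c) for c in coeffs):
            raise ValidationError("multivariate clock coefficients must be finite")

    @property
    def labels(self) -> list[str]:
        return [t[0] for t in self.terms]

    def to_dict(self) -> dict:
        return {
            "type": "multivariate",
            "intercept": self.intercept,
            "terms": [{"cpg": c, "coefficient": b} for c, b in self.terms],
            "provenance": self.provenance,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultivariateClock":
        return cls(
            intercept=d["intercept"],
            terms=[(t["cpg"], t["coefficient"]) for t in d["terms"]],
            provenance=d.get("provenance", "fitted"),
            metadata=dict(d.get("metadata", {})),
        )


def published_b6_clock() -> MultivariateClock:
    """The frozen published 4-CpG blood clock for C57BL/6 mice.

    Inputs are methylation percentages (0-100) at four pyrosequencing CpGs,
    each from a distinct amplicon; output is predicted age in weeks.
    """
    return MultivariateClock(
        intercept=167.4533,
        terms=[
            ("Aspa_pos1", 1.2421),
            ("Hsf4_pos3", 0.9824),
            ("Wnt3a_pos2", -1.3110),
            ("Prima1_pos1", -1.6088),
        ],
        provenance="published",
        metadata={
            "species": "Mus musculus",
            "strain": "B6",
            "tissue": "blood",
            "units": "percent DNAm -> weeks",
            "array_cpgs": {
                "Aspa_pos1": "cg29748675",
                "Hsf4_pos3": "5 bp upstream of cg46095458",
                "Wnt3a_pos2": "9 positions upstream of cg29601161",
                "Prima1_pos1": "cg31044702",
            },
        },
    )


def predict_multivariate(
    clock: MultivariateClock,
    dnam_percent: Mapping[str, float] | Sequence[float],
) -> float:
    """Evaluate the affine clock on one sample's methylation percentages.

    ``dnam_percent`` is either a mapping keyed by the clock's CpG labels or
    a sequence in term order.  Values outside [0, 100] are allowed (with a
    warning) since pyrosequencing noise can nudge measurements past the
    bounds; a missing value is an error.  The output is not clamped.
    """
    if isinstance(dnam_percent, Mapping):
        try:
            values = [float(dnam_percent[c]) for c in clock.labels]
        except KeyError as exc:
            raise PredictionError(f"missing DNAm value for CpG {exc.args[0]!r}") from exc
    else:
        values = [float(v) for v in dnam_percent]
        if len(values) != len(clock.terms):
            raise PredictionError(
                f"expected {len(clock.terms)} DNAm values, got {len(values)}"
            )
    for c, v in zip(clock.labels, values):
        if math.isnan(v):
            raise PredictionError(f"missing DNAm value for CpG {c!r}")
        if not (0.0 <= v <= 100.0):
            logger.warning("DNAm %g%% for %s outside [0, 100]", v, c)
    return clock.intercept + float(
        sum(b * v for (_, b), v in zip(clock.terms, values))
    )


def combination_count(amplicon_of: Mapping[str, str], k: int = 4) -> int:
    """Number of k-CpG models with all CpGs from distinct amplicons."""
    sizes = pd.Series(list(amplicon_of.values())).value_counts()
    total = 0
    for combo in itertools.combinations(sizes.to_numpy(), k):
        total += int(np.prod(combo))
    return total


def fit_multivariate(
    dnam_percent: pd.DataFrame,
    ages_weeks: pd.Series,
    amplicon_of: Mapping[str, str],
    k: int = 4,
) -> MultivariateClock:
    """Exhaustive search for the best k-CpG affine age model.

    Parameters
    ----------
    dnam_percent:
        Samples x CpGs methylation percentages (columns are CpG labels).
    ages_weeks:
        Chronological age per sample (index must match ``dnam_percent``).
    amplicon_of:
        CpG label -> amplicon label; each model uses k CpGs from k distinct
        amplicons (neighbouring CpGs on one amplicon are near-collinear, so
        mixing amplicons is both a biological and a numerical constraint).

    Every admissible combination is fit by ordinary least squares of age on
    the k methylation columns; the model minimising training MAD (mean
    absolute deviation, weeks) wins.  Ties break by higher r2, then by
    lexicographic CpG labels.  Rank-deficient designs are skipped.
    """
    missing = [c for c in dnam_percent.columns if c not in amplicon_of]
    if missing:
        raise ConfigurationError(f"CpGs without amplicon assignment: {missing[:5]}")
    by_amp: dict[str, list[str]] = {}
    for cpg in dnam_percent.columns:
        by_amp.setdefault(amplicon_of[cpg], []).append(cpg)
    for amp in by_amp:
        by_amp[amp] = sorted(by_amp[amp])
    if len(by_amp) < k:
        raise ConfigurationError(
            f"need >= {k} distinct amplicons, got {len(by_amp)}"
        )
    ages = ages_weeks.reindex(dnam_percent.index).to_numpy(dtype=float)
    if np.isnan(ages).any():
        raise ValidationError("every sample needs an age for multivariate fitting")
    if len(ages) < k + 2:
        raise ConfigurationError(f"need >= {k + 2} samples to fit {k} coefficients")

    X_full = dnam_percent.to_numpy(dtype=float)
    col_of = {c: i for i, c in enumerate(dnam_percent.columns)}
    best: tuple[float, float, tuple[str, ...]] | None = None  # (mad, -r2, labels)
    best_fit: tuple[np.ndarray, float, float] | None = None

    amps = sorted(by_amp)
    for amp_combo in itertools.combinations(amps, k):
        for cpgs in itertools.product(*(by_amp[a] for a in amp_combo)):
            labels = tuple(sorted(cpgs))
            idx = [col_of[c] for c in labels]
            X = np.column_stack([np.ones(len(ages)), X_full[:, idx]])
            if np.isnan(X).any():
                continue
            coef, _, rank, _ = np.linalg.lstsq(X, ages, rcond=None)
            if rank < k + 1:
                continue
            pred = X @ coef
            mad = float(np.mean(np.abs(pred - ages)))
            if np.var(pred) > 0 and np.var(ages) > 0:
                r2 = float(np.corrcoef(pred, ages)[0, 1] ** 2)
            else:
                r2 = 0.0
            key = (mad, -r2, labels)
            if best is None or key < best:
                best = key
                best_fit = (coef, mad, r2)

    if best_fit is None:
        raise ConfigurationError("every candidate design was rank-deficient")
    coef, mad, r2 = best_fit
    labels = best[2]
    return MultivariateClock(
        intercept=float(coef[0]),
        terms=[(c, float(b)) for c, b in zip(labels, coef[1:])],
        provenance="fitted",
        metadata={
            "train_mad_weeks": mad,
            "train_r2": r2,
            "n_samples": int(len(ages)),
            "n_combinations": combination_count(
                {c: amplicon_of[c] for c in dnam_percent.columns}, k
            ),
            "amplicons": {c: amplicon_of[c] for c in labels},
        },
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class PredictionMetrics:
    """Accuracy of age predictions.

    mae : median absolute error (weeks)
    mad : mean absolute deviation (weeks)
    r2  : squared Pearson correlation of predicted vs chronological age
    """

    mae: float
    mad: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"mae_weeks": self.mae, "mad_weeks": self.mad, "r2": self.r2,
                "n": self.n}


def evaluate(predictions, truths, allow_undefined_r2: bool = False) -> PredictionMetrics:
    """Compute MAE (median |error|), MAD (mean |error|) and r2.

    If either vector is constant, r2 is undefined: an
    :class:`UndefinedCorrelationError` is raised unless
    ``allow_undefined_r2``, in which case r2 is NaN and the absolute-error
    metrics are still returned.
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predictions and truths must be 1-D and equally long")
    if len(pred) < 2:
        raise ValidationError("evaluation needs >=2 pairs")
    err = np.abs(pred - true)
    mae = float(np.median(err))
    mad = float(np.mean(err))
    try:
        r2 = pearson_age_r(pred, true) ** 2
    except Exception:
        if not allow_undefined_r2:
            raise
        r2 = float("nan")
    return PredictionMetrics(mae=mae, mad=mad, r2=r2, n=len(pred))


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------


def save_clock(clock: EnsembleClock | MultivariateClock, path: str | Path) -> None:
    Path(path).write_text(json.dumps(clock.to_dict(), indent=2) + "\n")


def load_clock(path: str | Path) -> EnsembleClock | MultivariateClock:
    d = json.loads(Path(path).read_text())
    if d.get("type") == "ensemble":
        return EnsembleClock.from_dict(d)
    if d.get("type") == "multivariate":
        return MultivariateClock.from_dict(d)
    raise ValidationError(f"unknown clock type {d.get('type')!r} in {path}")
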