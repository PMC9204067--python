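"""Mouse-to-human mapping of age-associated CpGs.

Candidate mouse CpGs come with ~121-nt alignment windows in the human
genome (computed upstream with a genome browser's homology alignment; the
table is input data here, since alignments are assembly- and
version-dependent).  Human array CpGs falling inside a window are
categorized "homolog"; every other CpG on a chromosome carrying at least
one window gets the distance in bp to the center of the closest window
("distance" category).  Age association of the human CpGs is a Pearson
correlation with a t-test (t = r*sqrt((n-2)/(1-r^2)), n-2 df) and
Bonferroni correction; conserved candidates are homolog CpGs significant
in human whose direction of age-associated methylation change agrees with
both mouse strains.

Coordinates are 1-based and interval membership is inclusive at both ends.
A window's center is floor((start+end)/2).  Strand flips in the alignment
affect only how a region is displayed, never the distance computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .methylome_io import BetaMatrix

logger = logging.getLogger("muriclock")


def region_center(start: int, end: int) -> int:
    """Center of a 1-based inclusive interval, floor for even lengths."""
    return (start + end) // 2


def assign_human_cpgs(
    regions: pd.DataFrame, human_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Categorize human array CpGs against mouse homology windows.

    Parameters
    ----------
    regions:
        Homology table (columns mouse_probe_id, mouse_chrom, mouse_pos,
        human_chrom, human_start, human_end, strand_flip).
    human_annotation:
        Human probe annotation with probe_id, chrom, pos.

    Every CpG on a chromosome carrying at least one region is assigned to
    its nearest region: inside any window (inclusive) -> category
    ``homolog`` with distance 0; otherwise category ``distance`` with the
    bp distance to the closest window center.  Ties between equidistant
    regions break toward the lower start coordinate.  Regions on
    chromosomes absent from the annotation are skipped with a warning.
    """
    if regions.empty:
        raise ValidationError("homology table is empty")
    ann_by_chrom = dict(tuple(human_annotation.groupby("chrom", sort=False)))
    rows = []
    for chrom, reg in regions.groupby("human_chrom", sort=False):
        if chrom not in ann_by_chrom:
            logger.warning(
                "skipping %d homology region(s) on chromosome %s absent "
                "from the human annotation", len(reg), chrom,
            )
            continue
        reg = reg.sort_values(["human_start", "human_end"], kind="stable")
        starts = reg["human_start"].to_numpy()
        ends = reg["human_end"].to_numpy()
        centers = (starts + ends) // 2
        probes = ann_by_chrom[chrom]
        pos = probes["pos"].to_numpy()
        # (n_cpg, n_region) is tiny: a handful of windows per chromosome
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] <= ends[None, :])
        dist = np.abs(pos[:, None] - centers[None, :])
        for i, pid in enumerate(probes["probe_id"].to_numpy()):
            hit = np.flatnonzero(inside[i])
            if len(hit):
                # ties: lowest start first (rows pre-sorted by start)
                j = hit[0]
                category, d = "homolog", 0
            else:
                j = int(np.argmin(dist[i]))  # argmin takes first == lowest start
                category, d = "distance", int(dist[i, j])
            rows.append(
                {
                    "human_cpg_id": pid,
                    "mouse_probe_id": reg["mouse_probe_id"].iloc[j],
                    "category": category,
                    "distance_bp": d,
                    "human_chrom": chrom,
                    "human_pos": int(pos[i]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "human_cpg_id", "mouse_probe_id", "category", "distance_bp",
            "human_chrom", "human_pos",
        ],
    )


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the exact t transform.

    t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValidationError("correlation t-test needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def human_age_association(
    human_betas: BetaMatrix,
    ages_years: pd.Series,
    m: int | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Age correlation of every human CpG with Bonferroni-corrected t-test.

    ``m`` is the Bonferroni divisor; by default the number of CpGs
    analyzed, but the full array probe count can be passed to mimic
    correcting over the whole 450k array.  CpGs with zero beta variance
    are skipped with a warning.  Returns a DataFrame indexed by CpG id
    with pearson_r, n, t, p_raw, p_adj, significant.
    """
    x = ages_years.reindex(human_betas.sample_ids).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("every human sample needs an age")
    if len(x) < 10:
        raise ValidationError("human age association needs >=10 samples")
    Y = human_betas.values.to_numpy(dtype=float)
    M = ~np.isnan(Y)
    n = M.sum(axis=1)
    Xm = np.where(M, x, 0.0)
    Y0 = np.where(M, Y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = Xm.sum(1), Y0.sum(1)
        cov = (Xm * Y0).sum(1) - sx * sy / n
        varx = (Xm * Xm).sum(1) - sx * sx / n
        vary = (Y0 * Y0).sum(1) - sy * sy / n
        r = cov / np.sqrt(varx * vary)
    ok = (n >= 3) & (varx > 0) & (vary > 0)
    if (~ok).any():
        logger.warning("skipping %d zero-variance/underpowered CpG(s)",
                       int((~ok).sum()))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p_raw = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p_raw = np.where(np.abs(r) >= 1.0, 0.0, p_raw)
    r[~ok] = np.nan
    t[~ok] = np.nan
    p_raw[~ok] = np.nan
    divisor = m if m is not None else int(ok.sum())
    p_adj = np.minimum(p_raw * divisor, 1.0)
    out = pd.DataFrame(
        {
            "pearson_r": r,
            "n": n.astype(int),
            "t": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        },
        index=human_betas.values.index,
    )
    out.loc[~ok, "significant"] = False
    return out


def conserved_candidates(
    assignments: pd.DataFrame,
    mouse_results: dict[str, pd.DataFrame],
    human_results: pd.DataFrame,
) -> pd.DataFrame:
    """Join homolog assignments with mouse and human age correlations.

    ``mouse_results`` maps strain -> per-probe table with a ``pearson_r``
    column (indexed by probe_id).  Only homolog-category human CpGs that
    are significant in ``human_results`` are reported.  A row is
    ``sign_consistent`` when the human correlation and both strains'
    correlations share one sign — the hallmark of an age-associated change
    conserved across species.
    """
    strains = sorted(mouse_results)
    hom = assignments[assignments["category"] == "homolog"]
    rows = []
    for _, a in hom.iterrows():
        cpg, probe = a["human_cpg_id"], a["mouse_probe_id"]
        if cpg not in human_results.index or not bool(
            human_results.at[cpg, "significant"]
        ):
            continue
        row = {
            "mouse_probe_id": probe,
            "human_cpg_id": cpg,
            "human_chrom": a["human_chrom"],
            "human_pos": a["human_pos"],
            "r_human": float(human_results.at[cpg, "pearson_r"]),
            "p_adj_human": float(human_results.at[cpg, "p_adj"]),
        }
        signs = [np.sign(row["r_human"])]
        for s in strains:
            tab = mouse_results[s]
            r = float(tab.at[probe, "pearson_r"]) if probe in tab.index else np.nan
            row[f"r_{s}"] = r
            signs.append(np.sign(r))
        row["sign_consistent"] = bool(
            np.all(~np.isnan(signs)) and len(set(signs)) == 1 and signs[0] != 0
        )
        rows.append(row)
    cols = (
        ["mouse_probe_id"]
        + [f"r_{s}" for s in strains]
        + ["human_chrom", "human_pos", "human_cpg_id", "r_human", "p_adj_human",
           "sign_consistent"]
    )
    return pd.DataFrame(rows, columns=cols)
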