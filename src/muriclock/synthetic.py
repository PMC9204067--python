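"""Synthetic two-strain methylation cohorts with known ground truth.

The generator emulates the statistical structure the rest of the package
assumes, so the full pipeline can run and be validated without any
download: two inbred strains (B6, DBA) with different lifespans, probes in
four genomic-context classes, and planted probe classes —

``aging_shared``
    linear methylation trend with the same sign in both strains (the
    cross-strain clock candidates);
``aging_private``
    trend in one strain only;
``antagonistic``
    opposite-sign trends in the two strains (observed between real mouse
    strains and the reason candidate selection intersects both);
``strain_offset``
    constant between-strain shift (the differential-methylation class);
``null``
    baseline plus noise only.

Trends are linear in age normalized to the strain's sampled age span, with
a total beta change of ``effect_size`` over that span, so a planted effect
of 0.5 should yield slope_CpG ~ 0.5.  Noise is truncated Gaussian on the
beta scale (added then clipped to [0, 1]): the package consumes
post-normalization betas, and only the second-moment behaviour of the
noise matters to the statistics under test.  Default cohort sizes copy a
realistic array study design: 12 B6 females plus 6 male and 6 female
DBA/2J mice, ages spread evenly across each strain's usable span.

Every output is a deterministic function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .methylome_io import BetaMatrix, VALID_CONTEXTS

#: Baseline beta ranges per genomic context: islands are mostly
#: unmethylated, open sea mostly methylated, shores/shelves in between.
CONTEXT_BASELINE = {
    "island": (0.05, 0.30),
    "shore": (0.20, 0.60),
    "shelf": (0.30, 0.70),
    "open_sea": (0.50, 0.95),
}

PROBE_CLASSES = (
    "aging_shared",
    "aging_private_B6",
    "aging_private_DBA",
    "antagonistic",
    "strain_offset",
    "null",
    "null_xy",
)


@dataclass
class CohortSpec:
    """Parameters of a synthetic mouse cohort.

    ``n_samples`` maps (strain, sex) -> count; ``age_range_weeks`` maps
    strain -> (youngest, oldest) in weeks.  Probe-class counts are absolute
    numbers out of ``n_probes``; ``effect_size`` is the total beta change
    of an aging probe over the strain's age span; ``offset_range`` the
    uniform range of between-strain shifts for strain_offset probes;
    ``noise_sd`` the beta-scale Gaussian noise; ``island_direction_bias``
    the per-strain probability that a strain-private island probe
    hypermethylates with age (open sea gets the complementary bias);
    ``shared_island_bias`` the same for cross-strain shared probes.
    """

    n_samples: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {("B6", "F"): 12, ("DBA", "M"): 6, ("DBA", "F"): 6}
    )
    age_range_weeks: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"B6": (7.0, 91.0), "DBA": (6.0, 76.0)}
    )
    n_probes: int = 20_000
    n_aging_shared: int = 100
    n_aging_strain_private: int = 50  # per strain
    n_antagonistic: int = 25
    n_strain_offset: int = 1_000
    n_xy: int = 200
    effect_size: float = 0.5
    offset_range: tuple[float, float] = (0.2, 0.5)
    noise_sd: float = 0.02
    context_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "island": 0.30, "shore": 0.25, "shelf": 0.10, "open_sea": 0.35
        }
    )
    island_direction_bias: Mapping[str, float] = field(
        default_factory=lambda: {"B6": 0.8, "DBA": 0.2}
    )
    shared_island_bias: float = 0.8
    frac_snp: float = 0.01
    frac_cross_reactive: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.n_aging_shared
            + 2 * self.n_aging_strain_private
            + self.n_antagonistic
            + self.n_strain_offset
            + self.n_xy
        )
        if planted > self.n_probes:
            raise ValidationError(
                f"probe classes ({planted}) exceed n_probes ({self.n_probes})"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if abs(sum(self.context_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("context_mix proportions must sum to 1")
        if set(self.context_mix) != set(VALID_CONTEXTS):
            raise ValidationError(f"context_mix must cover {VALID_CONTEXTS}")
        for strain, (lo, hi) in self.age_range_weeks.items():
            if not (0 < lo < hi):
                raise ValidationError(f"bad age range for {strain}: ({lo}, {hi})")
        for (strain, _sex), n in self.n_samples.items():
            if strain not in self.age_range_weeks:
                raise ValidationError(f"no age range for strain {strain!r}")
            if n < 1:
                raise ValidationError("every group needs >=1 sample")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def _direction(rng: np.random.Generator, context: str, island_bias: float) -> int:
    """Draw a trend sign: islands biased toward +, open sea the mirror image."""
    if context == "island":
        p = island_bias
    elif context == "open_sea":
        p = 1.0 - island_bias
    else:
        p = 0.5
    return 1 if rng.random() < p else -1


def generate_mouse_cohort(
    spec: CohortSpec,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (beta matrix, sample sheet, probe annotation, truth table).

    The truth table records, per probe: class, context, per-strain trend
    direction, effect size, and the strain offset, so tests can score
    recovery exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- samples -----------------------------------------------------------
    sample_rows = []
    for (strain, sex), n in sorted(spec.n_samples.items()):
        lo, hi = spec.age_range_weeks[strain]
        ages = np.linspace(lo, hi, n)
        for i, age in enumerate(ages):
            sample_rows.append(
                {
                    "sample_id": f"{strain}_{sex}_{i:02d}",
                    "strain": strain,
                    "sex": sex,
                    "age_weeks": round(float(age), 1),
                }
            )
    sheet = pd.DataFrame(sample_rows)
    strains = sorted({s for s, _ in spec.n_samples})

    # per-sample normalized age on the strain's span (trend covariate)
    xs = np.empty(len(sheet))
    for strain in strains:
        lo, hi = spec.age_range_weeks[strain]
        m = (sheet["strain"] == strain).to_numpy()
        xs[m] = (sheet.loc[m, "age_weeks"].to_numpy() - lo) / (hi - lo)

    # --- probes ------------------------------------------------------------
    n = spec.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    classes = np.full(n, "null", dtype=object)
    counts = {
        "aging_shared": spec.n_aging_shared,
        "aging_private_B6": spec.n_aging_strain_private,
        "aging_private_DBA": spec.n_aging_strain_private,
        "antagonistic": spec.n_antagonistic,
        "strain_offset": spec.n_strain_offset,
        "null_xy": spec.n_xy,
    }
    order = rng.permutation(n)
    pos0 = 0
    for cls, k in counts.items():
        classes[order[pos0:pos0 + k]] = cls
        pos0 += k

    contexts = rng.choice(
        VALID_CONTEXTS, size=n, p=[spec.context_mix[c] for c in VALID_CONTEXTS]
    )
    xy_mask = classes == "null_xy"
    chroms = rng.integers(1, 20, size=n).astype(str)
    chroms[xy_mask] = rng.choice(["X", "Y"], size=int(xy_mask.sum()))
    positions = rng.integers(1, 150_000_000, size=n)
    is_snp = rng.random(n) < spec.frac_snp
    is_cross = rng.random(n) < spec.frac_cross_reactive
    # planted aging probes stay clean so their fate is decided by statistics,
    # not by the SNP/cross-reactive prefilter
    clean = np.isin(classes, ["aging_shared", "aging_private_B6",
                              "aging_private_DBA", "antagonistic"])
    is_snp[clean] = False
    is_cross[clean] = False

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": positions,
            "context": contexts,
            "gene": "",
            "is_snp": is_snp,
            "is_cross_reactive": is_cross,
        }
    )

    # --- per-probe truth ----------------------------------------------------
    dir_b6 = np.zeros(n, dtype=int)
    dir_dba = np.zeros(n, dtype=int)
    effect = np.zeros(n)
    offset = np.zeros(n)
    baseline = np.empty(n)
    for i in range(n):
        cls, ctx = classes[i], contexts[i]
        lo, hi = CONTEXT_BASELINE[ctx]
        if cls == "aging_shared":
            d = _direction(rng, ctx, spec.shared_island_bias)
            dir_b6[i] = dir_dba[i] = d
            effect[i] = spec.effect_size
        elif cls == "aging_private_B6":
            dir_b6[i] = _direction(rng, ctx, spec.island_direction_bias["B6"])
            effect[i] = spec.effect_size
        elif cls == "aging_private_DBA":
            dir_dba[i] = _direction(rng, ctx, spec.island_direction_bias["DBA"])
            effect[i] = spec.effect_size
        elif cls == "antagonistic":
            d = _direction(rng, ctx, spec.island_direction_bias["B6"])
            dir_b6[i], dir_dba[i] = d, -d
            effect[i] = spec.effect_size
        elif cls == "strain_offset":
            offset[i] = rng.uniform(*spec.offset_range) * rng.choice([-1, 1])
        # keep baseline + trend/offset clear of the beta bounds so planted
        # effects are not flattened by saturation/clipping
        margin = max(0.02, 3.0 * spec.noise_sd)
        room_lo, room_hi = margin, 1.0 - margin
        dmin = min(0.0, dir_b6[i] * effect[i], dir_dba[i] * effect[i], offset[i])
        dmax = max(0.0, dir_b6[i] * effect[i], dir_dba[i] * effect[i], offset[i])
        b_lo = max(lo, room_lo - dmin)
        b_hi = min(hi, room_hi - dmax)
        if b_lo >= b_hi:  # effect larger than the context band allows
            b_lo, b_hi = -dmin, 1.0 - dmax
        if b_lo >= b_hi:  # swing exceeds [0, 1] entirely (antagonistic, large
            baseline[i] = 0.5 * (b_lo + b_hi)  # effect): center, clip later
        else:
            baseline[i] = rng.uniform(b_lo, b_hi)

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "class": classes,
            "context": contexts,
            "chrom": chroms,
            "pos": positions,
            "baseline": baseline,
            "direction_B6": dir_b6,
            "direction_DBA": dir_dba,
            "effect": effect,
            "strain_offset": offset,
        }
    )

    # --- beta values ---------------------------------------------------------
    is_dba = (sheet["strain"] == "DBA").to_numpy()
    direction = np.where(is_dba[None, :], dir_dba[:, None], dir_b6[:, None])
    mean = (
        baseline[:, None]
        + direction * effect[:, None] * xs[None, :]
        + np.where(is_dba[None, :], offset[:, None], 0.0)
    )
    values = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    np.clip(values, 0.0, 1.0, out=values)
    matrix = BetaMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sheet["sample_id"].to_numpy())
    )
    return matrix, sheet, annotation, truth


# ---------------------------------------------------------------------------
# Human cohort + homology table
# ---------------------------------------------------------------------------


def generate_human_cohort(
    linked_truth: pd.DataFrame,
    n_samples: int = 656,
    age_range_years: tuple[float, float] = (19.0, 101.0),
    conservation_fraction: float = 0.5,
    n_null_probes: int = 2_000,
    effect_scale: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[BetaMatrix, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Generate a human blood cohort linked to the mouse ground truth.

    Each shared mouse aging probe (class ``aging_shared`` in
    ``linked_truth``) gets one human CpG; a ``conservation_fraction`` of
    them carry a sign-matched age trend (mouse effect scaled by
    ``effect_scale`` over the human age range), the rest are null, as are
    ``n_null_probes`` additional background CpGs.  The defaults mirror a
    large public blood cohort: 656 donors aged 19-101 years.

    Returns (beta matrix, ages in years, human annotation, link table);
    the link table maps mouse_probe_id <-> human_cpg_id with a
    ``conserved`` flag.
    """
    if not 0.0 <= conservation_fraction <= 1.0:
        raise ValidationError("conservation_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = linked_truth[linked_truth["class"] == "aging_shared"].reset_index(
        drop=True
    )
    n_linked = len(shared)
    n_conserved = int(round(conservation_fraction * n_linked))
    conserved = np.zeros(n_linked, dtype=bool)
    conserved[rng.choice(n_linked, size=n_conserved, replace=False)] = True

    sample_ids = [f"H{i:04d}" for i in range(n_samples)]
    ages = pd.Series(
        np.round(rng.uniform(*age_range_years, size=n_samples), 1),
        index=sample_ids, name="age_years",
    )
    u = (ages.to_numpy() - age_range_years[0]) / (
        age_range_years[1] - age_range_years[0]
    )

    link_rows, ann_rows, beta_rows, ids = [], [], [], []
    for i, row in shared.iterrows():
        hid = f"hcg{i:06d}"
        # deterministic "homologous" coordinate derived from the mouse locus
        hchrom = str(row["chrom"])
        hpos = int(row["pos"]) + 10_000_000
        ann_rows.append(
            {"probe_id": hid, "chrom": hchrom, "pos": hpos, "context": row["context"],
             "gene": "", "is_snp": False, "is_cross_reactive": False}
        )
        b_lo, b_hi = CONTEXT_BASELINE[row["context"]]
        eff = float(row["effect"]) * effect_scale * int(row["direction_B6"])
        base = rng.uniform(
            max(b_lo, 0.02 - min(eff, 0.0)), min(b_hi, 0.98 - max(eff, 0.0))
        )
        mean = base + (eff * u if conserved[i] else np.zeros_like(u))
        beta_rows.append(mean)
        ids.append(hid)
        link_rows.append(
            {
                "mouse_probe_id": row["probe_id"],
                "human_cpg_id": hid,
                "human_chrom": hchrom,
                "human_pos": hpos,
                "conserved": bool(conserved[i]),
            }
        )
    for j in range(n_null_probes):
        hid = f"hnull{j:06d}"
        ann_rows.append(
            {"probe_id": hid, "chrom": str(rng.integers(1, 23)),
             "pos": int(rng.integers(1, 240_000_000)), "context": "open_sea",
             "gene": "", "is_snp": False, "is_cross_reactive": False}
        )
        beta_rows.append(np.full(n_samples, rng.uniform(0.1, 0.9)))
        ids.append(hid)

    values = np.asarray(beta_rows) + rng.normal(
        0.0, noise_sd, size=(len(ids), n_samples)
    )
    np.clip(values, 0.0, 1.0, out=values)
    betas = BetaMatrix(pd.DataFrame(values, index=ids, columns=sample_ids))
    annotation = pd.DataFrame(ann_rows)
    links = pd.DataFrame(link_rows)
    return betas, ages, annotation, links


def generate_homology_table(
    links: pd.DataFrame,
    mouse_truth: pd.DataFrame,
    window_nt: int = 121,
    attrition: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate alignment windows for the linked mouse candidate CpGs.

    Each linked mouse probe gets a ``window_nt``-long window on the human
    genome.  With probability ``attrition`` the window is displaced so it
    contains no array CpG, emulating the real-world loss when most mouse
    homolog regions lack a probe on the human array; otherwise the window
    covers the linked human CpG at a random interior offset.
    """
    if not 0.0 <= attrition <= 1.0:
        raise ValidationError("attrition must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mouse = mouse_truth.set_index("probe_id")
    rows = []
    for _, link in links.iterrows():
        hpos = int(link["human_pos"])
        if rng.random() < attrition:
            start = hpos + 5_000 + int(rng.integers(0, 1_000))
        else:
            start = hpos - int(rng.integers(0, window_nt))
        start = max(1, start)
        mp = link["mouse_probe_id"]
        rows.append(
            {
                "mouse_probe_id": mp,
                "mouse_chrom": str(mouse.at[mp, "chrom"]),
                "mouse_pos": int(mouse.at[mp, "pos"]),
                "human_chrom": link["human_chrom"],
                "human_start": start,
                "human_end": start + window_nt - 1,
                "strand_flip": bool(rng.random() < 0.5),
            }
        )
    return pd.DataFrame(rows)
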