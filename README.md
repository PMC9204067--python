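# muriclock

Epigenetic clocks estimate chronological age from DNA methylation levels
(beta values, the methylated fraction in [0, 1]) at selected CpG sites.
Mouse clocks are usually trained within a single inbred strain, but inbred
strains differ extensively in their methylomes — including CpGs whose
methylation moves in *opposite* directions with age in different strains —
so a clock useful beyond one strain has to be built on the cross-strain
consensus of age-associated CpGs.

`muriclock` is a library and command-line tool for building, applying and
validating such clocks from processed beta-value matrices (e.g. Infinium
Mouse Methylation BeadChip exports). It is aimed at groups running mouse
aging studies on methylation arrays or targeted pyrosequencing assays. It
implements:

- **QC filtering** of beta matrices: detection-p, probe/sample missingness,
  X/Y removal.
- **Cross-strain candidate selection** by the slope statistic
  `slope_CpG = Σ(xᵢ−x̄)(yᵢ−ȳ) / Σ(xᵢ−x̄)²`, the least-squares slope of beta
  *y* on age *x* normalized to [0, 1] within each (strain, sex) group. With
  both axes on the unit scale, `|slope| > 0.3` selects CpGs whose absolute
  methylation changes by more than 30% over the observed lifespan; candidates
  must pass the threshold independently in both strains (C57BL/6 and DBA/2J
  have different life expectancies, 2.42 vs 1.87 years, hence the per-strain
  age normalization).
- **A single-CpG ensemble clock**: one univariate linear model per candidate
  CpG (normalized age on beta); the prediction is the mean of the per-CpG age
  estimates mapped back to weeks.
- **A multivariate pyrosequencing clock**: exhaustive search over all
  combinations of 4 CpGs from 4 distinct PCR amplicons, ordinary least
  squares of age (weeks) on methylation (%), minimizing the training MAD —
  plus the frozen published B6 blood clock
  `age = 167.4533 + 1.2421α + 0.9824β − 1.3110γ − 1.6088δ`.
- **Strain methylome comparison**: pairwise sample correlation matrices, a
  per-CpG Wilcoxon rank-sum screen with Bonferroni control, a Mann-Whitney
  sex-effect test on prediction errors, and the global
  methylated-fraction-vs-age trend.
- **Mouse→human homology mapping**: categorizing human array CpGs against
  ~121-nt alignment windows ("homolog" inside a window, otherwise distance to
  the nearest window center), with a correlation t-test
  `t = r·√((n−2)/(1−r²))` and Bonferroni correction on the human side.
- **A synthetic cohort generator** with planted ground truth (shared,
  strain-private, antagonistic and strain-offset CpGs), so the entire
  pipeline runs and is tested without any download.

Evaluation metrics follow the convention that **MAE is the median absolute
error and MAD the mean absolute deviation** of predicted minus chronological
age, in weeks; r² is the squared Pearson correlation of predicted versus
chronological age.

## Worked example

```python
import muriclock as mc

# a two-strain cohort: 12 B6 females + 12 DBA/2J (6M/6F), 20,000 probes,
# 100 planted cross-strain aging CpGs (effect 0.5, noise sd 0.02)
matrix, sheet, ann, truth = mc.generate_mouse_cohort(mc.CohortSpec(seed=1))
filtered, report = mc.qc_filter(matrix, ann, drop_xy=True)
ages = mc.normalize_ages(sheet)

sets = []
for strain in ("B6", "DBA"):
    ids = sheet.loc[sheet.strain == strain, "sample_id"]
    sets.append(mc.select_candidates(filtered.subset(samples=ids), ages, strain=strain))
venn = mc.intersect_candidates(*sets)
print(venn.counts())
# {'shared': 125, 'only_B6': 50, 'only_DBA': 50}

b6 = sheet.loc[sheet.strain == "B6", "sample_id"]
dba = sheet.loc[sheet.strain == "DBA", "sample_id"]
clock = mc.fit_ensemble(filtered.subset(probes=venn.shared, samples=b6), ages)
preds = mc.predict_ensemble_matrix(clock, filtered.subset(probes=venn.shared, samples=dba), sheet)
truth_ages = sheet.set_index("sample_id")["age_weeks"].reindex(preds.index)
print(mc.evaluate(preds, truth_ages).to_dict())
# {'mae_weeks': 13.93, 'mad_weeks': 13.98, 'r2': 0.9998, 'n': 12}
```

The intersection of the per-strain screens contains all 100 planted shared
CpGs plus the 25 planted antagonistic CpGs (they exceed the threshold in both
strains, with opposite signs). The B6-trained ensemble transferred to DBA
ranks ages almost perfectly (r² ≈ 1.0) but carries a systematic offset
(MAD ≈ 14 weeks) — exactly the effect of antagonistic CpGs pulling each
prediction in the wrong direction for the other strain; dropping them, or
training on a cohort without antagonistic trends, removes the offset.

The frozen published 4-CpG clock evaluates directly on pyrosequencing
methylation percentages:

```python
clock = mc.published_b6_clock()
mc.predict_multivariate(clock, [5.0, 41.5, 22.3, 60.2])   # -> 88.35 weeks
```

The same workflow is available from the shell:

```sh
muriclock simulate --out-dir sim --seed 1
muriclock qc --betas sim/betas.tsv --annotation sim/annotation.csv --out-dir qc
muriclock select --betas qc/betas_qc.tsv --samples sim/samples.csv --out-dir sel
muriclock train-ensemble --betas qc/betas_qc.tsv --samples sim/samples.csv \
    --probes sel/intersection.txt --out clock.json
muriclock run --out-dir full_run --seed 1      # the whole pipeline at once
```

## Layout

- `src/muriclock/methylome_io.py` — beta matrices, sample sheets,
  annotations, homology tables, QC.
- `src/muriclock/age_association.py` — age normalization, `slope_cpg`,
  per-strain screens, intersection, genomic-context summaries.
- `src/muriclock/clocks.py` — ensemble and multivariate clocks, the
  published model, MAE/MAD/r² evaluation.
- `src/muriclock/strain_comparison.py` — correlation matrix, rank-sum
  screen, sex-effect test, global methylation trend.
- `src/muriclock/homology.py` — homolog-region assignment, human age
  association, conserved-candidate report.
- `src/muriclock/synthetic.py` — mouse/human cohort and homology-table
  generators with ground truth.
- `src/muriclock/cli.py` — subcommands wiring the stages together.

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
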