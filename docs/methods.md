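# Methods

`luxscreen` implements the statistical layer of a two-stage dual-luciferase
production screen in budding yeast. Stage 1 screens a library of ribosomal
variant strains (RVS) — diploid strains each heterozygously deleted for one
ribosomal-protein (RP) gene — for a strain whose altered ribosome pool
*selectively* boosts production of a Firefly-luciferase-fused protein of
interest (TE-FF) while leaving the independently expressed Renilla control
(REN) unchanged; the deleted gene's protein is then a candidate target
ribosomal protein. Stage 2 takes small-molecule candidate ligands of that
target and triages them on a dose panel read with the homogeneous Dual-Glo
assay, normalized to an untreated control.

## Measurement model

All analysis treats luminescence counts as positive with multiplicative
noise. The simulator draws a readout for group *g*, reporter *r*,
biological replicate (culture) *b*, technical replicate *t* as

    y = calib_r · m_{g,r} · B_{g,b} · T_{g,r,b,t}

with `m` the planted fold effect and `B`, `T` independent mean-one
lognormal factors (log-mean −σ²/2, so E[y] = calib·m exactly and planted
multipliers are unbiased targets). The total log-variance
σ² = ln(1 + cv_total²) is split between the culture and measurement level
by `bio_fraction`. `B` is shared between the FF and REN readouts of the
same culture: both reporters ride on the same cell density and lysis
efficiency, which is the covariation a dual-reporter design exists to
cancel. A visible consequence is that a null screen already shows a
positive FF–REN concordance across strains (ρ ≈ 0.5–0.6), the pattern real
screens of this kind report.

Assumptions: no plate-position or batch effects, no heteroscedasticity
across groups, no growth differences among viable strains, and viability
is a hard flag rather than a graded phenotype. Real readout tables violate
these in ways the synthetic data cannot reveal; passing tests therefore
demonstrate correctness of the inference given this noise model, not
robustness to instrument artefacts.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `calib_ff`, `calib_ren` (screen) | 1.0e4, 8.0e7 | counts | wild-type calibration means of the screen-format assay |
| `calib_ff`, `calib_ren` (Dual-Glo) | 2.5e3, 1.7e5 | counts | wild-type calibration means of the compound assay |
| `cv_total` | 0.24 | — | back-solved from the screen's 48% two-fold SD of wild-type-normalized FF measurements |
| `bio_fraction` | 0.5 | — | no published variance decomposition; an even split is the neutral choice |
| `n_bio × n_tech` (screen) | 2 × 3 | — | two independent transformations, three technical reads each |
| replicates (panel) | 3 | — | triplicate wells, modelled as independent cultures (each well is grown and treated separately) |
| `doses` | 1 nM…100 µM | M | six-decade grid; the top dose is where the reference compound acts |
| `alpha` | 0.05 | — | all per-test and FDR levels |
| Grubbs `alpha`, policy, `min_n` | 0.05, iterative, 4 (3 for panels) | — | two-sided test, repeated until clean, never trimming below a usable mean/SD |

Dose–effect interpolation: `m(d) = 1 + (m_top − 1)(d/d_max)^h` with
exponent `h = 1` by default — anchored so the top-dose multiplier equals
the planted `m_top` exactly (recovery targets stay well-defined) and
effects fade smoothly to null toward low doses, concentrating the visible
effect at the top decade as the reference compound shows. Hill-type
shapes can be emulated via `h`.

## Stage 1: screen inference

1. **Viability filter** — readouts of non-viable strains are dropped; with
   the packaged 137-gene library (19 single-copy genes, 59 duplicated A/B
   paralog pairs; 9 strains non-viable) this leaves 129 usable vehicles.
   Paralogs are analyzed independently throughout.
2. **Outlier QC** — per group × reporter, a two-sided Grubbs test
   (`G = max|x−x̄|/s`, critical value `((n−1)/√n)·√(t²/(n−2+t²))` at
   `α/(2n)`) applied iteratively on raw counts, with a floor of usable
   values per group.
3. **Normalization** — per-strain folds are ratios of QC-filtered
   arithmetic means to the wild-type means; the wild type sits at (1, 1)
   in fold space. This estimator is the field convention but carries a
   small upward ratio bias, E[x̄_S/x̄_W] ≈ m·(1 + CV²(x̄_W)) — about +2%
   at the default replicate structure — documented rather than corrected.
4. **Testing** — strain vs wild type per reporter on log counts. Because
   technical replicates are nested within cultures, the test statistic
   compares culture-level mean log counts, standardized by a culture-level
   SD pooled across all strains (each strain contributes n_bio − 1 df;
   with two cultures per strain no per-strain variance is usable on its
   own). Per reporter, p-values are Benjamini–Hochberg adjusted across
   strains. With no nesting (single culture) the code falls back to a
   Welch t-test on individual log readouts.
5. **Concordance** — Pearson ρ between FF and REN folds across strains
   (wild type excluded), the screen-level summary of how tightly the two
   reporters co-vary.
6. **Inert circle** — radius = 2 × SD of wild-type-normalized FF
   measurements. The default estimator pools log-scale variance
   components (culture + technical, one-way random effects) across every
   group and converts to a CV via cv² = exp(σ²) − 1: each group's scatter
   estimates the same assay noise, whereas the wild-type group's own six
   clustered readouts give a radius anywhere between ~0.1 and ~0.9.
   `radius_source="wildtype"` restores the literal construction, and
   `inert_radius()` computes it for any supplied measurement vector. The
   REN "wild-type band" uses the same construction on REN.
7. **Classification** — exactly one class per strain: `inert` when the
   Euclidean distance from (1, 1) is within the radius; otherwise
   `selective_hit` when the FF fold clears the circle on the FF axis alone
   (ff_fold − 1 > radius) with FDR-significant FF shift, REN inside the
   band and REN not significant; otherwise the quadrant of the
   (FF, REN) shift signs. Distance is Euclidean because the inert region
   is drawn as a literal circle; a strain moving both reporters equally
   can never be a selective hit.

## Stage 2: compound triage

Per compound and dose, folds and Welch tests on log counts against the
shared untreated control (FF one-sided for an increase — the assay screens
for boosts — REN two-sided). Dose dependence is a one-sided test for a
positive slope of log counts against *relative* dose d/d_max over all
treated replicates, standardized by a log-SD pooled across every panel
group (≈350 df; with triplicates no per-group variance is usable). The
linear dose scale matches the saturating shape of m(d); a log-dose
regressor severely underfits it and costs most of the power at the
reference effect size (1.7× at the top dose with triplicates is only a
~3.5σ effect — there is no power to waste). `trend_test()` also offers the
fold-level and log-dose variants.

Triage: a compound is **active** when its BH-adjusted (across the panel's
compounds) FF trend q-value is ≤ α and its top-dose FF fold exceeds 1;
an active compound is a **selective hit** when the top-dose FF shift is
individually significant and REN is quiet (p > α) at every dose, else
**minor_active**; everything else is **inactive**. Gating activity on the
panel-adjusted trend keeps the expected number of false actives on an
all-null panel α-governed, which per-dose significance reading alone does
not (six uncorrected per-dose tests would make ~25% of null compounds
"active"). At the reference conditions the selective/minor label within
the active set remains noisy — with triplicates at 24% CV the per-dose
REN tests have limited power — but the active/inactive boundary is stable.

## Numerical and edge-case choices

- `cv_total = 0` is an exact zero-noise limit (counts equal calibration ×
  multiplier), used by tests as an oracle.
- Degenerate two-sample tests (zero variance in both groups) return p = 1
  for equal means and p = 0 for a deterministic difference, keeping FDR
  adjustment defined.
- Grubbs on a constant group flags nothing; groups with n < 3 pass QC
  untouched; iterative removal stops before the usable count drops below
  `min_n`.
- CSV writes are byte-deterministic (sorted rows, `%.17g` floats) and
  reads round-trip float64 exactly.
- Strains with fewer than `min_n` usable readouts on either reporter are
  excluded from the points table and listed in the result.
- All simulation is driven by a single integer seed through
  `numpy.random.default_rng`; identical configuration and seed reproduce
  tables bit for bit.

## Verification problem sizes

Calibration checks use 10,000 independent wild-type draws; recovery checks
average 200 screens/panels at consecutive seeds; null calibration uses
40–100 seeded replicates. These sizes put Monte-Carlo error well below
the tolerances being checked while keeping the whole suite fast.

## Known limitations

- The ratio-of-means fold estimator is ~2% biased upward at two cultures
  per strain; averaged recovery lands near 2.75/2.7 and 1.73/1.70.
- With triplicates at 24% CV, a 1.7× top-dose compound is a borderline
  detection: the panel-adjusted trend gate recovers it in roughly 70–85%
  of seeds, and an "exactly 3 actives" outcome on the reference panel
  composition occurs in roughly two-thirds of seeds.
- The packaged RP gene list is a curated naming fixture (including the
  P-stalk proteins to reach the 78-protein/137-gene count); protein labels
  are display names, not strict unified nomenclature.
- No instrument-file ingestion, plate-layout modelling, growth/viability
  modelling, EC50 fitting, or chemistry — compounds are opaque ids.
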