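# Methods

## Scope

serodx implements the computational side of a multi-marker autoantibody
panel study: calling panel positivity from titrated, calibrated assay
signals; choosing per-antigen cutoffs by constrained Monte-Carlo direct
search; correcting apparent specificity for occult cancers in high-risk
control populations; and the diagnostic performance statistics reported
around such a design. The wet-lab side (antigen production, ELISA
protocol, optical-density-to-RU calibration) is out of scope: RU values are
taken as already calibrated inputs.

## Positivity model

A measurement is a titration series (coat level 0…k−1, RU ≥ 0), with the
highest coat level as the reference point scored against the cutoff.
Positivity requires two things:

1. **Dose response.** A genuine autoantibody signal rises with antigen
   coat concentration. The published criterion is qualitative, so this
   package operationalizes it as Spearman rank correlation between RU and
   coat level ≥ 0.8 by default (configurable, and logged in every search
   report). With four titration points this admits at most one adjacent
   rank inversion; a flat series (zero RU variance) is defined to carry no
   evidence (ρ := 0). The check needs ≥ 3 points.
2. **Cutoff exceedance.** Strictly greater than the cutoff; a tie is
   negative. The convention is arbitrary but fixed, and the optimizer uses
   the same calling path, so searches and validations are internally
   consistent.

Panel positivity is the OR over member antigens. SOX2-B and SOX2-N (the
same protein under two expression tags) are carried as distinct antigen
codes; a panel names which one it uses.

## Synthetic cohort generator

The generator stands in for case–control and prospective at-risk
populations and defines the conditions under which the pipeline is tested.

* **Signal model.** Per antigen, RU at the reference level is a
  two-component log-normal mixture: background (default log-mean 0, log-sd
  0.5) and elevated (default log-mean 3, log-sd 0.5), the elevated
  component stochastically dominating. Elevation prevalence per
  (population, antigen) defaults to the per-antigen positivity percentages
  of the optimization case–control set (e.g. p53 13% in cancers, 3% in
  normals). `true_cutoffs()` returns the geometric midpoint of the two
  log-means; with the default separation, positivity at those cutoffs
  equals the elevation prevalence to within ~0.1%.
* **Correlation.** Elevation indicators share one latent Gaussian
  "immunogenicity" factor with loading √ρ (Gaussian copula), ρ = 0.3 by
  default. This changes joint panel behaviour without moving marginals:
  under independence panel positivity is 1 − ∏(1 − p_i) (0.398 at the
  non-small-cell seven-assay rates); positive ρ pulls it down toward the
  largest single-antigen rate. ρ is deliberately flagged as uncalibrated —
  printed tables give marginals only, and the fact that the printed panel
  positivity (38%) sits below the independence closed form (39.8%) is the
  one hint that real antigens are positively correlated.
* **Titration shape.** Elevated series decay geometrically below the
  reference level (default 40% RU drop per dilution step); background
  series are flat. Both carry multiplicative log-normal noise (sd 0.05 on
  the log scale) at non-reference levels, so background series pass the
  dose-response check only at the chance rate of a random permutation.
* **Occult cancers.** Each control/at-risk subject is independently truly
  cancerous with probability `occult_rate` (default 0.027, the prevalence-
  round figure for high-risk screening populations); occult subjects keep
  their disease-free label but draw elevations at the cancer rates, and are
  flagged in a truth table only the generator can produce.
* **Demographics** (age, gender, smoking mix) default to the printed
  cohort tables per population and are sampled independently of antigen
  status except through occult status, consistent with the absence of any
  reported autoantibody–demographic association. Not emulated: plate and
  batch effects, assay imprecision beyond the noise model, antigen-specific
  RU scales, age drift of seropositivity — so passing tests show pipeline
  correctness under the assumed structure, not robustness to real-assay
  artefacts.

## Risk model

Absolute 5-year lung-cancer risk from gender, age, and smoking history:

    risk = min(cap, baseline(gender, 5-yr age band) · multiplier(smoking)
                    · exp(coefficient · years smoked))

Age bands span 40–84 and clamp outside; multipliers are ordered never ≤ ex
≤ current. The published coefficient sets for demographic risk models of
this family are not freely reusable, so the default configuration is an
explicit illustrative fixture (male baselines 0.08%–0.7% across bands,
female 0.75×, multipliers 1/4/8, coefficient 0.015/yr, cap 12%) chosen by
hand so that a typical high-risk screening mix lands mean risk in the 2–3%
range; it makes no claim to reproduce any published model, and the 5-year
horizon is a label, not a survival-analysis derivation. Subjects with
unknown smoking status are not evaluable; summaries exclude them and report
the exclusion count, while the occult adjustment imputes the evaluable
mean for them (they contribute to N and must contribute to E).

Summary quantiles use the nearest-rank convention: the p-th percentile of n
sorted values is the ⌈p·n/100⌉-th.

## Cutoff search

* **Candidate space.** Per antigen, the grid defaults to the empirical
  80th–99.9th percentiles of control reference RU at 0.1-percentile steps
  (200 points), making the search scale-free in RU units. Candidates are
  drawn uniformly and independently per antigen, with replacement.
* **Constraint band.** The constrained metric must land within ±0.5
  percentage points of the target: with finite cohorts exact equality is
  generically unattainable, and "approximately 40%" targets motivate a
  band rather than a knife edge.
* **Tie-break.** Max free metric, then max constrained metric, then
  lexicographically smallest cutoff vector — fully deterministic given the
  seed, which is recorded in the result.
* **Occult adjustment.** E = Σ r_i over nominal controls; adjusted FP =
  max(0, FP − s·E); adjusted specificity = 100·(1 − adjFP/(N − E)). This
  expected-count deflation is one defensible formalization and is isolated
  behind `adjusted_specificity()` so a per-subject reclassification scheme
  could be swapped in. Note its direction: it *lowers* specificity when
  the panel misses occult cancers (s·E < FP share attributable to them),
  and at the default 2.7% occult rate it moves specificity by roughly one
  point — it cannot, by itself, produce a two-point shift like 91%→93%
  unless the implied occult burden is several times larger. That gap is a
  documented limitation, not calibrated away.
* **Complexity.** Evaluation is vectorized over candidates × subjects ×
  antigens in bounded-memory chunks; 10,000 candidates on a 3,000-subject,
  7-antigen cohort take ~1.5 s on one core.

## Statistics

* Binomial intervals are exact Clopper–Pearson via beta-quantile
  inversion. (Wilson intervals do not reproduce the printed whole-percent
  bounds for small counts, e.g. 9/53 → lower bound 8 exact vs 9 Wilson.)
* Two-proportion comparisons use Pearson chi-squared **without** Yates
  continuity correction, which is what reproduces the printed p ≈ 0.63 on
  10/25 vs 9/19.
* All internal math is full precision; presentation rounding is half-up to
  whole percent (one decimal for the positive-test cancer fraction) and
  applied only at the reporting layer. "1 in N" is round(100/PPV) on the
  unrounded PPV.
* Where a test needs counts behind a printed percentage, they are
  reconstructed as round(pct·n/100) and labelled as such at the use site.

## Problem sizes and seeds

Unit tests run on 300–800-subject cohorts; the calibration and
parameter-recovery checks use 3,000-subject train/test pairs with the
full 10,000-candidate search, and the independence closed-form check uses
20,000 cancers — sizes at which binomial 3σ bands are a few tenths of a
percentage point. All randomness flows through explicit integer seeds
(numpy PCG64); pipeline stages derive their seeds from one master seed by
fixed offsets so stages can be rerun independently.

## Known limitations

* The optimization-set headline operating points (39%/89%, 41%/91→93%)
  depend on the study sera and are not recoverable from printed summary
  statistics; the package substitutes property-based checks (optimizer =
  exhaustive oracle on small grids; held-out recovery of the constrained
  target; generator closed forms; OR-rule and adjustment monotonicity).
* Inter-antigen correlation, titration length (default 4 coat levels), and
  the dose-response operationalization are package choices where the
  source material is silent; each is configurable and surfaced in reports.
* The risk model is a stand-in family, adequate for exercising the occult
  adjustment, not for individual counselling.
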