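# Methods

## The biphasic life-cycle model

The community holds two species, A and B, alternating each cycle between a
host phase (worm gut) and an environmental phase (agar plate).  Both habitats
are assumed to be saturated at the end of their phase: worms are maximally
colonized every iteration (carrying capacity `K_W` CFU/worm) and plates carry
dense lawns (`K_P` CFU/plate).  Under that assumption absolute abundances
carry no extra information and the state reduces to the proportion `p` of
species A per phase; abundances are recovered as `p·K`.

Selection within a phase is a single relative-fitness parameter
`w ∈ [0, 1]` for species A (B receives `1 − w`).  The default (`replicator`)
update is

```
p' = p·w / (p·w + (1 − p)(1 − w))        (odds of A multiply by w/(1−w))
```

applied once with `w_W_A` for the worm phase and once with `w_P_A` for the
plate phase.  This is the normalized reading of "abundances weighted by
relative fitness under a fixed carrying capacity".  The unnormalized product
form `n_A' = p·w·K`, `n_B' = K − n_A'` is retained as `mode="literal"`: it is
the face-value reading of the weighting, but whenever both fitness values are
below one it shrinks A's proportion every cycle regardless of which species
is fitter, so it cannot reproduce the observed serial-passage sweep and is
kept only for transparency.  In the literal mode the complement species is
assigned `K − n_A` at the *updated* abundance, the only bookkeeping that
conserves the phase total.

Assumptions worth stating plainly: fitness values are static (no adaptation),
there is no within-cycle time resolution, no migration between replicate
communities, and fixation is absorbing.  Proportions are clamped to [0, 1]
after each update; fixation is declared within 1e−12 of the boundary.
Cycle indexing is 1-based for reported milestones ("dominance after four
cycles" means the 4th worm phase); index 0 is the pre-cycle inoculated plate,
seeded as `n_P_A(0) = prop_A_initial · K_P`.

An independent check used throughout the tests: iterating the odds
`odds ← odds·w/(1−w)` phase by phase must agree with the simulator to
1e−12, which it does over a 20×20 parameter grid.

### Stochastic mode

The serial-passage experiment transfers 10% of the worm-associated community
to found the next cycle.  The stochastic mode models the worm community as a
finite founder population of size `F` (`n_worm_founders`, default 1000): the
species-A founder count is binomial with success probability equal to the
replicator-updated plate proportion; the bottleneck then draws
`round(transfer_fraction·F)` individuals binomially from the worm community;
plate growth afterwards is treated deterministically (plate populations are
~10⁹, where drift is negligible).  Only the bottleneck fraction (10%) comes
from the study design; the founder-population abstraction and its default
size are this package's modelling choice.  With large `F` and full transfer
the ensemble mean converges to the deterministic trajectory (checked at
F = 10⁷, 500 runs, 3 ensemble standard errors).

## Parameter estimation

* `w_W_A`: summary (default median) of per-replicate co-culture proportions
  of A during short-term persistence — the community a serial-passage
  protocol would transfer.
* `w_P_A`: the same summary on agar at 72 h (the length of the plate phase);
  the timepoint is configurable.
* `K_W`, `K_P`: maxima over replicates of species-summed totals (plate: at
  the final growth timepoint; worm: over established colonization and
  persistence), co-culture records only by default.
* `prop_A_initial`: 0.5 under the equal-OD protocol (default), or the
  CFU-corrected value through the OD calibration (≈0.699 for the default
  constants, OD 1 ≙ 1.86×10⁹ A and 8.0×10⁸ B CFU).  Which basis matches a
  given experiment is a protocol fact the user must declare; both are
  supported.

The median is preferred because CFU noise is multiplicative: under the
lognormal noise model the replicate proportions follow a logit-normal-like
law whose *median* is the planted proportion, while the mean is biased
toward 0.5.  Zero-total replicates are excluded with a logged warning, not
imputed.

## Synthetic assay generator

The generator emulates the statistical structure of the assay design so the
whole pipeline is testable without data: co-culture plate growth at
0/24/72/168 h (totals saturating at `K_P` from 72 h, proportion reaching
`true_w_P_A` at 72 h, the 24 h composition halfway between inoculum and
equilibrium), and four worm assays.  Persistence (and release) proportions
equal `true_w_W_A`; early and established colonization are a 50:50 mixture
(configurable) of the lawn proportion and `true_w_W_A`, reflecting that
within-host abundance results from both uptake from the plate and host
filtering.  Mono-culture plate records reach the full `K_P` (competition
released) while mono-culture worm records equal the co-culture per-species
means (no detectable within-host competition) — the qualitative mono/co
contrast of the study.  Noise is i.i.d. lognormal per CFU count with
log-scale standard deviation `noise_sigma_log` (default 0.3, a choice:
replicate-to-replicate variance is not printed anywhere and 0.3 gives
realistic ~35% coefficient of variation).  Defaults: 6 replicates,
`K_W = 10⁴` CFU/worm, `K_P = 10⁹` CFU/plate, planted
`(w_W_A, w_P_A) = (0.3, 0.9)` — the qualitative pattern of a plate-favoured
A and a worm-favoured B.  Worm-assay `time_h` values (1.5/48/49/49 h) are
bookkeeping labels for the record key, not modelled durations.

What passing tests on these data do **not** show about real data: the
generator has no dilution-series error structure, no worm-to-worm
colonization heterogeneity beyond lognormal noise, no temporal
autocorrelation within a replicate, and its trait tables place background
species at a single community-typical trait vector.  Parameter recovery on
synthetic data demonstrates estimator correctness under the stated noise
law, not robustness to real assay artefacts.

The trait generator plants strategies structurally: planted species take
extreme values (with seeded, pairwise-distinct jitter) on their
strategy-congruent traits and community-typical values elsewhere, so under
the strict-quartile scoring rule recovery at zero noise is exact whenever
planted species are a minority per strategy; background species score zero
and classify as intermediate.

## Life-history classification

Doubling time is `ln(2)/r_max`; the fast/slow dichotomy sits at 5 h
(equivalently a rate of ≈0.14 h⁻¹), with the boundary itself assigned to
"slow" (a convention; the threshold is quoted as separating the groups).
CSR scoring: per trait, the community Q25/Q75 are computed by linear
interpolation of order statistics (numpy default, R type 7 — the common
default in the ecosystem the analysis style comes from; configurable), and a
species' trait contributes to a strategy when it lies strictly above Q75
("high" traits) or strictly below Q25 ("low" traits).  Strict inequalities
mean degenerate all-equal traits contribute to nobody.  Antibiotic pathways
are scored by the same quantile rule as every other count by default, with a
binary presence mode (count > 0) available.  The strategy with the highest
count wins; any tie for the maximum — including the all-zero case — is
intermediate.  Ternary coordinates are the scores normalized by their sum
(centroid for all-zero).  Scores are invariant under strictly monotone
rescaling of any trait column, since only ranks enter the quantiles.

Only `max_growth_rate` carries the growth criteria; codon usage bias enters
the ruderal list alone, even though it correlates with growth — double
counting slow growth for stress-toleration would weight one biological
signal twice.

## Exact statistics

With 4–6 replicates per group, asymptotic rank tests are unreliable, so both
tests enumerate exactly, conditional on the observed tie pattern (mid-ranks):

* Mann–Whitney U, reported as `min(U_x, U_y)`; two-sided p = share of the
  C(n1+n2, n1) group labelings whose U is at most the observed one.  The
  null distribution is cached per rank multiset, which makes the 10,000-fold
  calibration loop cheap.
* Paired comparisons use the exact Wilcoxon signed-rank test (the standard
  paired analogue of the U test); V is the smaller signed-rank sum over
  nonzero differences, p enumerates all 2ⁿ sign patterns.  Six uniformly
  signed pairs give V = 0, p = 2/64 ≈ 0.03.
* Above combined size 20 both fall back to the tie-corrected,
  continuity-corrected normal approximation with a logged note.
* BH-FDR adjustment delegates to statsmodels (`fdr_bh`) behind input
  validation.

Because the exact p-values are discrete, the tests are conservative: the
type-I error at nominal 0.05 is at most 0.05, which the calibration run
(lognormal null, 6 vs 6, 10,000 simulations) confirms empirically.

## Pipeline and reproducibility

`RunConfig` drives generate → estimate → simulate → classify → test; one
top-level seed fans out to per-stage sub-seeds (numpy `SeedSequence`-style
key lists), so each stage is independently reproducible and two runs of the
same config are byte-identical.  Configs and summaries are JSON; tabular
artefacts are TSV.  Problem sizes used by the analysis scripts and the
acceptance script — 100 replicates for noisy parameter recovery, a 0.02-step
fitness grid for the milestone scan, 10,000 null simulations for
calibration, 500 stochastic runs at 10⁷ founders for the limit check — were
chosen as the smallest sizes at which the Monte-Carlo error is clearly below
the quantity being checked.

## Known limitations

* The model is ecological only: no mutation, no host adaptation, no
  frequency-dependent fitness; `w` is constant across cycles.
* Carrying capacities enter only as scale factors in deterministic modes;
  deviations from the saturation assumption (e.g. under-colonized worms) are
  outside the model.
* The estimation layer uses endpoint proportions, not growth curves; no
  ODE/logistic fitting is attempted.
* The CSR classifier depends on the supplied community: quartiles — and
  therefore scores — change with community membership, which is a property
  of the method, not a bug.
* The exact tests handle ties by conditional enumeration on mid-ranks;
  p-values are conservative for heavily tied data.
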