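# Methods

## The model

The outcome is the WHO three-way birth-weight category: LBW (< 2,500 g),
NBW (2,500–4,000 g, both boundaries included) and HBW (> 4,000 g). The
boundary convention follows the usual reading of the category
definitions: LBW and HBW are strict inequalities, so 2,500 g and 4,000 g
are NBW. Categorisation is a total function of positive grams — the three
intervals partition (0, ∞).

With reference category *r* (default LBW, so exponentiated coefficients
are relative risk ratios of NBW and HBW against low birth weight), the
multinomial logit is

    log[ π_j(x) / π_r(x) ] = β_j' x ,   j ≠ r,

and probabilities are the softmax of the J − 1 linear predictors with the
reference predictor fixed at 0, always evaluated through log-sum-exp so
extreme predictors saturate rather than overflow.

### Survey weighting

Each child carries the design weight w_i = N_c / n_c of its cluster. The
default estimator maximises the pseudo-likelihood Σ_i w_i Σ_j y_ij log
π_j(x_i; β): weights multiply each record's log-likelihood contribution,
which is what standard survey estimation software does. An alternative
convention that multiplies the *linear predictor* by w_i (equivalently,
scales each design row by the weight) appears in some presentations of
the weighted model; it changes the model itself and is kept available as
`weighting="literal"` purely for comparison. Weights are rescaled to mean
one inside the optimiser — the argmax is invariant to the scale of the
weights, and the mean-one scale makes the gradient tolerance meaningful
across sample sizes; reported pseudo-log-likelihoods and AICs are on the
raw-weight scale.

Strata (urban/rural) enter only through jackknife grouping. No stratum
weight multiplier is applied: the N_c/n_c construction is the only weight
the data model defines, and inventing an additional stratum factor would
not be identifiable from the inputs.

The finite population correction √((N − n)/(N − 1)) is computed and
reported (for a national under-five population of 2,645,948 and a sample
of 11,680 it is 0.9978) but never applied to estimates — at that sampling
fraction it is indistinguishable from 1.

### Estimation and variance

Newton–Raphson on the stacked (J − 1)(p + 1) parameter vector with
analytic gradient and Hessian and step halving; convergence when the
gradient max-norm falls below `tol` (default 1e-8) times the total
(mean-one) weight. An ill-conditioned Hessian triggers a small ridge
retry and then an L-BFGS fallback. Coefficients whose magnitude exceeds
the separation guard (default 30) raise a separation error, as does an
outcome category with no observations. Unweighted fits agree with an
independent multinomial fitter to better than 1e-5 per coefficient; with
J = 2 the fit reduces to binary logistic regression.

Variance is the delete-one-cluster jackknife: each cluster is removed in
turn, the remaining weights in its stratum are rescaled by n_h/(n_h − 1),
and the replicate fits (warm-started at the full-sample estimate) are
combined as V = Σ_h (n_h − 1)/n_h Σ_{c∈h} (β̂_(c) − β̂)(β̂_(c) − β̂)'.
Replicates that separate or fail to converge are dropped with a warning;
a stratum with a single cluster is an error (collapse strata first).
Wald p-values from this covariance feed the model-selection narrative;
the selected model is simply the AIC minimiser (ties: fewer parameters,
then list order), with AIC = −2·pseudo-loglik + 2(J − 1)(p + 1).

## Diagnostics

All per-record statistics treat each child as a single multinomial trial
(m_i = 1). Reading the trial count instead as the *category total* makes
residuals non-comparable across children and is offered only as a
comparison option.

* Pearson cell residuals r_ij = (y_ij − π̂_ij)/√π̂_ij. Their total sum of
  squares over records and categories is the chi-square goodness-of-fit
  statistic with df = n(J − 1) − (J − 1)(p + 1). For individual-level
  data this statistic has the right mean but is not exactly
  chi-square-distributed (with uniform probabilities each record
  contributes exactly J − 1), so the p-value is an approximation — the
  same caveat as for any ungrouped Pearson test.
* Squared deviance residual d²_i = 2 Σ_j y_ij log(y_ij / π̂_ij) =
  −2 log π̂_{i,observed} under 0·log 0 = 0.
* Leverage: the stacked design has J − 1 rows per record; with blocks
  V_i = w_i (diag(π̂_i) − π̂_i π̂_i') over the non-reference categories,
  a record's leverage is the sum of its J − 1 diagonal entries of
  H = V^½X(X'VX)⁻¹X'V^½ (the square roots cancel under the trace, so H's
  diagonal blocks are computed as tr(V_i · X_i'M⁻¹X_i)). Leverages are in
  [0, 1) and sum exactly to (J − 1)(p + 1).
* Generalized Cook's distance Δβ̂_i = r_i² h_ii/(1 − h_ii)². The scalar
  r_i² defaults to the record's full Pearson chi-square contribution
  Σ_j r_ij², because that choice reduces *exactly* to the textbook binary
  r²h/(1 − h)² when J = 2 (two-cell identity Σ_j (y_j − p_j)²/p_j =
  (y − p)²/(p(1 − p))); the observed-cell-only variant is available as
  `scalar_residual="observed"`.

Cluster screening: the local mean deviance D_c = Σ_{i∈c} d²_i/(n_c − 1)
and the analogous (n_c − 1)-average of Cook's distances. The (n_c − 1)
denominator exceeds the arithmetic mean by n_c/(n_c − 1) and requires
n_c ≥ 2; a plain-mean option exists. Flags: individual |residual| > 2.5
and Cook's distance > 1; clusters by `rank_top_k` (default k = 2 —
cluster-by-cluster comparison without asserting a cutoff) or by modified
z-score 0.6745(x − median)/MAD > 3.5, falling back to ranking when the
MAD is zero.

## Synthetic data

The generator emulates a DHS-style kids-recode extract: 850 clusters by
default, cluster sizes uniform on 7–25 (at least 2, since D_c divides by
n_c − 1), urban probability 0.185 per cluster, and N_c set to a uniform
50–150 multiple of n_c so the weights genuinely vary. Covariate marginals
default to the published national level counts normalised within each
covariate (counts, not the printed percentages, which are internally
inconsistent for several covariates). Covariates are drawn independently
across children and covariates — only the marginals are documented, so no
correlation structure is asserted — with one exception: `residence` is
set to the cluster's stratum, because residence is a cluster-level trait
in a two-stage design and its marginal matches the urban fraction anyway.
Outcomes are independent multinomial draws from π(x; true β) (no
within-cluster random effect: none is documented for the emulated
design, and inventing one would change every downstream calibration).
Gram values are drawn from truncated normals strictly inside each WHO
band so outcome and grams never disagree; a configured missing fraction
is realised as an *exact* rounded count so survey-sized record-filter
figures (13,448 observed / 1,768 missing / 11,680 analysed) reproduce
deterministically.

Each cluster draws from its own spawned random substream, so
contaminating selected clusters leaves every other record byte-identical
at the same seed. Contamination modes: `all_normal_high` resamples the
cluster's LBW outcomes to NBW/HBW in proportion to their overall shares;
`covariate_atypical` overwrites the forced covariates (default: first
birth order, non-caesarean, singleton — the signature reported for
influential communities in field data); `category_shift` redraws the
cluster's outcomes from the overall shares with a log-share offset
(default strongly toward HBW). Grams are redrawn whenever an outcome
changes.

What passing tests on these data do *not* show: real surveys have
within-cluster correlation, covariate dependence, informative weights and
missingness mechanisms the generator deliberately omits, so detection
rates measured here bound what the method does under clean conditions,
not its field performance.

## Validation experiments and their design

**Parameter recovery.** 200 replicates at n = 10,000 (100 clusters of
100) with moderate published effect sizes on common covariates (sex,
wealth; every outcome-by-level cell keeps hundreds of expected events).
The mean estimate of every coefficient falls within 3 Monte-Carlo
standard errors of the truth. The scenario intentionally avoids sparse
cells: with only ~100 events in a cell, the ordinary O(1/events)
likelihood bias of *any* ML fitter (~0.02 on the log scale) becomes
resolvable at this Monte-Carlo precision and the experiment would measure
a property of maximum likelihood rather than the correctness of the
implementation.

**Detection power, and a known limitation.** With clusters whose outcomes
are strongly shifted toward an improbable category (`category_shift`),
the top-2 cluster-mean Cook's distance rule recovers the contaminated
clusters almost always (~95% of replicates at 40 clusters). But for the
subtler pattern — clusters purged of LBW with an atypical-but-common
covariate signature (`all_normal_high` + `covariate_atypical`) — the
cluster-averaged per-record Cook's distance has essentially **no power**
(0/200 replicates top-2 at 100 clusters of 12, zero-slope truth; the
contaminated clusters in fact rank near the bottom). The reason is
structural: per-record influence r²h/(1 − h)² is driven by individually
improbable outcomes, and removing a cluster's LBW records removes exactly
its most surprising observations, *lowering* its mean; the forced
covariate signature occupies a common design cell, so leverage does not
rise; and the N_c/n_c weight spread adds ~3× multiplicative noise to
cluster leverage. Screens built on averaged per-record influence should
therefore be read as detectors of *individually surprising* outcome
concentrations, not of coherent no-event patterns; a leave-one-cluster-
out refit (used here as a validation check — deleting the top-ranked
cluster moves coefficients more than deleting a median one) is the
sharper but costlier instrument for the latter.

## Numerical conventions

* Storage order of categories is fixed at (LBW, NBW, HBW); the modelling
  reference is independent of storage order.
* Record order, not child id, aligns every diagnostic vector.
* Design columns: intercept first, then terms in specification order,
  levels in declared order, reference levels skipped; an all-zero dummy
  column is retained with a warning (the fit will report separation).
* Missing values in CSVs are empty cells or `NA`; floats are written with
  6 significant digits by default (10 for dataset round-trips).
* AIC ties are broken by parameter count, then list position; jackknife
  flattening of β is row-major over (category, column).
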