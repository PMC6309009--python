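# Methods

This note documents the statistical machinery implemented in `socionet`,
the conventions chosen where several are in circulation, and what the
synthetic validation does and does not establish.

## Data model and quality control

A *sampling occasion* is one survey day; associations are scored within
occasions, and every permutation scheme is constrained within them.  Two
animals photographed in the same group (spatially cohesive party) on the
same day are associated for that occasion; repeat co-sightings within a day
collapse to a single event.

Quality filters mirror standard photo-identification practice:

* a group is dropped when more animals were identified than the field crew's
  maximum estimate (group-size control lost) or when fewer than half of the
  best field estimate were identified (coverage too poor);
* an individual is retained when it carries significant long-lasting marks,
  is neither a calf nor known dead, and was photographed on >= 10 occasions
  with >= 5 in each half of the study (guards against demographic artefacts
  and rarely encountered animals).

Area preference uses one vote per animal per day per subarea, excluding the
transition zone at the estuary mouth (created precisely so that transiting
animals are not scored as estuary users).  The class rules are strict
inequalities: E/S/N needs > 50% in the area and < 30% in each other area;
animals never seen in the estuary need > 70% in one coastal area, else they
are "coastal" (C); everything else is a "wanderer" (W).  Transition
sightings *do* count toward occasion totals (sighting thresholds, period
classification): the zone erases spatial information, not effort.  Seasonal
classes use the May-October (cold) / November-April (warm) split; > 70% of
an individual's occasions in one season makes it a transient.

Longitude/latitude input is projected to planar metres with a local
equirectangular tangent-plane approximation centred on the data centroid -
sub-metre error at the ~10 km extent these coastal studies cover.

## Association indices

The half-weight index for a dyad is

    HWI = x / (x + y_ab + 0.5 (y_a + y_b))

with `x` co-grouped occasions, `y_ab` occasions both identified but apart,
and `y_a`, `y_b` one-sided identification counts.  Algebraically this equals
`2x / (seen_a + seen_b)`, which is how the permutation kernels compute it.

The gregariousness-corrected index is

    HWIG_ab = HWI_ab * (sum of all HWI) / (sum_a HWI * sum_b HWI)

with the grand total taken over all ordered off-diagonal entries (the sum of
the row sums).  Under random association HWIG has expectation 1; a complete
network with all HWI equal yields the constant n/(n-1), which approaches 1
from above - the "equals 1" reading of the correction is an asymptotic
statement, not a finite-n identity.  The exact finite-n contract is the
round-trip identity `HWIG_ab * sum_a * sum_b / total = HWI_ab`, which the
tests verify to 1e-13.

Typical group size (the group size an individual experiences) is the mean
number of *identified* animals in its groups, including itself; field
estimates only gate quality control.  Its across-individual SD is the
gregariousness test statistic.

## Permutation null models

The null model permutes each occasion's group-by-individual incidence
matrix with random 2x2 checkerboard swaps, conserving group sizes, groups
per occasion, and each individual's per-occasion membership count.
Permuted datasets form a sequential chain: 1,000 burn-in swaps from the
observed data, then a configured number of swaps (default 1,000; reduced in
the test profile) between successive recorded statistics.  Statistics are
recorded once per permutation, not per swap.  The burn-in length and the
record-every-chunk convention are our choices; the chain construction
itself follows the standard swap-test practice for association data.
Defaults at full scale: 40,000 recorded permutations.

Tails: SD and CV of the index high => long-term preferred companionship;
mean low => short-term preference; proportion of nonzero dyads low =>
avoidance; SD of typical group size high => gregariousness heterogeneity.
All p-values are `(k+1)/(N+1)`.

Calibration (measured in the validation suite, 500 exchangeable-population
replicates): the continuously-distributed statistics reject at 3-7% at a
nominal 5%.  The proportion-of-nonzero-dyads statistic is integer-valued;
ties make its permutation p-value conservative (~2.5% rejection), which is
a structural property of discrete test statistics, so only the upper bound
of the calibration band applies to it.

The Mantel class screen uses the within-class minus between-class mean
difference of the index, standardised by its spread under random
relabelling of individuals; one-sided upper p.

## Social differentiation and precision

Dyadic counts are modelled as `x_ab ~ Binomial(d_ab, p_ab)` with
`p_ab ~ Beta(alpha, beta)` and `d_ab = x + y_ab + y_a + y_b` (occasions on
which either member was identified).  The likelihood is maximised by
bounded quasi-Newton on `(log alpha, log beta)` from five starts
(tolerance 1e-8, best likelihood kept).  Social differentiation is the CV
of the fitted Beta, `S = sqrt(beta / (alpha (alpha + beta + 1)))`: near 0,
homogeneous relationships; near or above 1, highly differentiated.  The
cited likelihood method does not pin the mixing distribution; the Beta is
this package's concrete realisation.

Precision `r` - the correlation between true and estimated indices - is
computed by Monte-Carlo integration: draw `p` from the fitted Beta, `d`
from the empirical denominator distribution, `x ~ Binomial(d, p)`, and
correlate `p` with `x/d` (20,000 draws).  It rises toward 1 as effort
grows at fixed S.  Standard errors bootstrap whole sampling occasions
(days are exchangeable sampling units; dyads are not), re-tallying counts
and refitting from the point estimate.

## Structural predictors

* **Gregariousness** (dyadic): `log[(sum_i!=b HWI_ai)(sum_j!=a HWI_bj)]`.
* **Spatial overlap**: fraction of jointly-identified calendar months in
  which the pair shared at least one subarea (transition excluded).  An
  individual's month-area presence is the set of areas where it was
  identified that month; multi-area months are allowed.
* **Temporal overlap**: months both identified / months either identified.
  The bounded Jaccard orientation is deliberate: the other orientation of
  the ratio is >= 1 and unbounded, and the MRQAP sign conventions here
  assume a [0, 1] similarity.
* **Home-range overlap (UDOI)**: bivariate-normal kernel utilisation
  distributions on a shared grid (default cell 100 m in the library,
  250 m in the study-scale drivers; reference bandwidth
  `sqrt((var_x+var_y)/2) n^(-1/6)` per individual), then
  `UDOI = A_overlap * integral(UD_a UD_b)` with `A_overlap` the
  intersection area of the two 90% isopleths.  Isopleths are density level
  sets (cells tied with the cutoff included), so identical uniform
  distributions give exactly 1.  Whether published analyses used 90%, 95%
  or full-grid support for the area term is generally unstated; 90% is this
  package's convention, configurable.
* **Class matches**: binary same-class indicators for area, sex and period;
  dyads with unknown sex are masked rather than scored as mismatches.

## Generalized affiliation indices

The GAI is the deviance residual of a logit-link binomial GLM over the
n(n-1)/2 dyads: successes `x_ab`, trials the half-weight denominator
rounded half-up (the model needs integer trials; the HWI denominator is
half-integer when identification is one-sided).  Anscombe residuals are
computed alongside; |residual| > 2.5 flags exceptionally strong
affiliations and avoidances.

Predictor significance uses MRQAP with double semi-partialing on the linear
dyadic regression of the association index: the focal predictor is
residualised on the others, permuted as a matrix by simultaneous row/column
relabelling, re-residualised, and its regression t statistic compared
two-sidedly to the observed one (20,000 permutations at full scale).
Partial correlations are between the doubly-residualised focal predictor
and response.

Stepwise retention is backward elimination under a dual criterion: a
predictor survives only if its MRQAP p < 0.05 *and* its partial correlation
is at least 0.1 in magnitude.  The second clause matters on large networks,
where thousands of dyads make negligible effects significant; it is why a
predictor can be "significant but removed".  One predictor is dropped per
round (smallest |partial correlation| among the failing set, ties lexical).

## Social units and network metrics

Units maximise weighted Newman modularity
`Q = (1/2m) sum_ij (A_ij - s_i s_j / 2m) delta(c_i, c_j)` by recursive
leading-eigenvector splitting with the subgraph-corrected modularity
matrix, a Kernighan-Lin single-vertex sweep after each split, and a final
node-move refinement across units; splitting stops when no division
raises Q.  Q >= 0.3 is read as a meaningful division.  Negative weights
(possible for GAI networks) are clamped to zero first - modularity is
defined for nonnegative weights, and the clamping convention is declared
rather than silent.  Unit labels are ordered by descending size.  On
graphs small enough for exhaustive enumeration (n <= 8) the returned Q
attains the global optimum in >= 95% of random instances and never
exceeds it.

Node metrics on the weighted matrix: strength (row sum); eigenvector
centrality (leading eigenvector, sign-fixed, unit maximum); the Holme
weighted clustering coefficient
`c_i = (W^3)_ii / (w_max (s_i^2 - sum_j w_ij^2))`; affinity
`(W s)_i / s_i`.  Per-unit means are compared two-sidedly against the swap
null (10,000 permutations at full scale).  Display networks threshold at
HWIG > 1 (above-chance dyads).

## Temporal analysis

For every ordered occasion pair (t, t+tau) and focal animal identified at
both, the SLAR numerator accumulates associates shared between the two
occasions and the denominator the product of associate counts, giving a
standardized conditional probability robust to incomplete identification:
stable groups of size k sit at 1/(k-1), not 1.  Curves pool consecutive
lags until a moving-average window of association records is reached
(8,000 for population curves, 5,000 within units, following the usual
plotting convention); a window of 1 reproduces the unsmoothed curve.

The null SNAR randomises identities among the individuals identified on
the later occasion (preserving group sizes, gregariousness and effort) and
averages >= 100 randomisations at full scale.  Standard errors come from a
delete-block jackknife omitting 10 consecutive occasions per replicate
(1,000 replicates requested; with fewer distinct blocks the count
truncates, since re-deleting a block adds no information).

Four decay models are fitted to the per-lag persistence events by maximum
binomial pseudo-likelihood (Nelder-Mead on transformed parameters - logit
levels, log rates - from six starts): constant (preferred companions),
exponential (casual acquaintances), constant + exponential, and double
exponential (two acquaintance timescales).  Overdispersion `c_hat` is the
Pearson statistic of the double-exponential fit over its residual degrees
of freedom, floored at 1; models are ranked by `QAIC = -2 logL / c_hat +
2k` with Akaike weights.  The pseudo-likelihood treats persistence events
as independent binomials, which they are not (the same dyads recur across
occasion pairs); QAIC's overdispersion correction absorbs much of this,
and the simulation checks show the selection identifies a constant vs.
decaying generating regime reliably.

## Synthetic data: what it emulates and what it does not

The generator simulates a decade of boat surveys: a rotating subarea plan
(~318 evenly spread survey days over ten years in the study-scale preset),
planted social units with distinct subarea preferences and centroids,
cold/warm-season transients, lognormal gregariousness multipliers, and
per-member identification probability (0.9 in the preset).  Groups form by
sequential aggregation: an arriving animal joins an existing group with
weight proportional to its gregariousness times the mean pairwise affinity
to members (`lambda_in` within its unit, `lambda_out` across), or opens a
new group.  The preset's weights (`lambda_in = 6`, `lambda_out = 0.6`,
new-group weight 0.8, availability 0.6) were calibrated once so the mean
identified group size falls in the 4-8 range typical of such surveys, with
the within/between affinity ratio held at 10.  Field size estimates get
Poisson(0.5) noise; groups are logged in the transition zone with
probability 0.08.

Deliberately absent: movement trajectories (locations are draws around
blended subarea/unit centroids, so home ranges are stylised), demographic
turnover, misidentification, and observation-effort weather gaps.  Passing
the validation suite therefore demonstrates that the estimators recover
known structure under realistic sampling intensity and incomplete
identification - not that they are robust to misidentification or
non-stationary populations, which this data model does not generate.

## Numerical conventions

* Undefined dyads (zero denominators, unknown classes, < 5 locations for a
  kernel) are NaN-masked, never zero-filled, except where a zero has
  defined meaning (never co-temporal pairs in spatial overlap).
* SDs of dyadic statistics use ddof = 1 consistently for observed and
  permuted values.
* Binomial trials round half-up; successes clamp to trials.
* Permutation p-values are `(k+1)/(N+1)` throughout; two-sided p-values are
  `min(1, 2 min(p_hi, p_lo))`.
* All randomness flows through explicit seeds (numpy Generator for
  vectorised code, the numba global RNG for the swap kernels); a fixed seed
  reproduces every table bit-for-bit.

## Validation problem sizes

The test suite runs the statistical checks at deliberately reduced sizes
chosen as the smallest that still discriminate: 500 null replicates with
1,000 permutations of 100 swaps for the type-I calibration; 100 random
graphs (n <= 8) against exhaustive enumeration; 100 replicates for S
recovery; 100 simulated studies for decay-model identification; 50
replicates at n = 35 for MRQAP stepwise retention; 50 study-scale
replicates for planted-unit recovery.  Full-scale defaults (40,000 /
20,000 / 10,000 permutations, 10,000 bootstraps) remain the pipeline
configuration.
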