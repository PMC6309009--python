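# socionet

Dyadic social-structure inference for photo-identification studies of
wild animal populations — built around the analysis pipeline used for
fission–fusion societies such as coastal bottlenose dolphins, where "who
is photographed with whom, where, and when" is the only observable.

Given a table of sighting records (one row per identified individual per
group per survey day), the package takes the analysis from raw records to
social units and their temporal dynamics:

1. **Quality control and classification** — group-size control against
   field estimates, minimum-sighting inclusion rules, area-preference and
   seasonal-residency classes (`data_model`).
2. **Association indices** — the half-weight index
   `HWI = x / (x + y_ab + 0.5 (y_a + y_b))` and its gregariousness
   correction HWIG (expectation 1 under random association)
   (`association`).
3. **Permutation null models** — within-occasion checkerboard swaps that
   conserve group sizes and individual activity; tests for preferred and
   avoided companionship and for gregariousness differences
   (`permutations`).
4. **Sampling precision** — maximum-likelihood social differentiation *S*
   (CV of the true association probabilities under a beta-binomial model)
   and the correlation *r* between true and estimated indices
   (`precision`).
5. **Generalized affiliation indices** — dyadic binomial regression of
   association on structural predictors (gregariousness, spatial overlap,
   temporal overlap, kernel home-range overlap UDOI, class matches), with
   MRQAP double-semi-partialing significance, stepwise retention, and
   Anscombe-residual calls of exceptional dyads (`predictors`, `gai`).
6. **Social units** — Newman leading-eigenvector modularity with
   Kernighan–Lin refinement, weighted node metrics (strength, eigenvector
   centrality, Holme clustering, affinity), permutation comparison
   (`community`).
7. **Temporal dynamics** — standardized lagged association rates (SLAR)
   with identity-randomisation nulls (SNAR), delete-block jackknife
   errors, and QAIC-ranked exponential decay models (`temporal`).
8. **Synthetic surveys** — a generator with planted units, seasonal
   transients, heterogeneous gregariousness and incomplete identification,
   so every stage is testable against known truth (`synthetic`).

`docs/methods.md` documents the statistical conventions in detail.

## Worked example

The `analysis/` scripts run the whole study on a simulated decade-long
survey (~102 marked individuals, 318 survey days, four planted social
units, 8 cold-season and 11 warm-season transients):

```bash
python analysis/01_simulate.py
python analysis/02_prepare.py
python analysis/03_associations.py
python analysis/04_affiliation.py
python analysis/05_social_units.py
python analysis/06_temporal.py
```

which prints, among other things:

```
simulated 318 survey days, 102 marked individuals, 1131 groups (mean identified size 5.21)
retained 102 individuals over 318 occasions; excluded 6 groups, 0 individuals
HWIG: mean 1.078, max 18.25
SD of typical group size: real 1.485 vs null 0.849 (p = 0.0005) -> gregariousness differs between individuals; use HWIG
social differentiation S = 0.792 +/- 0.027; precision r = 0.836 +/- 0.009
Mantel area_class: t = 17.30, p = 0.0005
retained predictors: ['spatial_overlap', 'temporal_overlap', 'homerange_udoi']
11 strong affiliations, 9 strong avoidances (|Anscombe| > 2.5)
HWIG network: 3 units, Q = 0.346, ARI vs planted = 0.953
best decay model: CONSTANT (QAIC weight 0.61), parameters {'a2': 0.01371}
```

Reading the output: the gregariousness permutation test is significant
(real SD of typical group size 1.49 against a null mean of 0.85), so the
association network is built on the corrected index.  *S* ≈ 0.79 marks a
well-differentiated society and *r* ≈ 0.84 says the sighting effort
suffices to represent it.  The stepwise MRQAP keeps the spatiotemporal
predictors; modularity on the corrected index recovers the planted units
almost exactly (adjusted Rand index 0.95) with Q ≈ 0.35, above the 0.3
yardstick for a meaningful division.  The affiliation-based (GAI) network,
with spatial and temporal structure regressed out, retains little unit
structure — exactly what it should do on data whose planted units are
spatially driven.  Pair stability is best described by the constant
(preferred-companion) model, as expected for planted units that never
dissolve.

The same pipeline runs from the command line on real tables:

```bash
socionet simulate --seed 1 --out data/
socionet prepare --records R.csv --groups G.csv --individuals I.csv --out prep/
socionet run --records R.csv --groups G.csv --individuals I.csv --scale full --out run/
```

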