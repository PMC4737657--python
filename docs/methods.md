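# Methods

This note documents the models behind `synaptometry`, the calibration of
its synthetic-data generator, the numerical choices, and what the tests do
and do not establish about real data.

## Pair precision as an upper bound on plasticity variability

Two spines on one dendrite innervated by the same axon share their history
of pre- and postsynaptic activity. If plasticity adjusted strength
deterministically from that history, their sizes would be identical; the
observed spread within such pairs therefore bounds the variability of the
adjustment process. The statistic used throughout is the **per-pair
coefficient of variation**: the sample standard deviation of the two head
volumes (denominator n−1 = 1, i.e. |a−b|/√2) divided by their mean, and the
**median** of this quantity over pairs. The median is used because per-pair
CVs are right-skewed; it is also what the calibration below inverts.

Pairs produced by a multi-synaptic bouton contacting three or more spines
on one dendrite are flagged and excluded from the headline median by
default (`exclude_multi_contact=True`): a shared vesicle pool introduces
competition effects that the pair model does not capture.

## The synthetic population

The generator emulates the statistical structure of a dense reconstruction
of CA1 stratum radiatum neuropil, not its geometry:

* **Head volumes** are log-normal. The functional form is an assumption —
  the measured distributions are only known to be right-skewed with a long
  tail — and is flagged as such. Defaults: median 0.03 µm³ (typical for CA1
  stratum radiatum), `log_sigma = 0.6`. This σ is a calibration with two
  consequences checked by tests: the median CV of randomly paired spines is
  ≈ 0.39, and a 287-spine sample spans a max/min head-volume ratio of
  roughly 15–75 across seeds (median ≈ 30; band frozen from a 300-seed
  Monte-Carlo before the tests were written).
* **Dependent metrics** follow power laws of head volume with log-normal
  noise, `metric = k·V^e·exp(ε)`. Defaults: head area (e = 2/3,
  log-noise 0.04, giving log-log r² ≈ 0.99 — area is the most reliable
  correlate of volume), PSD area (e = 0.85, noise 0.25, moderate coupling),
  neck diameter (e = 0.10, noise 0.30, weak coupling), neck length (e = 0,
  i.e. independent), docked vesicles (Poisson around a e = 0.8 power law
  with prefactor set so a median spine has ~15 docked vesicles). Exponents
  and noise levels are choices constrained by the qualitative pattern
  (strong / moderate / weak / absent coupling), not fits to published
  per-figure equations.
* **Neck volume** is the cylinder π(d/2)²L and whole-spine volume is head +
  neck, so the subtraction identity holds by construction. Neck length and
  diameter are carried as table columns only; no mesh-based procedure for
  them is defined.

### Pair calibration

Coupled pairs are built by drawing a base volume v from the population and
assigning the members v·e^{+δ/2} and v·e^{−δ/2}, δ ~ N(0, σδ). The
multiplicative, symmetric jitter keeps the pair's geometric mean at v, so
planting pairs does not distort the population distribution. For such a
pair the CV is exactly √2·tanh(|δ|/2), a monotone function of |δ|, so

    median CV = √2·tanh(0.6745·σδ / 2),

and the calibration inverts this exactly:
σδ = 2·atanh(target/√2)/0.6745. For the target median CV 0.083 this gives
σδ ≈ 0.1742. Note the calibration fixes the *median* of the per-pair CV
distribution; the *mean of per-seed medians* over 17-pair samples is
slightly higher (≈ 0.0845) because the sampling distribution of a small-
sample median of a right-skewed variable is itself right-skewed. This bias
is well inside the ±0.005 recovery tolerance and is left uncorrected.

Pair members' dependent metrics are regenerated from the coupling model at
their jittered volumes, so cross-metric pair correlations (areas, neck
diameter, docked counts) emerge mechanistically from the volume coupling
rather than by copying values.

## Morphometry

* **Region volumes** are convex hulls (Qhull) of a tagged region's
  vertices. The head/neck boundary is an *input tag*, not computed: in real
  reconstructions it is a standardized human judgment, and synthetic
  fixtures carry ground-truth tags. An optional clip intersects the hull
  with the closed mesh interior by winding-number sampling on a fixed
  lattice (default 24³) — a robust alternative to exact Boolean CSG; for
  the convex fixtures used in tests the clip is a no-op.
* **Docked vesicles** are centers within 100 nm (closed inequality) of the
  active-zone region. Point-to-triangle distances are computed exactly in
  vectorized numpy (projection-or-edge minimum); the test suite checks them
  against an independent scalar closest-point-on-triangle oracle. Meshes
  are in µm and vesicle coordinates in nm (conversion 10⁻³); a span check
  rejects clouds that appear to be in the wrong unit. The generator places
  centers at least 1 nm away from the threshold so counts are never
  tie-ambiguous.
* **Measurement error** follows the replicate protocol (four tracings per
  spine): SEM = sd/√k and SEM/mean. Multiplicative tracer noise of ~2%
  reproduces a median relative SEM of ~1%.
* The toy spine mesh is a truncated lat/long sphere joined to a capped
  cylinder sharing the junction ring, watertight by construction, with
  analytic head/neck volumes stored (the head ground truth subtracts the
  small spherical cap replaced by the neck). The PSD patch is a polar cap;
  the same patch is tagged `active_zone`, since the apposed pre- and
  postsynaptic membranes coincide in this toy geometry (no cleft).

## Pair statistics

Random-pairing nulls draw disjoint pairs (each spine used at most once per
resample) and record per-pair CVs and per-resample medians; the empirical
p-value for an observed median is add-one corrected. KS comparisons default
to the asymptotic two-sample test at effective size n_x·n_y/(n_x+n_y), with
an exact-method option for small samples (17 pairs is small). Which two
distributions enter the KS comparison is a design choice here: the coupled
per-pair CVs versus the pooled null per-pair CVs. Regressions on size
metrics are Pearson OLS after log transformation, the standard treatment
for these right-skewed, power-law-coupled quantities. The CV-versus-size
trend test regresses per-pair CV on log mean pair volume; the calibrated
generator's jitter is size-independent, so a flat (non-significant) slope
is the expected outcome and an injected size-dependent jitter must be
detected — both are tested.

## Capacity

`n_distinguishable` implements N = ln(range)/ln(1 + 2·CV·z) with
z = √2·erf⁻¹(confidence). N is real-valued; the ladder uses ⌊N⌋ levels and
the headline integer uses round(N) — both conventions are exposed because
N = 26.3 reads as "26" while N = 22.98 reads as "23". The level ladder is
anchored with its first mean at the minimum observed volume and constant
mean ratio 1 + 2·CV·z (uniform width and spacing on a log scale); the
anchoring convention affects no headline number. A range factor of exactly
1 yields N = 0.

Overlap convention: the default `adjacent_overlap` uses the equal-σ
identity 2·Φ(−z) = 1 − confidence (31% at 69%). With σ proportional to the
mean — which is what constant CV implies — the exact minimum-density
overlap of adjacent levels is slightly larger (≈ 0.35 at CV 0.083);
`exact_adjacent_overlap` computes it by numeric integration as a
diagnostic. The headline numbers use the equal-σ convention.

No SNR-to-percent-correct psychophysical mapping is implemented; the model
is parameterized directly by the discrimination probability.

## Release averaging

The binomial model treats each spike as one Bernoulli release opportunity
("one or more vesicles" collapses to a single success); short-term
plasticity is excluded — `simulate_release` accepts a per-spike probability
sequence as a hook, but none is shipped. The default table uses
p_r ∈ {0.1, 0.2, 0.5} and rates {1, 25} Hz at CV = 0.083. Spike counts are
reported real-valued and rounded; times format as seconds below one minute
and minutes above, to three significant figures.

## Pipeline determinism

A single integer seed expands into fixed per-component substreams
(population, pairs, vesicles, null, release) via `numpy` seed sequences
with distinct spawn keys, so each stage is reproducible in isolation and
the end-to-end report is byte-identical across runs at the same seed. The
report carries the seed, package version and a SHA-256 hash of the
canonical config.

When `use_estimated_cv` is enabled, the capacity stage consumes the pair
stage's estimated median CV instead of the configured 0.083. A 17-pair
median CV has sampling sd ≈ 0.023, so the resulting level count scatters
widely seed-to-seed (95% range roughly 17–51 levels) while remaining
centered on 26; tests assert the center, not per-seed closeness. Tight
closed-loop agreement would require on the order of hundreds of pairs.

## Problem sizes and limitations

Tests and the acceptance script run at the study's own scales: 287-spine
populations, 17 pairs per seed, 1000-seed averages for the pair-CV
recovery, 10⁴ Monte-Carlo replicates for the binomial CV, meshes of a few
thousand triangles, vesicle clouds of 100–200 points.

What passing tests show — and do not show: the generator reproduces the
*assumed* statistical structure (log-normal sizes, power-law couplings,
calibrated pair jitter), so downstream recovery tests validate the
statistical machinery, not the biology. Real reconstructions add features
the generator omits: non-log-normal tails, tracing artifacts, spatially
structured connectivity, correlated measurement error between tracers,
partial-volume truncation, and multi-synaptic-bouton configurations beyond
the simple flag modelled here. Population-specific empirical values
(regression slopes per metric, the different-dendrite pair CV of 0.39,
absolute synapse counts) are properties of particular tissue volumes and
are exercised only as qualitative properties on synthetic data.
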