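# synaptometry

Quantitative tools for dendritic-spine morphometry and the information
capacity of synapses.

In hippocampal neuropil, the size of a dendritic spine head is a structural
correlate of synaptic strength. When one axon makes synapses onto two spines
of the same dendrite, both synapses have experienced the same pre- and
postsynaptic activity history — a natural experiment on the precision of
synaptic plasticity. The spread in size within such *axon-coupled* pairs
bounds the variability of plasticity from above, and with a signal-detection
argument this bound converts into the number of distinguishable synaptic
strengths, i.e. bits of storable information per synapse.

`synaptometry` implements the full analysis chain as a tested, reusable
pipeline on synthetic data:

1. **`synaptometry.synthetic`** — a generator for spine-metric tables with a
   log-normal head-volume population, power-law cross-metric couplings,
   planted axon-coupled pairs with a calibrated within-pair jitter, toy
   watertight spine meshes (spherical head + cylindrical neck, tagged
   regions, analytic ground truth), and vesicle clouds with known docked
   labels.
2. **`synaptometry.morphometry`** — convex-hull region volumes, region
   areas, neck volume by subtraction, docked-vesicle counts by the 100-nm
   center-to-active-zone rule, PSD-centroid distances, and replicate
   measurement error (SEM).
3. **`synaptometry.pairs`** — axon-coupled pair discovery from connectivity
   labels, per-pair CV (sample sd of the two values over their mean) and its
   median, disjoint random-pairing null distributions, two-sample KS tests,
   and log-log (power-law) regressions.
4. **`synaptometry.capacity`** — the signal-detection ladder of
   distinguishable strength levels.
5. **`synaptometry.release`** — the binomial release-averaging model and its
   Monte-Carlo check.
6. **`synaptometry.pipeline` / CLI** — one reproducible run from a single
   seed, with a JSON report.

## The two core calculations

**Distinguishable strengths.** Suppose strength levels are Gaussian
distributions of spine size with a common coefficient of variation CV, tiled
over a `range`-fold span of sizes, spaced so that an ideal observer assigns
a sample to the correct level with probability *c*. With
z = √2·erf⁻¹(c), adjacent means keep the constant ratio 1 + 2·CV·z, so

    N = ln(range) / ln(1 + 2·CV·z),    bits = log₂(N).

At the empirically motivated CV = 0.083, range = 60 and c = 0.69 (the
SNR = 1 psychophysical threshold, 31% overlap between neighbours) this gives
N ≈ 26.3 levels ≈ 4.7 bits; at c = 0.76 (SNR = 2), ≈ 23 levels ≈ 4.5 bits.

**Release averaging.** Release is probabilistic: over n presynaptic spikes
the release count is Binomial(n, p_r), so CV = √((1−p_r)/(n·p_r)). Reaching
a target CV requires n = (1−p_r)/(p_r·CV²) spikes, a time window T = n/R at
spike rate R. At CV = 0.083 this means minutes of averaging at 1 Hz.

## Worked example

```python
>>> from synaptometry import DiscriminationModel, build_table, ks_two_sample, \
...     PairConfig, PopulationConfig, generate_population, generate_coupled_pairs, \
...     find_axon_coupled_pairs, median_pair_cv, random_pairing_null
>>> m = DiscriminationModel(cv=0.083, range_factor=60, confidence=0.69)
>>> round(m.n_levels, 1), m.n_levels_round, round(m.bits, 2)
(26.3, 26, 4.72)
```

26.3 distinguishable levels tile the 60-fold size range; rounded, 26 levels,
i.e. 4.72 bits of information per synapse.

```python
>>> from synaptometry.release import table_to_frame
>>> print(table_to_frame(build_table()).to_string(index=False))
 p_r  cv_target  n_spikes  n_spikes_real  T_at_1Hz_s T_at_1Hz  T_at_25Hz_s T_at_25Hz
 0.1      0.083      1306    1306.430541      1306.0 21.8 min        52.24  52.2 sec
 0.2      0.083       581     580.635796       581.0 9.68 min        23.24  23.2 sec
 0.5      0.083       145     145.158949       145.0 2.42 min         5.80   5.8 sec
```

A synapse with release probability 0.1 needs 1306 spikes — 21.8 minutes at
1 Hz, 52.2 seconds at 25 Hz — before the accumulated release count estimates
strength to within 8.3%.

```python
>>> pop = generate_population(PopulationConfig(seed=11))       # 287 spines
>>> pairs, records = generate_coupled_pairs(pop, PairConfig(seed=11))
>>> found = [p for p in find_axon_coupled_pairs(records) if p.same_dendrite]
>>> len(found), round(median_pair_cv(found), 3)
(17, 0.069)
>>> null = random_pairing_null(records, 17, 2000, seed=5)
>>> null.empirical_p(median_pair_cv(found)) < 0.01
True
```

The 17 planted axon-coupled pairs are recovered from connectivity alone;
their median per-pair CV (0.069 for this seed; 0.083 in calibration) is far
below anything seen among 2000 random re-pairings of the same spines.

The same run from a shell:

```sh
synaptometry run --seed 11 --out results/
synaptometry capacity --cv 0.083 --range-factor 60 --confidence 0.69
synaptometry timewindow --cv 0.083 --pr 0.1 --pr 0.2 --pr 0.5 --rate 1 --rate 25
```

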