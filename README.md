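# nichedyn

Climatic-niche dynamics of invasive species: has an invader conserved its
climatic niche in the new range, and has it reached geographic equilibrium
there?

`nichedyn` is a Python toolkit for invasion biogeographers that implements
the two standard lines of evidence side by side:

1. **Niche comparison in environment space.** Occurrences from the native
   and invaded ranges are projected into a common climate plane (a PCA of
   both regions' pooled background climates), smoothed into gridded
   occupancy densities corrected for climate availability, and compared
   with Schoener's overlap `D = 1 − ½ Σ |p₁ − p₂|`, directional
   similarity tests against randomly relocated niches, and the
   stability / unfilling / expansion decomposition (S + E = 1; U measures
   how much of the native niche the invader has not yet filled).
2. **Reciprocal distribution models in geographic space.** A regularized
   maximum-entropy SDM — Gibbs density `q(x) ∝ exp(λ·f(x))` with an L1
   penalty `β Σⱼ sⱼ|λⱼ|` — is fitted in each range, evaluated by replicated
   75/25 splits and rank AUC, thresholded at the 10th presence percentile,
   and projected across ranges; binary ranges are compared by area and
   inclusion, and suitability is integrated along altitude-like gradients
   into niche occupancy profiles (weighted means, KS distance).

Because the interesting quantities have no observable truth in real data,
the package ships a **virtual species simulator**: correlated, spatially
autocorrelated climate landscapes, Gaussian-niche species, and occurrence
sampling proportional to suitability, with scenario constructors whose
ground truth (conserved, unfilled, expanded niche) the estimators must
recover. All validation and the reproduction script run on these synthetic
data; real analyses take GeoTIFF-style rasters as plain-text ASCII grids
(`.asc`) plus occurrence CSVs (`lon,lat,year,source`).

## Worked example

`examples/02_niche_overlap.py` simulates a conserved-niche invasion (same
species, two independent 160×160 landscapes, 1000 records per range),
builds the shared PCA space from 10,000 background points per region, and
compares the gridded niches:

```
variance explained by PCA axes 1-2: 47.4%, 17.7%
D = 0.862; P(native->invaded) = 0.02, P(invaded->native) = 0.03; S = 0.903, U = 0.075, E = 0.097 (75% envelope)
```

The overlap is high (D = 0.86) and beats randomly relocated niches in both
directions (p ≤ 0.05); stability is near 1 with little unfilling or
expansion — the signature of a conserved niche, as built in.
`examples/03_scenario_comparison.py` contrasts all three ground truths:

```
scenario                    D      S      U      E
conserved               0.862  0.903  0.075  0.097
unfilled                0.608  1.000  0.337  0.000
expanded (2 breadths)   0.412  0.681  0.331  0.319
```

Truncating the invaded range to the central native climates leaves a
nested niche (E = 0) with large unfilling; shifting the niche center two
breadths moves a third of the invaded density into novel conditions
(E = 0.32) and drags D down. `examples/04_reciprocal_sdm.py` shows the
geographic counterpart of unfilling: the native-trained model's range
contains 100% of the invaded-trained range, covers ~4× its area, and
predicts a higher mean position on the filtered gradient.

The other examples cover the simulator itself (`01`) and the end-to-end
config-driven pipeline (`05`), which is also available from the shell:

```bash
nichedyn run --config cfg.yaml --out results_dir
nichedyn synth --scenario unfilled --out data_dir
```

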