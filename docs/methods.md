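# Methods

## Growth model

A batch culture is modelled as carbon-limited Monod competition of `n` taxa
for one shared substrate pool:

    dN_i/dt = mu_i * S/(K_s + S) * N_i
    dS/dt   = -(c_cell/Y) * sum_i dN_i/dt

Assumptions: a single rate-limiting carbon pool; no death, maintenance, lag,
cross-feeding or inhibition; populations are continuous during growth.
Because every taxon shares the factor `S/(K_s+S)`, two consequences follow
and are exploited by the tests: (i) the final total size is stoichiometric,
`N_tot(∞) = N_tot(0) + Y·S0/c_cell`, independent of all `mu_i` and `K_s`;
(ii) final compositions are `N_i(0)·exp(mu_i·tau)` for a common effective
exposure `tau`, so faster growers gain share monotonically.

Stochasticity enters only at two multinomial bottlenecks — drawing the
inoculum (default 200,000 cells) from the pool's relative abundances, and
subsampling the grown community to read depth (default 200,000) — which is
exactly the design needed to ask whether sampling noise alone explains
replicate divergence. A taxon drawn at zero cells stays at zero
deterministically.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `c_cell` | carbon per cell | 2×10⁻¹³ g (200 fg) | typical soil-bacterium carbon quota |
| `Y` | biomass-C yield on substrate-C | 0.2 | conservative heterotrophic yield |
| `S0` | substrate carbon per batch | 2×10⁻⁴ g | grows a 2×10⁵-cell inoculum to ~2×10⁸ cells, the observed weekly ceiling |
| `K_s` | half-saturation | 0.05·S0 | kinetic shape only; scaled to S0 so depletion completes on the batch timescale. K_s never affects final sizes, only time courses |
| `mu` range | mapped growth rates | 0.01–0.4 h⁻¹ | slow-to-moderate soil heterotrophs |
| focal rates | rare fast-growers | 0.55, 0.25, 0.8, 0.6, 0.35 h⁻¹ | the overridden high-rate taxa of the bottleneck design |

The growth-rate map is linear in log10 relative abundance with the *most
abundant taxon fastest*. The direction and functional form are a package
design choice: an abundance-skewed map needs a direction, and abundant→fast
makes the dominant taxa consistent with their having grown to dominance;
the rare-fast focal taxa are then explicit overrides, which keeps the
contrast between mapped and focal taxa sharp. Degenerate cases (single
taxon, equal abundances, collapsed rate interval) resolve to `mu_max`.

### Numerics

`solve_ivp` (LSODA, rtol 1e-8, per-state absolute tolerances) integrates the
system with a terminal event at `S = 1e-6·S0` and a hard cap of 10,000 h.
The residual substrate at termination corresponds to ≤ Y·10⁻⁶·S0/c_cell
cells (hundreds, against ~10⁸), far inside the 0.1% mass-balance band the
tests enforce. Zero-count taxa are pinned to exactly zero after integration
to remove solver noise. The independent checks are a fixed-step explicit
Euler oracle (step 10⁻³ h, final partial step consuming exactly the
remaining carbon) and the stoichiometric closed form.

## Serial transfers

Each cycle: batch growth on fresh `S0` (plus carried-over unconsumed
substrate) → record a depth-subsampled composition table → binomial 1:10
thinning of every taxon's (rounded) integer count into the next cycle.
Thinning is stochastic per cell because the transfer bottleneck is part of
the phenomenon; deterministic division would suppress exactly the
variability under study. A community smaller than the dilution factor is
flagged extinct and the trajectory truncated. The cycle engine renders the
experimental weekly-transfer regime in silico; the long-incubation decline
seen in real microcosms involves death/turnover and is out of scope.

## Strain quantification

A read is assigned to a strain iff the strain's unique 60- or 90-nt
identifier occurs as an exact forward-strand substring (reverse-complement
search is available behind a flag, off by default, matching counting on
oriented merged reads). Reads matching two or more identifiers are excluded
as ambiguous and logged; reads matching none are unclassified. Counting is
per read, not per occurrence. Corrected counts are `raw/operon_copies`
(reads → cells), relative abundances are corrected counts over their sum,
and absolute abundances are relative abundances times an externally measured
total cell density, so they sum to that total by construction. An all-zero
count vector returns an explicit empty-community table rather than NaNs.
`select_identifiers` offers a minimal-unique-window utility for building
catalogs from marker genes; curating real catalogs remains a manual task.

## Flow cytometry

Cell-like events satisfy strictly `FSC-H > 50` and `FITC-H > 350`
(instrument units; thresholds configurable). Background from uninoculated
blanks is subtracted on *gated counts* at matched volume and dilution — a
documented choice; subtracting derived densities is equivalent when volumes
match. Density = net counts / acquisition volume × dilution, clipped at
zero. Plain CSV only; FCS parsing is out of scope.

## Metrics and calculators

Depth normalisation rescales each sample to a common continuous total
(default 5×10⁴) without rounding, avoiding floor artefacts; richness counts
taxa at ≥ 1 normalised read. Shannon is in natural log (units: nats).
Bray-Curtis is Σ|x−y|/Σ(x+y) (delegated to scipy; cross-checked against
scikit-bio in tests). Replicate variability is each replicate's Bray-Curtis
distance to its group's arithmetic-mean composition; singleton groups warn
and return 0. Ordination, PERMANOVA and dispersion tests are deliberately
left to external stats environments — the package exports plain TSV distance
matrices for them. The budget calculators (supportable cells from TOC,
fold/doublings, nominal solvent concentration with toluene constants
0.867 g/mL and 92.14 g/mol, RockEval HI/OI) are pure arithmetic, kept in
code so the printed numbers are reproducible rather than copied.

## Synthetic data

The fixture generators emulate the statistical *shape* of the real inputs,
not their content: a lognormal rank-abundance pool (default 314 taxa,
σ_log = 2, giving ≥ half the taxa below 10⁻³ relative abundance — a soil-like
long tail; the actually measured soil abundance vector is not public, so the
pool is a synthetic stand-in); error-free reads embedding exactly one
identifier each, with rejection checks against chance identifier collisions
and an exact truth table; and two-population FCM event tables with normal
channel draws, either hard-separated from the gate (`strict`, the default,
so truth counts are exact) or overlapping with closed-form expected
misclassification rates in the metadata. All generators are pure functions
of (parameters, seed) and byte-reproducible.

What passing tests therefore show: the pipeline arithmetic, the sampling
statistics and the growth model's guarantees are correct. What they do not
show: robustness to sequencing error, chimeras, primer bias, real FCM
spectral overlap, or non-lognormal soil communities.

## Problem sizes

The default test and acceptance runs use the full study-scale simulation
(314 taxa, 200,000-cell inocula, five replicates — the ODE system is small
enough that this costs milliseconds) and read sets of 10⁴–2×10⁴ reads,
chosen so multinomial 3-SD bands are a few tenths of a percent wide.

## Known limitations

- No interactions, death or lag: long-incubation succession and decline are
  outside the model.
- The carbon pool size `S0` in the simulations is a calibration to the
  observed final density, not a measured quantity.
- Identifier counting is exact-match; one sequencing error in an identifier
  window drops the read (acceptable for proportion estimates with error-free
  merging or high-quality filtering; biased under heavy error).
- The growth-rate/abundance map's direction is a modelling choice flagged
  above; reversing it changes compositions, not totals.
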