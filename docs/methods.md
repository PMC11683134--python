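# Methods

## Measurement model and estimator

Total stainable DNA per cell is `N + c·s`, with `N` the nuclear genome size
at the cell's cycle stage (12.1 Mb at 1n, 24.2 Mb at 2n), `c` the mtDNA
copy number and `s = 0.085 Mb` the mitochondrial genome size. The stain
signal is assumed proportional to this mass, up to a per-cell multiplicative
noise. On the log2 axis the instrument gain is an additive constant that
cancels in every contrast, which is why all shifts are read on log2 modes:

- **rho contrast** `Δ = mode(rho+) − mode(rho0)` at the same peak and
  condition gives `c = (2^Δ − 1)·N/s`. The estimator is strictly increasing
  in Δ and continuous at 0; a negative Δ (noise near c = 0) is floored at
  zero with a warning rather than silently.
- **arrest contrast** `δ = mode(37 °C) − mode(25 °C)` within one strain. The
  rho0 strain also shows a small positive δ₀ of unknown origin (plasmids,
  rDNA rings); the default formula treats it as a multiplicative
  mtDNA-independent background on the nuclear-dominated signal,
  `surplus = N·(2^δ⁺ − 2^δ₀)/s`. An alternative reading — the background
  scales the whole baseline signal including mtDNA,
  `surplus = (2^(δ⁺−δ₀) − 1)(N + c₀·s)/s` — is available as
  `formula="ratio"`. For shifts of the observed magnitude the two differ by
  a few percent. Fold change is `1 + surplus/baseline`; the baseline for a
  G1-arrested (1n) strain defaults to half the 2n copy estimate.
- Replicates are aggregated as mean ± SD (ddof = 1) of per-replicate copy
  numbers, i.e. after the nonlinear `2^Δ` transform, not before.

The 2µ plasmid bound `plasmid_max_count · plasmid_unit / s = 4.45`
copies-equivalent quantifies the worst-case overestimate from the
endogenous multicopy plasmid.

## Density estimation and mode detection

The log2 signal density is a Gaussian KDE with Silverman's bandwidth
(`0.9·min(sd, IQR/1.34)·n^(−1/5)`), evaluated on a 1024-point grid spanning
the data range ± 3 bandwidths. Implementation: histogram on the grid
convolved with the Gaussian kernel (`mode="constant"`), mathematically a
binned KDE — O(n + m) instead of the O(n·m) direct sum, exact to well below
grid spacing, and the profile integrates to 1 within 1%. Constant-valued
input raises a degenerate-input error rather than producing a grid spike;
fewer than 100 events raises a sample-size error.

Modes are local maxima with prominence ≥ 5% of the global density maximum
(`scipy.signal.find_peaks`). Up to two are kept: with two, the lower is 1n
and the upper 2n; with more candidates, the most prominent pair whose
spacing is closest to 1.0 log2 unit wins (DNA doubling fixes the spacing; a
|gap − 1| > 0.15 flag marks suspicious pairs). A lone mode is labelled by
the sample's expected arrest ploidy, since G1-arrested cultures sit at 1n
and G2/M-arrested cultures at 2n. Mode positions are reported at grid
resolution, with no sub-grid interpolation — grid spacing (~0.001–0.003
log2 units on typical data) is an order of magnitude below every tolerance
used, and it keeps the detector exactly verifiable against an exhaustive
local-maximum search.

Gates: the CV analysis uses `[mode_2n, mode_2n + width]` with width 0.5 by
default, hard-capped at +1.0 log2 units to exclude 4n/doublet signal; the
scaling regression gates `mode ± 0.25` log2 units around the chosen peak.
Neither gate width is prescribed by the source experiments; both are
exposed as options.

## Size scaling and binned CV

Scaling is plain OLS of log2 fluorescence on log2 FSC-A
(`scipy.stats.linregress`), no trimming or robust variant, minimum 500
gated events. The rho+/rho0 comparison reports slope ratio and difference
and flags ratio ≥ 2. In simulations the rho0 slope is measurement noise
around zero, so the ratio's sign is unstable even though its magnitude is
huge; the robust statement, and the one the tests assert, is that the rho+
slope exceeds the rho0 slope magnitude (which implies ratio > 1 whenever
the rho0 slope is positive).

The binned CV is sd/mean of the **linear** fluorescence within half-open
log2 FSC bins (default width 0.1), anchored at the gated population's
minimum FSC or at an explicit shared anchor so two samples can be compared
bin-by-bin. Bins under 200 events are reported but flagged excluded. CV on
the linear scale is gain-invariant; CV of a logged quantity would depend on
arbitrary units. The population CV (no binning) is reported alongside.

**Gate-edge truncation.** When fluorescence is coupled to size, a
fluorescence gate acts as a soft size cut: size bins whose mean signal sits
within a few noise SDs of a gate edge contain only noise-selected events
and their CV is biased low (lower edge) or clipped (upper edge).
`truncation_free_bins` returns the bins whose mean log2 signal lies ≥ k
(default 3) measurement-noise SDs inside the gate; only there is the
per-bin CV interpretable as intrinsic variation. The flatness diagnostics
use these interior bins; the monotone-trend diagnostic for stochastic
accumulation uses all qualifying bins, because there the gate clips every
size bin equally and the trend survives.

## Synthetic populations

Per event: cycle class from `ploidy_fractions` (default G1/S/G2M =
0.35/0.25/0.40, an exponential-phase mix); true size `v = 2^x` with
`x ~ Normal(16.0, 0.5)` (log2 FSC-A a.u.); FSC adds `Normal(0, 0.2)` optics
noise in log2; nuclear DNA is 12.1 Mb (G1), 24.2 Mb (G2M) or uniform in
between (S); copies `c = round(c̄(ploidy)·(v/v̄)^β·η)` with gamma
`η` (mean 1, CV `copies_cv` = 0.25 by default), `c̄(G2M) = c̄(S) = 30.8`,
`c̄(G1) = 15.4` so the 1n and 2n rho contrasts match; rho0 forces c = 0.
Signal is `gain·(N + c·s)·background_inflation·ε` with lognormal `ε`
(mean 1, CV `measurement_cv` = 0.05) and gain 2000 a.u./Mb, putting signals
in a realistic 5·10⁴ a.u. range. The analytic rho contrast is
`log2(1 + c̄·s/N)` = 0.148 at defaults.

Arrest pairs: the arrested member contains only the arrested ploidy class
(arrest eliminates budded cells), is `growth_factor` (default 2.5) larger,
and accumulates `accumulation_fold` (default 3.3) more copies either
**size-coupled** (β = 1: copies track realised size — the regulated
scenario) or as a **stochastic walk** (copies decoupled from size with
extra lognormal dispersion whose sigma grows as `walk_dispersion·√(v/v̄)` —
the unregulated scenario; per-size-bin CV rises with size by
construction). `background_inflation` is applied to the arrested member
only, since it models the arrest-specific rho0 signal increase; the control
member is generated without it.

Not modelled: spectral properties of individual dyes, cell-shape effects on
scatter, debris/doublets, S-phase mtDNA dynamics (S-phase cells get the
2n-level copy mean; they are excluded from every estimator anyway). A green
simulation test therefore establishes correctness of the estimators under
the stated noise model, not robustness to instrument artefacts.

## Numerical and statistical choices

- The mode-shift estimator targets the **modal**, not mean, copy number:
  with 25% gamma dispersion the copy-distribution mode sits ~6% below the
  mean, so recovery tests that compare against an exact true c set
  `copies_cv = 0`; with the default dispersion the recovered copy number is
  biased low by roughly that amount at low c.
- The per-bin-CV ≈ measurement-CV identity holds when FSC is a faithful
  size readout; with the default 0.2 log2 FSC noise an FSC bin mixes true
  sizes and legitimately carries extra CV from the size-coupled component,
  so that diagnostic is run at `fsc_noise_sd = 0.02`.
- Published constants are embedded as defaults (`GenomeParams`); the
  reported surplus for G2/M arrest computed from the *rounded* published
  shifts (0.7, 0.3) is ~112 copies under the default formula (~118 under
  the ratio variant), not the published ~147 — evidently the original
  calculation used unrounded per-replicate shifts. The package does not
  force agreement; the fold identity `1 + 147/30.8 = 5.77 ≈ 5.8` is exact.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the specs; mode detection itself is deterministic. Pipeline reports round
  floats to 6 decimals and sort keys, making reruns byte-identical.

## Limitations

- The method is semi-quantitative: it assumes stain fluorescence strictly
  proportional to DNA mass regardless of GC content, chromatin state or
  dye access, and attributes the whole rho+/rho0 signal difference to
  mtDNA (the plasmid bound quantifies the largest known bias).
- Mode positions at 1n can be undetectable in exponentially growing rho+
  cultures (S-phase shoulder); the detector then reports a single labelled
  mode rather than guessing.
- The rho0 arrest background is treated phenomenologically; its biological
  source is unidentified, and the two surplus formulas bracket the
  plausible treatments.
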