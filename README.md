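# cytomito

Semi-quantitative estimation of mitochondrial DNA (mtDNA) copy number in
budding yeast from DNA-stain flow cytometry.

## The idea

A DNA-intercalating dye (Sytox Green, propidium iodide) makes each cell
fluoresce in proportion to its total stainable DNA. In *S. cerevisiae* the
mitochondrial genome is unusually large (s = 0.085 Mb) relative to the
nuclear genome (N = 12.1 Mb haploid, 24.2 Mb diploid), so a few dozen mtDNA
copies add a measurable few percent to the total signal. Comparing cells
that have mtDNA (rho+) with cells completely lacking it (rho0) therefore
turns a fluorescence histogram into a copy-number assay: on a log2 axis the
mode shift Δ between the matched rho+ and rho0 peaks gives

```
c = (2^Δ − 1) · N / s        (mtDNA copies per cell)
```

A measured 2n-peak shift of Δ ≈ 0.15 log2 units corresponds to ~31 copies
per G2/M cell. The same bookkeeping quantifies mtDNA accumulation during
cell-cycle arrest (thermosensitive *cdc* mutants at 37 °C): the arrest
shift of the rho+ strain, corrected by the matched rho0 shift δ₀ (an
mtDNA-independent background), yields the surplus

```
surplus = N · (2^δ⁺ − 2^δ₀) / s,     fold = 1 + surplus / baseline.
```

Beyond population averages, the per-event data support two single-cell
analyses: an OLS regression of log2 fluorescence on log2 forward scatter
(FSC-A, a cell-size proxy) inside a ploidy gate, which asks whether the
signal scales with cell size; and the coefficient of variation (CV) of the
stain signal within narrow cell-size bins (≥ 200 cells per bin) on the
right flank of the 2n peak, which asks whether similarly sized cells are
uniform in mtDNA content — a flat, low per-bin CV profile is the signature
of regulated copy number, a CV rising with size the signature of
unregulated stochastic accumulation.

The package implements this whole pipeline — FCS/CSV event I/O, log2
transform, kernel-density 1n/2n mode detection, copy-number and surplus
arithmetic, size-scaling regression, binned-CV profiles — plus a synthetic
population generator with ground-truth labels (ploidy mix, per-cell copies
with selectable size coupling, measurement noise) so every stage is
testable without instrument data.

## Worked example

```python
import cytomito as cm

g = cm.GenomeParams()                      # 0.085 / 12.1 / 24.2 Mb defaults

# absolute copies from the 2n rho+ vs rho0 mode shift
est = cm.copies_from_rho_contrast(0.15, g, ploidy="2n")
print(round(est.copies, 1))                # 31.2 copies per 2n cell

# upper bound on the 2-micron plasmid bias
print(round(cm.plasmid_equivalent_copies(g), 2))   # 4.45 copies-equivalent

# G1-arrest surplus from arrest shifts (rho+ 0.4, rho0 0.1) at the 1n peak
res = cm.arrest_surplus(0.4, 0.1, baseline=15.4, genome=g, ploidy="1n")
print(round(res.surplus_copies, 1), round(res.fold_change, 2))  # 35.3 3.29

# simulate a matched pair and recover the shift through the full pipeline
spec = dict(ploidy_fractions={"G1": 0, "S": 0, "G2M": 1}, measurement_cv=0.05)
plus = cm.generate_population(cm.PopulationSpec(seed=11, **spec))
zero = cm.generate_population(
    cm.PopulationSpec(mito_status="rho_zero", seed=12, **spec))

def mode_2n(table):
    t = cm.log2_transform(table)
    d = cm.estimate_density(t.events["fluor_log2"].to_numpy())
    return cm.find_peak_modes(d).mode_2n

print(round(mode_2n(plus) - mode_2n(zero), 3))     # 0.154 log2 units
```

The printed 31.2 is the copy number implied by the 0.15 log2 shift; 4.45 is
the worst-case overestimate attributable to the endogenous 2µ plasmid; 35.3
surplus copies and fold 3.29 describe a G1-arrested culture; and 0.154 is
the shift a 50,000-event simulated pair returns through density estimation
and mode detection (truth: 0.148 analytically).

## Command line

```
cytomito simulate --seed 4 --out sim.csv      # synthetic 50k-event sample
cytomito modes sim.csv                        # 1n/2n mode positions
cytomito scaling sim.csv --gate-ploidy 2n     # size-scaling OLS fit
cytomito cv sim.csv --bin-width 0.1           # size-binned CV profile
cytomito run config.yaml                      # full multi-sample pipeline
```

`cytomito run` takes a YAML config listing samples with their roles
(rho+/rho0 × 25 °C/37 °C, arrest ploidy, replicate id) and writes a JSON
report with per-replicate and mean ± SD mode positions, shifts, copy
numbers, surpluses, folds, scaling fits and CV profiles. Re-running an
identical config reproduces byte-identical outputs.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from package code alone: the plasmid-load copy equivalent, the
absolute 2n copy number implied by the 0.15 log2 shift, the G1-arrest
surplus implied by the (0.4, 0.1) shift pair, and the 2n mode shift
recovered by the full detection pipeline from matched 50,000-event
synthetic rho+/rho0 populations (averaged over ten seed pairs), writing the
results as JSON.
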