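"""Synthetic flow-cytometry populations with ground-truth labels.

Generates event tables with the statistical structure the analysis assumes,
standing in for deposited raw data so that every pipeline stage is testable.

Measurement model (per event i):

    fluor_linear_i = gain * (nDNA_i + c_i * s) * background_inflation * eps_i
    fsc_linear_i   = 2 ** (size_log2_i + Normal(0, fsc_noise_sd))

where s is the mtDNA genome size, ``eps_i`` is lognormal with mean 1 and CV
``measurement_cv`` (stain chemistry + optics noise), and the per-cell copy
number is

    c_i = round(copies_mean(ploidy_i) * (v_i / v_bar)**beta * eta_i)

with ``v_i = 2**size_log2_i`` the true cell size, ``v_bar`` its geometric
mean, ``beta`` the size-coupling exponent (0 = mtDNA decoupled from size, 1 =
proportional), and ``eta_i`` gamma-distributed with mean 1 and CV
``copies_cv``. G1 cells carry half the 2n copy mean (mtDNA roughly doubles
over the cycle along with everything else), S-phase cells get nuclear DNA
uniform between 1n and 2n but the 2n-level copy mean, and rho0 cells carry
zero copies regardless of other settings. ``background_inflation`` models
the moderate mtDNA-independent signal increase that arrested rho0 cells
show; it multiplies the whole stain signal.

Arrest pairs add a size multiplier (``growth_factor``) and copy accumulation
in one of two modes: ``size_coupled`` (copies track realised size, beta = 1 —
the regulated scenario) or ``stochastic_walk`` (copies pick up extra
multiplicative dispersion growing with cell size — the unregulated scenario
whose per-size-bin CV rises with size).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .copynumber import GenomeParams
from .errors import SpecError
from .events import EventTable

PLOIDY_CLASSES = ("G1", "S", "G2M")
#: exponential-phase budding yeast cycle-phase mix
DEFAULT_PLOIDY_FRACTIONS = {"G1": 0.35, "S": 0.25, "G2M": 0.40}


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters for one stained suspension.

    Defaults describe a 50,000-event exponentially growing rho+ diploid-DNA
    culture with 30.8 mtDNA copies per 2n cell, 25% intercellular copy
    spread, 5% multiplicative measurement noise, and FSC-A centred at
    2**16 a.u. with 0.5 log2 units of true size spread plus 0.2 log2 units
    of optics noise.
    """

    n_events: int = 50_000
    mito_status: str = "rho_plus"
    ploidy_fractions: dict = field(default_factory=lambda: dict(DEFAULT_PLOIDY_FRACTIONS))
    genome: GenomeParams = GenomeParams()
    copies_mean_2n: float = 30.8
    copies_cv: float = 0.25
    size_log2_mean: float = 16.0
    size_log2_sd: float = 0.5
    size_coupling_beta: float = 0.0
    fsc_noise_sd: float = 0.2
    measurement_cv: float = 0.05
    background_inflation: float = 1.0
    gain: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise SpecError("n_events must be positive")
        if self.mito_status not in ("rho_plus", "rho_zero"):
            raise SpecError("mito_status must be rho_plus or rho_zero")
        fr = self.ploidy_fractions
        if set(fr) - set(PLOIDY_CLASSES):
            raise SpecError(f"unknown ploidy classes {set(fr) - set(PLOIDY_CLASSES)}")
        vals = [fr.get(k, 0.0) for k in PLOIDY_CLASSES]
        if any(v < 0 for v in vals):
            raise SpecError("ploidy fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise SpecError(f"ploidy fractions must sum to 1, got {sum(vals)}")
        for name in ("copies_cv", "fsc_noise_sd", "measurement_cv"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be non-negative")
        if self.background_inflation < 1.0:
            raise SpecError("background_inflation must be >= 1")
        if self.gain <= 0 or self.size_log2_sd < 0:
            raise SpecError("gain must be positive and size_log2_sd non-negative")


@dataclass(frozen=True)
class ArrestSpec:
    """A matched 25C control / 37C arrested pair.

    The arrested suspension contains only the arrested ploidy class (no
    budded cells), is ``growth_factor``-fold larger, and has accumulated
    ``accumulation_fold``-fold mtDNA in the chosen ``accumulation_mode``.
    ``base.background_inflation`` is applied to the arrested member only (it
    models the arrest-specific rho0 signal increase); the control is
    generated without it.
    """

    base: PopulationSpec
    arrest_ploidy: str = "2n"
    growth_factor: float = 2.5
    accumulation_mode: str = "size_coupled"
    accumulation_fold: float = 3.3
    walk_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.arrest_ploidy not in ("1n", "2n"):
            raise SpecError("arrest_ploidy must be 1n or 2n")
        if self.growth_factor < 1.0:
            raise SpecError("growth_factor must be >= 1")
        if self.accumulation_mode not in ("size_coupled", "stochastic_walk"):
            raise SpecError("accumulation_mode must be size_coupled or stochastic_walk")
        if self.accumulation_fold < 1.0 or self.walk_dispersion < 0:
            raise SpecError("accumulation_fold >= 1 and walk_dispersion >= 0 required")


def expected_rho_contrast(spec: PopulationSpec, ploidy: str = "2n") -> float:
    """Analytic log2 mode contrast of this population against a matched rho0.

    For mean copies c and nuclear size N the stain-signal ratio is
    (N + c*s)/N, so the expected mode shift is log2(1 + c*s/N); it is the
    same at both peaks because copies and nuclear DNA both halve at 1n.
    """
    g = spec.genome
    c = spec.copies_mean_2n if ploidy == "2n" else spec.copies_mean_2n / 2.0
    return float(np.log2(1.0 + c * g.mtdna_size / g.ndna(ploidy)))


def _generate(
    spec: PopulationSpec,
    sample_id: str,
    walk_dispersion: float = 0.0,
    walk_size_ref_log2: float | None = None,
) -> EventTable:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    g = spec.genome

    fractions = np.array([spec.ploidy_fractions.get(k, 0.0) for k in PLOIDY_CLASSES])
    ploidy_idx = rng.choice(3, size=n, p=fractions / fractions.sum())
    ploidy = np.array(PLOIDY_CLASSES)[ploidy_idx]

    size_log2 = rng.normal(spec.size_log2_mean, spec.size_log2_sd, size=n)
    fsc_log2 = size_log2 + rng.normal(0.0, spec.fsc_noise_sd, size=n)
    v = np.exp2(size_log2)
    v_bar = np.exp2(spec.size_log2_mean)  # geometric mean size

    ndna = np.where(ploidy == "G1", g.ndna_1n, g.ndna_2n).astype(float)
    s_mask = ploidy == "S"
    if s_mask.any():
        ndna[s_mask] = rng.uniform(g.ndna_1n, g.ndna_2n, size=int(s_mask.sum()))

    copies_mean = np.where(ploidy == "G1", spec.copies_mean_2n / 2.0, spec.copies_mean_2n)
    if spec.copies_cv > 0:
        k = 1.0 / spec.copies_cv**2
        eta = rng.gamma(shape=k, scale=1.0 / k, size=n)
    else:
        eta = np.ones(n)
    c = copies_mean * (v / v_bar) ** spec.size_coupling_beta * eta
    if walk_dispersion > 0:
        # Unregulated accumulation: extra lognormal dispersion whose sigma
        # grows with cell size (larger arrested cells have random-walked
        # longer). Drawn from a sub-stream so the base draw path is shared
        # with the matched regulated population.
        walk_rng = np.random.default_rng([spec.seed, 7])
        v_ref = np.exp2(walk_size_ref_log2 if walk_size_ref_log2 is not None else spec.size_log2_mean)
        sigma = walk_dispersion * np.sqrt(v / v_ref)
        c = c * np.exp(walk_rng.normal(0.0, 1.0, size=n) * sigma)
    c = np.rint(np.maximum(c, 0.0)).astype(np.int64)
    if spec.mito_status == "rho_zero":
        c = np.zeros(n, dtype=np.int64)

    if spec.measurement_cv > 0:
        sigma2 = np.log(1.0 + spec.measurement_cv**2)
        eps = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)
    else:
        eps = np.ones(n)
    fluor = spec.gain * (ndna + c * g.mtdna_size) * spec.background_inflation * eps

    df = pd.DataFrame(
        {
            "fluor_linear": fluor,
            "fsc_linear": np.exp2(fsc_log2),
            "truth_ploidy_class": ploidy,
            "truth_mtdna_copies": c,
            "truth_cell_size": v,
        }
    )
    return EventTable(sample_id=sample_id, events=df)


def generate_population(spec: PopulationSpec, sample_id: str = "synthetic") -> EventTable:
    """Draw one population; reproducible given ``spec.seed``."""
    return _generate(spec, sample_id)


def generate_arrest_pair(spec: ArrestSpec) -> dict[str, EventTable]:
    """Matched control (25C) and arrested (37C) populations.

    Returns ``{"control": ..., "arrested": ...}``. Both use the base seed so
    a null arrest (growth_factor = accumulation_fold = 1, matching ploidy
    mix and coupling) reproduces the control exactly.
    """
    base = spec.base
    control = generate_population(
        replace(base, background_inflation=1.0), sample_id="control_25C"
    )

    pure = {"G1": 0.0, "S": 0.0, "G2M": 0.0}
    pure["G1" if spec.arrest_ploidy == "1n" else "G2M"] = 1.0
    beta = 1.0 if spec.accumulation_mode == "size_coupled" else base.size_coupling_beta
    arrested_spec = replace(
        base,
        ploidy_fractions=pure,
        size_log2_mean=base.size_log2_mean + float(np.log2(spec.growth_factor)),
        copies_mean_2n=base.copies_mean_2n * spec.accumulation_fold,
        size_coupling_beta=beta,
    )
    walk = spec.walk_dispersion if spec.accumulation_mode == "stochastic_walk" else 0.0
    arrested = _generate(
        arrested_spec,
        sample_id="arrested_37C",
        walk_dispersion=walk,
        walk_size_ref_log2=base.size_log2_mean,
    )
    return {"control": control, "arrested": arrested}
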