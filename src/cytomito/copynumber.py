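"""Convert log2 mode shifts into absolute mtDNA copy numbers.

The estimator rests on a bookkeeping identity: a DNA-intercalating stain
reports total stainable DNA, so a cell with nuclear genome size N (Mb) and c
mitochondrial genomes of size s (Mb) fluoresces in proportion to N + c*s.
A matched rho0 cell (no mtDNA) fluoresces in proportion to N alone. On a
log2 axis the mode shift between the two populations is therefore

    delta = log2((N + c*s) / N)   =>   c = (2**delta - 1) * N / s.

With the budding-yeast constants (s = 0.085 Mb, N_2n = 24.2 Mb) the
measured 2n shift of ~0.15 log2 units translates to ~31 mtDNA copies per
G2/M cell.

For cell-cycle arrest, the 37C-vs-25C shift of the rho+ sample (delta_plus)
contains both genuine mtDNA accumulation and a small mtDNA-independent
background increase that the matched rho0 sample also shows (delta_zero).
The default surplus formula treats that background as a multiplicative
inflation of the nuclear-dominated signal:

    surplus = N * (2**delta_plus - 2**delta_zero) / s.

An alternative variant ("ratio") divides out the background first and scales
the full baseline signal including mtDNA; both are exposed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

PLOIDIES = ("1n", "2n")
SHIFT_KINDS = ("rho_contrast", "arrest_contrast")


@dataclass(frozen=True)
class GenomeParams:
    """Genome-size constants, all in Mb.

    Defaults are the budding-yeast values: mtDNA 0.085 Mb, diploid nuclear
    genome 24.2 Mb, endogenous 2-micron plasmid 6.3 kb at up to 60 copies.
    """

    mtdna_size: float = 0.085
    ndna_1n: float = 12.1
    ndna_2n: float = 24.2
    plasmid_unit: float = 0.0063
    plasmid_max_count: int = 60

    def __post_init__(self) -> None:
        for name in ("mtdna_size", "ndna_1n", "ndna_2n", "plasmid_unit"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if not np.isclose(self.ndna_2n, 2 * self.ndna_1n, rtol=1e-6):
            raise ContractError("ndna_2n must equal 2 * ndna_1n")

    def ndna(self, ploidy: str) -> float:
        if ploidy not in PLOIDIES:
            raise ContractError(f"ploidy must be one of {PLOIDIES}")
        return self.ndna_1n if ploidy == "1n" else self.ndna_2n


@dataclass(frozen=True)
class ModeShift:
    """A log2 mode-position difference between two samples at one peak.

    ``kind`` is ``rho_contrast`` for rho+ minus rho0 under the same condition
    (the absolute copy-number basis) or ``arrest_contrast`` for 37C minus
    25C within one strain (the accumulation basis).
    """

    delta: float
    ploidy: str
    kind: str

    def __post_init__(self) -> None:
        if self.ploidy not in PLOIDIES:
            raise ContractError(f"ploidy must be one of {PLOIDIES}")
        if self.kind not in SHIFT_KINDS:
            raise ContractError(f"kind must be one of {SHIFT_KINDS}")


@dataclass
class CopyNumberEstimate:
    """mtDNA copies per cell at one ploidy, with replicate spread if available."""

    copies: float
    ploidy: str
    copies_sd: float | None = None
    basis: tuple = ()
    clipped_negative: bool = False


@dataclass
class ArrestResult:
    """Arrest-induced surplus mtDNA copies and the resulting fold change."""

    surplus_copies: float
    fold_change: float
    delta_rho_plus: float
    delta_rho_zero: float
    baseline_copies: float
    ploidy: str
    formula: str = "background"


def copies_from_rho_contrast(
    shift: ModeShift | float, genome: GenomeParams = GenomeParams(), ploidy: str | None = None
) -> CopyNumberEstimate:
    """mtDNA copies per cell from a rho+ vs rho0 mode shift.

    Accepts a :class:`ModeShift` (of kind ``rho_contrast``) or a bare delta
    with ``ploidy`` given. A negative delta — possible from noise when true
    copy number is near zero — is floored at zero with a warning and flagged.
    """
    if isinstance(shift, ModeShift):
        if shift.kind != "rho_contrast":
            raise ContractError("copies_from_rho_contrast requires a rho_contrast shift")
        delta, ploidy = shift.delta, shift.ploidy
        basis = (shift,)
    else:
        if ploidy is None:
            raise ContractError("ploidy required when passing a bare delta")
        delta = float(shift)
        basis = (ModeShift(delta=delta, ploidy=ploidy, kind="rho_contrast"),)
    clipped = False
    if delta < 0:
        warnings.warn(
            f"negative rho contrast ({delta:.3f} log2 units) floored to 0 copies",
            stacklevel=2,
        )
        delta = 0.0
        clipped = True
    copies = (2.0**delta - 1.0) * genome.ndna(ploidy) / genome.mtdna_size
    return CopyNumberEstimate(
        copies=copies, ploidy=ploidy, basis=basis, clipped_negative=clipped
    )


def plasmid_equivalent_copies(genome: GenomeParams = GenomeParams()) -> float:
    """Maximal 2-micron plasmid load expressed in mtDNA-copy equivalents.

    The endogenous 2-micron plasmid inflates total stainable DNA; at the
    maximal load this bias is worth plasmid_max_count * plasmid_unit /
    mtdna_size copies (4.45 with defaults), the upper bound on the
    overestimate it can cause.
    """
    return genome.plasmid_max_count * genome.plasmid_unit / genome.mtdna_size


def arrest_surplus(
    delta_plus: ModeShift | float,
    delta_zero: ModeShift | float,
    baseline: CopyNumberEstimate | float,
    genome: GenomeParams = GenomeParams(),
    ploidy: str | None = None,
    formula: str = "background",
) -> ArrestResult:
    """Surplus mtDNA copies accumulated during arrest, and the fold change.

    ``delta_plus`` / ``delta_zero`` are the arrest contrasts (37C minus 25C
    mode position) of the rho+ and matched rho0 strains at the same peak.
    ``baseline`` is the pre-arrest copy number at that ploidy (for a
    G1-arrested strain, half the 2n estimate by default — see
    :func:`baseline_for_ploidy`).

    formula="background" (default):
        surplus = N * (2**d+ - 2**d0) / s
    formula="ratio":
        surplus = (2**(d+ - d0) - 1) * (N + c0*s) / s
    Both collapse to 0 when d+ == d0. fold = 1 + surplus / baseline.
    """

    def unpack(x, name):
        if isinstance(x, ModeShift):
            if x.kind != "arrest_contrast":
                raise ContractError(f"{name} must be an arrest_contrast shift")
            return x.delta, x.ploidy
        return float(x), None

    dp, pp = unpack(delta_plus, "delta_plus")
    dz, pz = unpack(delta_zero, "delta_zero")
    ploidies = {p for p in (pp, pz, ploidy) if p is not None}
    if len(ploidies) > 1:
        raise ContractError(f"mismatched ploidies in arrest contrast: {sorted(ploidies)}")
    if not ploidies:
        raise ContractError("ploidy must be supplied with bare deltas")
    ploidy = ploidies.pop()

    c0 = baseline.copies if isinstance(baseline, CopyNumberEstimate) else float(baseline)
    N = genome.ndna(ploidy)
    s = genome.mtdna_size
    if formula == "background":
        surplus = N * (2.0**dp - 2.0**dz) / s
    elif formula == "ratio":
        surplus = (2.0 ** (dp - dz) - 1.0) * (N + c0 * s) / s
    else:
        raise ContractError(f"unknown surplus formula {formula!r}")
    if c0 > 0:
        fold = 1.0 + surplus / c0
    else:
        fold = float("nan")
    return ArrestResult(
        surplus_copies=surplus,
        fold_change=fold,
        delta_rho_plus=dp,
        delta_rho_zero=dz,
        baseline_copies=c0,
        ploidy=ploidy,
        formula=formula,
    )


def baseline_for_ploidy(
    copies_2n: float, ploidy: str, override: float | None = None
) -> float:
    """Pre-arrest copy number at the arrest ploidy.

    A G1-arrested (1n) strain starts from half the 2n copy number — mtDNA
    content roughly doubles over the cell cycle along with everything else —
    unless an explicit override is supplied.
    """
    if override is not None:
        return float(override)
    if ploidy == "1n":
        return copies_2n / 2.0
    if ploidy == "2n":
        return float(copies_2n)
    raise ContractError(f"ploidy must be one of {PLOIDIES}")


def aggregate_replicates(estimates: list[CopyNumberEstimate]) -> CopyNumberEstimate:
    """Mean +/- SD over per-replicate copy-number estimates.

    Copies are computed per replicate pair and then averaged — the nonlinear
    2**delta transform is applied before aggregation, not after.
    SD (ddof=1) is reported only with >= 2 replicates.
    """
    if not estimates:
        raise ContractError("no estimates to aggregate")
    ploidies = {e.ploidy for e in estimates}
    if len(ploidies) > 1:
        raise ContractError(f"cannot aggregate across ploidies {sorted(ploidies)}")
    vals = np.array([e.copies for e in estimates], dtype=float)
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else None
    basis = tuple(b for e in estimates for b in e.basis)
    return CopyNumberEstimate(
        copies=float(vals.mean()),
        ploidy=ploidies.pop(),
        copies_sd=sd,
        basis=basis,
        clipped_negative=any(e.clipped_negative for e in estimates),
    )
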