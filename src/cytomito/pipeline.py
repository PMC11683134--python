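"""End-to-end pipeline: read -> transform -> modes -> estimates -> regression -> CV.

Driven by a declarative YAML/dict config listing samples with their
experimental roles (rho+/rho0, 25C control / 37C arrested, arrest ploidy)
and replicate ids. Produces a machine-readable JSON report plus per-analysis
CSVs; re-running with an identical config and seed reproduces byte-identical
outputs (fixed key ordering and float formatting).

Per replicate the report contains: detected peak modes, rho-contrast shifts
and the copy numbers they imply, arrest-contrast shifts with surplus and
fold change, size-scaling fits with the rho+/rho0 slope comparison, and
size-binned CV profiles; each quantity is also aggregated over replicates as
mean +/- SD.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cv as cv_mod
from . import density, scaling
from .copynumber import (
    GenomeParams,
    ModeShift,
    aggregate_replicates,
    arrest_surplus,
    baseline_for_ploidy,
    copies_from_rho_contrast,
)
from .errors import ConfigError, CytomitoError
from .events import SampleRole, log2_transform, read_events

logger = logging.getLogger("cytomito")

ROLE_MEMBERS = [
    ("rho_plus", "control_25C"),
    ("rho_zero", "control_25C"),
    ("rho_plus", "arrested_37C"),
    ("rho_zero", "arrested_37C"),
]


class PipelineStageError(CytomitoError):
    """A stage failed; names the stage and sample for diagnosis."""

    def __init__(self, stage: str, sample_id: str, cause: Exception):
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")


@dataclass
class SampleEntry:
    path: str
    role: SampleRole
    replicate_id: str
    format: str | None = None
    channel_map: dict | None = None

    @property
    def sample_id(self) -> str:
        return f"{self.role.mito_status}_{self.role.condition}_{self.replicate_id}"


@dataclass
class AnalysisOptions:
    bandwidth: float | str = "auto"
    gate_width: float = 0.5
    bin_width: float = cv_mod.DEFAULT_BIN_WIDTH
    min_events: int = cv_mod.DEFAULT_MIN_EVENTS
    min_fit_events: int = scaling.MIN_FIT_EVENTS
    min_prominence: float = 0.05
    ploidy_gate_halfwidth: float = scaling.DEFAULT_PLOIDY_GATE_HALFWIDTH
    surplus_formula: str = "background"


@dataclass
class RunConfig:
    samples: list[SampleEntry]
    genome: GenomeParams = GenomeParams()
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    output_dir: str = "cytomito_out"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            samples = [
                SampleEntry(
                    path=s["path"],
                    role=SampleRole(
                        mito_status=s["mito_status"],
                        condition=s.get("condition", "control_25C"),
                        arrest_ploidy=s.get("arrest_ploidy", "none"),
                    ),
                    replicate_id=str(s.get("replicate_id", "r1")),
                    format=s.get("format"),
                    channel_map=s.get("channel_map"),
                )
                for s in raw["samples"]
            ]
        except KeyError as exc:
            raise ConfigError(f"sample entry missing required key {exc}") from exc
        genome = GenomeParams(**raw.get("genome", {}))
        options = AnalysisOptions(**raw.get("options", {}))
        return cls(
            samples=samples,
            genome=genome,
            options=options,
            output_dir=raw.get("output_dir", "cytomito_out"),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _validate(config: RunConfig) -> None:
    if not config.samples:
        raise ConfigError("config lists no samples")
    seen = {}
    for s in config.samples:
        key = (s.role.mito_status, s.role.condition, s.replicate_id)
        if key in seen:
            raise ConfigError(f"duplicate sample role {key}")
        seen[key] = s
    # Every arrested replicate needs all four members (rho+/rho0 x 25C/37C).
    arrested_reps = {
        s.replicate_id for s in config.samples if s.role.condition == "arrested_37C"
    }
    for rep in sorted(arrested_reps):
        for status, cond in ROLE_MEMBERS:
            if (status, cond, rep) not in seen:
                raise ConfigError(
                    f"arrest contrast for replicate {rep!r} is missing the "
                    f"({status}, {cond}) member"
                )
        ploidies = {
            s.role.arrest_ploidy
            for s in config.samples
            if s.replicate_id == rep and s.role.condition == "arrested_37C"
        }
        if len(ploidies) != 1 or "none" in ploidies:
            raise ConfigError(
                f"arrested replicate {rep!r} must declare one arrest_ploidy (1n or 2n), "
                f"got {sorted(ploidies)}"
            )


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), ndigits)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def _mean_sd(values: list[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size >= 2 else None,
        "n": int(arr.size),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict and writes outputs.

    Any stage failure raises :class:`PipelineStageError` naming the stage and
    sample; whatever report sections were completed are written first.
    """
    _validate(config)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = config.options
    report: dict = {"samples": {}, "rho_contrasts": {}, "arrest": {}, "scaling": {}, "cv": {}}

    tables: dict = {}
    peaks: dict = {}

    def stage(name, sample_id, fn):
        try:
            result = fn()
        except Exception as exc:
            _write_report(report, out_dir)
            raise PipelineStageError(name, sample_id, exc) from exc
        return result

    # --- per-sample: read, transform, density, modes --------------------
    for entry in config.samples:
        sid = entry.sample_id
        table = stage("read_events", sid, lambda e=entry: read_events(
            e.path, channel_map=e.channel_map, format=e.format, sample_id=sid
        ))
        table = stage("log2_transform", sid, lambda t=table: log2_transform(t))
        profile = stage("estimate_density", sid, lambda t=table: density.estimate_density(
            t.events["fluor_log2"].to_numpy(), bandwidth=opts.bandwidth
        ))
        expected = entry.role.arrest_ploidy if entry.role.arrest_ploidy != "none" else "2n"
        pk = stage("find_peak_modes", sid, lambda p=profile, e=expected: density.find_peak_modes(
            p, min_prominence=opts.min_prominence, expected_arrest_ploidy=e
        ))
        key = (entry.role.mito_status, entry.role.condition, entry.replicate_id)
        tables[key] = (entry, table)
        peaks[key] = pk
        logger.info(
            "stage=modes sample=%s n_events=%d dropped=%d mode_1n=%s mode_2n=%s",
            sid, table.n_events, table.dropped_count, pk.mode_1n, pk.mode_2n,
        )
        report["samples"][sid] = {
            "path": entry.path,
            "role": asdict(entry.role),
            "replicate_id": entry.replicate_id,
            "n_events": table.n_events,
            "dropped_count": table.dropped_count,
            "peaks": {
                "mode_1n": pk.mode_1n,
                "mode_2n": pk.mode_2n,
                "bandwidth": pk.bandwidth,
                "n_modes_found": pk.n_modes_found,
                "spacing_ok": pk.spacing_ok,
            },
        }

    replicates = sorted({s.replicate_id for s in config.samples})

    # --- rho contrasts -> absolute copies (per condition) ----------------
    baseline_2n_by_rep: dict[str, float] = {}
    for condition in ("control_25C", "arrested_37C"):
        per_ploidy: dict[str, list] = {"1n": [], "2n": []}
        for rep in replicates:
            kp = ("rho_plus", condition, rep)
            kz = ("rho_zero", condition, rep)
            if kp not in peaks or kz not in peaks:
                continue
            for ploidy in ("1n", "2n"):
                mp = peaks[kp].mode_1n if ploidy == "1n" else peaks[kp].mode_2n
                mz = peaks[kz].mode_1n if ploidy == "1n" else peaks[kz].mode_2n
                if mp is None or mz is None:
                    continue
                shift = ModeShift(delta=mp - mz, ploidy=ploidy, kind="rho_contrast")
                est = copies_from_rho_contrast(shift, config.genome)
                per_ploidy[ploidy].append((rep, shift, est))
                if condition == "control_25C" and ploidy == "2n":
                    baseline_2n_by_rep[rep] = est.copies
        section = {}
        for ploidy, items in per_ploidy.items():
            if not items:
                continue
            agg = aggregate_replicates([est for _, _, est in items])
            section[ploidy] = {
                "per_replicate": [
                    {"replicate_id": rep, "delta": sh.delta, "copies": est.copies}
                    for rep, sh, est in items
                ],
                "copies_mean": agg.copies,
                "copies_sd": agg.copies_sd,
            }
        if section:
            report["rho_contrasts"][condition] = section

    # --- arrest contrasts -> surplus + fold ------------------------------
    arrest_rows = []
    for rep in replicates:
        keys = {
            status: {cond: (status, cond, rep) for cond in ("control_25C", "arrested_37C")}
            for status in ("rho_plus", "rho_zero")
        }
        needed = [keys["rho_plus"]["control_25C"], keys["rho_plus"]["arrested_37C"],
                  keys["rho_zero"]["control_25C"], keys["rho_zero"]["arrested_37C"]]
        if not all(k in peaks for k in needed):
            continue
        entry_arr = tables[keys["rho_plus"]["arrested_37C"]][0]
        ploidy = entry_arr.role.arrest_ploidy
        if ploidy == "none":
            continue
        try:
            dp = peaks[keys["rho_plus"]["arrested_37C"]].mode(ploidy) - \
                peaks[keys["rho_plus"]["control_25C"]].mode(ploidy)
            dz = peaks[keys["rho_zero"]["arrested_37C"]].mode(ploidy) - \
                peaks[keys["rho_zero"]["control_25C"]].mode(ploidy)
        except CytomitoError as exc:
            _write_report(report, out_dir)
            raise PipelineStageError("arrest_contrast", rep, exc) from exc
        if rep not in baseline_2n_by_rep:
            continue
        baseline = baseline_for_ploidy(baseline_2n_by_rep[rep], ploidy)
        res = arrest_surplus(
            ModeShift(dp, ploidy, "arrest_contrast"),
            ModeShift(dz, ploidy, "arrest_contrast"),
            baseline,
            config.genome,
            formula=opts.surplus_formula,
        )
        arrest_rows.append((rep, res))
    if arrest_rows:
        report["arrest"] = {
            "per_replicate": [
                {
                    "replicate_id": rep,
                    "ploidy": r.ploidy,
                    "delta_rho_plus": r.delta_rho_plus,
                    "delta_rho_zero": r.delta_rho_zero,
                    "baseline_copies": r.baseline_copies,
                    "surplus_copies": r.surplus_copies,
                    "fold_change": r.fold_change,
                }
                for rep, r in arrest_rows
            ],
            "surplus": _mean_sd([r.surplus_copies for _, r in arrest_rows]),
            "fold": _mean_sd([r.fold_change for _, r in arrest_rows]),
            "formula": opts.surplus_formula,
        }

    # --- size scaling within the arrest-ploidy gate ----------------------
    for (status, condition, rep), (entry, table) in tables.items():
        ploidy = entry.role.arrest_ploidy
        if ploidy == "none":
            continue
        sid = entry.sample_id
        def _fit(t=table, k=(status, condition, rep), p=ploidy):
            gated = scaling.gate_ploidy(t, peaks[k], p, opts.ploidy_gate_halfwidth)
            return scaling.fit_size_scaling(gated, gate=p, min_events=opts.min_fit_events)
        fit = stage("fit_size_scaling", sid, _fit)
        report["scaling"].setdefault(condition, {}).setdefault(rep, {})[status] = asdict(fit)
    for condition, reps in report["scaling"].items():
        for rep, fits in reps.items():
            if "rho_plus" in fits and "rho_zero" in fits:
                comp = scaling.compare_scaling(
                    scaling.SizeScalingFit(**fits["rho_plus"]),
                    scaling.SizeScalingFit(**fits["rho_zero"]),
                )
                fits["comparison"] = asdict(comp)

    # --- binned CV on the right flank of the 2n peak ---------------------
    for rep in replicates:
        kp_ctl = ("rho_plus", "control_25C", rep)
        kp_arr = ("rho_plus", "arrested_37C", rep)
        if kp_ctl not in tables or kp_arr not in tables:
            continue
        if tables[kp_arr][0].role.arrest_ploidy != "2n":
            continue
        sid = tables[kp_arr][0].sample_id
        def _profiles():
            g_ctl = density.gate_right_of_2n(tables[kp_ctl][1], peaks[kp_ctl], opts.gate_width)
            g_arr = density.gate_right_of_2n(tables[kp_arr][1], peaks[kp_arr], opts.gate_width)
            anchor = float(
                min(
                    g_ctl.events["fsc_log2"].min(),
                    g_arr.events["fsc_log2"].min(),
                )
            )
            p_ctl = cv_mod.compute_binned_cv(g_ctl, opts.bin_width, opts.min_events, anchor)
            p_arr = cv_mod.compute_binned_cv(g_arr, opts.bin_width, opts.min_events, anchor)
            return p_ctl, p_arr
        p_ctl, p_arr = stage("compute_binned_cv", sid, _profiles)
        entry = {"control": _profile_dict(p_ctl), "arrested": _profile_dict(p_arr)}
        try:
            comp = cv_mod.compare_cv_profiles(p_arr, p_ctl)
            entry["comparison"] = {
                "shared_centers": comp.shared_centers,
                "cv_difference": comp.cv_difference,
                "slope_arrested": comp.slope_arrested,
                "slope_control": comp.slope_control,
                "arrested_cv_flat_or_decreasing": comp.arrested_cv_flat_or_decreasing,
            }
        except CytomitoError:
            entry["comparison"] = None
        report["cv"][rep] = entry
        _profile_csv(p_arr, out_dir / f"cv_profile_arrested_{rep}.csv")
        _profile_csv(p_ctl, out_dir / f"cv_profile_control_{rep}.csv")

    # CV aggregation over replicates: mean per-bin difference sign summary
    if report["cv"]:
        diffs = [
            float(np.mean(e["comparison"]["cv_difference"]))
            for e in report["cv"].values()
            if e.get("comparison")
        ]
        if diffs:
            report["cv"]["aggregate"] = {"mean_cv_difference": _mean_sd(diffs)}

    _write_report(report, out_dir)
    return report


def _profile_dict(profile) -> dict:
    return {
        "population_cv": profile.population_cv,
        "bin_width": profile.bin_width,
        "min_events": profile.min_events,
        "bins": [asdict(b) for b in profile.bins],
    }


def _profile_csv(profile, path) -> None:
    pd.DataFrame(
        [
            {
                "bin_low": b.fsc_log2_low,
                "bin_high": b.fsc_log2_high,
                "n": b.n_events,
                "cv": b.cv,
                "included": b.included,
            }
            for b in profile.bins
        ]
    ).to_csv(path, index=False, float_format="%.6g")


def _write_report(report: dict, out_dir: Path) -> None:
    payload = _round_floats(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
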