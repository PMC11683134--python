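"""Event-table I/O: read flow-cytometry events (FCS or CSV), filter, log2-transform.

The central container is :class:`EventTable`, a thin wrapper around a pandas
DataFrame with one row per cytometer event. Two channels are consumed: a
DNA-stain fluorescence area channel (default ``FITC-A``, the Sytox Green
channel) and forward-scatter area (``FSC-A``, a semi-quantitative cell-size
proxy). Optional ground-truth columns (``truth_ploidy_class``,
``truth_mtdna_copies``, ``truth_cell_size``) carry simulator labels.

Non-positive instrument values are dropped, not clamped: the downstream
analysis lives on a log2 axis and clamping would create an artificial
density spike at the clamp value.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _fcs
from .errors import ChannelNotFoundError, CytomitoError, FormatError

DEFAULT_FLUOR_CHANNEL = "FITC-A"
DEFAULT_FSC_CHANNEL = "FSC-A"

TRUTH_COLUMNS = ("truth_ploidy_class", "truth_mtdna_copies", "truth_cell_size")

MITO_STATUSES = ("rho_plus", "rho_zero")
CONDITIONS = ("control_25C", "arrested_37C")
ARREST_PLOIDIES = ("1n", "2n", "none")


@dataclass(frozen=True)
class SampleRole:
    """Experimental role of one sample.

    ``mito_status`` distinguishes cells with mtDNA (rho+) from mtDNA-free
    rho0 cells; ``condition`` distinguishes the 25 degC proliferating control
    from the 37 degC arrested culture. ``arrest_ploidy`` names the DNA-content
    peak at which a cdc mutant arrests (1n for G1 arrest, 2n for G2/M arrest);
    it is ``"none"`` exactly for non-arresting (wild-type style) controls.
    """

    mito_status: str
    condition: str = "control_25C"
    arrest_ploidy: str = "none"

    def __post_init__(self) -> None:
        if self.mito_status not in MITO_STATUSES:
            raise CytomitoError(f"mito_status must be one of {MITO_STATUSES}")
        if self.condition not in CONDITIONS:
            raise CytomitoError(f"condition must be one of {CONDITIONS}")
        if self.arrest_ploidy not in ARREST_PLOIDIES:
            raise CytomitoError(f"arrest_ploidy must be one of {ARREST_PLOIDIES}")


@dataclass
class EventTable:
    """Per-cell measurements for one stained sample.

    Attributes
    ----------
    sample_id:
        Free-text sample identifier.
    events:
        DataFrame with columns ``fluor_linear`` and ``fsc_linear`` (arbitrary
        linear instrument units, strictly positive), plus ``fluor_log2`` /
        ``fsc_log2`` after :func:`log2_transform` and optional truth columns.
    channel_map:
        Mapping with keys ``fluor_channel_name`` and ``fsc_channel_name``.
    dropped_count:
        Number of events removed because a consumed channel was <= 0 or
        non-finite.
    """

    sample_id: str
    events: pd.DataFrame
    channel_map: dict = field(
        default_factory=lambda: {
            "fluor_channel_name": DEFAULT_FLUOR_CHANNEL,
            "fsc_channel_name": DEFAULT_FSC_CHANNEL,
        }
    )
    dropped_count: int = 0

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def is_transformed(self) -> bool:
        return "fluor_log2" in self.events.columns

    def __post_init__(self) -> None:
        missing = {"fluor_linear", "fsc_linear"} - set(self.events.columns)
        if missing:
            raise CytomitoError(f"EventTable missing columns {sorted(missing)}")


def _filter_positive(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    vals = df[["fluor_linear", "fsc_linear"]].to_numpy(dtype=float)
    keep = np.isfinite(vals).all(axis=1) & (vals > 0).all(axis=1)
    dropped = int((~keep).sum())
    return df.loc[keep].reset_index(drop=True), dropped


def read_events(
    path,
    channel_map: dict | None = None,
    format: str | None = None,
    sample_id: str | None = None,
) -> EventTable:
    """Read events from an FCS or CSV file.

    ``format`` is ``"fcs"`` or ``"csv"``; when omitted it is inferred from
    the file suffix. The named channels must exist in the file header;
    otherwise a :class:`ChannelNotFoundError` lists the available channels.
    Events with non-positive fluorescence or FSC are dropped and counted.
    """
    path = str(path)
    cm = {
        "fluor_channel_name": DEFAULT_FLUOR_CHANNEL,
        "fsc_channel_name": DEFAULT_FSC_CHANNEL,
    }
    if channel_map:
        cm.update(channel_map)
    if format is None:
        format = "fcs" if path.lower().endswith(".fcs") else "csv"
    if format not in ("fcs", "csv"):
        raise FormatError(f"unknown format {format!r}")

    if format == "fcs":
        names, matrix, _ = _fcs.read_fcs(path)
        cols = {}
        for key in ("fluor_channel_name", "fsc_channel_name"):
            if cm[key] not in names:
                raise ChannelNotFoundError(cm[key], names)
            cols[key] = matrix[:, names.index(cm[key])]
        df = pd.DataFrame(
            {"fluor_linear": cols["fluor_channel_name"], "fsc_linear": cols["fsc_channel_name"]}
        )
    else:
        try:
            raw = pd.read_csv(path)
        except Exception as exc:  # pandas raises several parse error types
            raise FormatError(f"{path}: could not parse CSV ({exc})") from exc
        for key in ("fluor_channel_name", "fsc_channel_name"):
            if cm[key] not in raw.columns:
                raise ChannelNotFoundError(cm[key], list(raw.columns))
        df = pd.DataFrame(
            {
                "fluor_linear": raw[cm["fluor_channel_name"]].astype(float),
                "fsc_linear": raw[cm["fsc_channel_name"]].astype(float),
            }
        )
        for col in TRUTH_COLUMNS:
            if col in raw.columns:
                df[col] = raw[col].to_numpy()

    df, dropped = _filter_positive(df)
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return EventTable(sample_id=sample_id, events=df, channel_map=cm, dropped_count=dropped)


def write_events_csv(table: EventTable, path) -> None:
    """Write an event table as CSV using the raw channel names as headers.

    Truth columns, if present, are written alongside so that a read/write
    round trip is the identity.
    """
    out = pd.DataFrame(
        {
            table.channel_map["fluor_channel_name"]: table.events["fluor_linear"],
            table.channel_map["fsc_channel_name"]: table.events["fsc_linear"],
        }
    )
    for col in TRUTH_COLUMNS:
        if col in table.events.columns:
            out[col] = table.events[col]
    out.to_csv(path, index=False)


def write_events_fcs(table: EventTable, path) -> None:
    """Write the two consumed channels as a minimal FCS 3.0 file."""
    _fcs.write_fcs(
        path,
        [table.channel_map["fluor_channel_name"], table.channel_map["fsc_channel_name"]],
        table.events[["fluor_linear", "fsc_linear"]].to_numpy(),
    )


def write_processed_csv(table: EventTable, path) -> None:
    """Write a transformed table as CSV with sample_id, fluor_log2, fsc_log2."""
    if not table.is_transformed:
        raise CytomitoError("table must be log2-transformed first")
    pd.DataFrame(
        {
            "sample_id": table.sample_id,
            "fluor_log2": table.events["fluor_log2"],
            "fsc_log2": table.events["fsc_log2"],
        }
    ).to_csv(path, index=False)


def log2_transform(table: EventTable) -> EventTable:
    """Return a new table with ``fluor_log2`` and ``fsc_log2`` columns added.

    Linear columns are retained (the binned-CV statistic is computed on the
    linear scale); event order is preserved, so the transform is rank- and
    index-stable. Non-positive values violate the precondition — they must
    have been filtered by :func:`read_events` or the generator.
    """
    vals = table.events[["fluor_linear", "fsc_linear"]].to_numpy(dtype=float)
    if not (np.isfinite(vals).all() and (vals > 0).all()):
        raise CytomitoError("log2_transform requires strictly positive finite values")
    df = table.events.copy()
    df["fluor_log2"] = np.log2(df["fluor_linear"].to_numpy(dtype=float))
    df["fsc_log2"] = np.log2(df["fsc_linear"].to_numpy(dtype=float))
    return replace(table, events=df)
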