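"""Post-unmixing localisation filters and per-trace centroids.

After two-colour separation, localisations are filtered by effective
photon-emission frequency (efo < 80 kHz, strict) and traces by their number
of surviving localisations (> 3, strict); the centroid of each remaining
trace is then the unweighted arithmetic mean of its surviving event
positions.  Events of a colour-called trace contribute to its length count
and centroid regardless of their own event label: the trace's colour is
already decided by the majority vote.

Every input event is accounted for in exactly one disposition —
``kept``, ``efo_dropped``, ``short_trace_dropped`` or
``unmixing_excluded`` — and the counts are carried in a
:class:`FilterReport` whose conservation identity is checked on
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .unmixing import COLOUR_A, COLOUR_B

__all__ = [
    "FilterReport",
    "filter_events_by_efo",
    "filter_traces_by_length",
    "trace_centroids",
    "process_traces",
]

EFO_MAX_KHZ = 80.0
MIN_LOCS_EXCLUSIVE = 3


@dataclass(frozen=True)
class FilterReport:
    """Event bookkeeping across the filter chain; kept + dropped = input."""

    n_input_events: int
    n_unmixing_excluded: int
    n_efo_dropped: int
    n_short_trace_dropped: int
    n_kept: int
    n_traces_out: int

    def __post_init__(self) -> None:
        total = (
            self.n_unmixing_excluded
            + self.n_efo_dropped
            + self.n_short_trace_dropped
            + self.n_kept
        )
        if total != self.n_input_events:
            raise ValueError(
                f"event conservation violated: {total} != {self.n_input_events}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def filter_events_by_efo(
    events: pd.DataFrame, efo_max: float = EFO_MAX_KHZ
) -> pd.DataFrame:
    """Keep exactly the events with efo strictly below ``efo_max`` (kHz)."""
    return events[events["efo_khz"] < efo_max].reset_index(drop=True)


def filter_traces_by_length(
    events: pd.DataFrame, min_locs_exclusive: int = MIN_LOCS_EXCLUSIVE
) -> pd.DataFrame:
    """Keep events of traces with strictly more than ``min_locs_exclusive``
    surviving events.  Apply after event-level filtering: the counts refer
    to events that survived it."""
    if events.empty:
        return events.reset_index(drop=True)
    n = events.groupby("trace_id")["event_index"].transform("count")
    return events[n > min_locs_exclusive].reset_index(drop=True)


def trace_centroids(events: pd.DataFrame, photon_weighted: bool = False) -> pd.DataFrame:
    """Per-trace centroid of surviving event positions.

    Returns columns ``trace_id, x_nm, y_nm, n_events, colour``.  The
    centroid is the unweighted arithmetic mean by default; with
    ``photon_weighted=True`` events are weighted by their pooled photon
    count (``total_ech``).
    """
    if events.empty:
        return pd.DataFrame(columns=["trace_id", "x_nm", "y_nm", "n_events", "colour"])
    if photon_weighted:
        w = events["total_ech"].to_numpy(dtype=float)
        tmp = events.assign(wx=events["x_nm"] * w, wy=events["y_nm"] * w, w=w)
        agg = tmp.groupby("trace_id", as_index=False).agg(
            wx=("wx", "sum"), wy=("wy", "sum"), w=("w", "sum"),
            n_events=("event_index", "count"), colour=("trace_label", "first"),
        )
        agg["x_nm"] = agg["wx"] / agg["w"]
        agg["y_nm"] = agg["wy"] / agg["w"]
        return agg[["trace_id", "x_nm", "y_nm", "n_events", "colour"]]
    agg = events.groupby("trace_id", as_index=False).agg(
        x_nm=("x_nm", "mean"),
        y_nm=("y_nm", "mean"),
        n_events=("event_index", "count"),
        colour=("trace_label", "first"),
    )
    return agg[["trace_id", "x_nm", "y_nm", "n_events", "colour"]]


def process_traces(
    events: pd.DataFrame,
    efo_max: float = EFO_MAX_KHZ,
    min_locs_exclusive: int = MIN_LOCS_EXCLUSIVE,
    photon_weighted: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter chain: drop unmixing-excluded traces, apply the efo and
    trace-length filters, and compute centroids.

    ``events`` is the per-event frame produced by
    :func:`mfxduet.unmixing.unmix_table` (must carry ``trace_label``).
    """
    n_input = len(events)
    coloured = events[events["trace_label"].isin([COLOUR_A, COLOUR_B])]
    n_excluded = n_input - len(coloured)

    after_efo = filter_events_by_efo(coloured, efo_max)
    n_efo_dropped = len(coloured) - len(after_efo)

    kept = filter_traces_by_length(after_efo, min_locs_exclusive)
    n_short_dropped = len(after_efo) - len(kept)

    centroids = trace_centroids(kept, photon_weighted=photon_weighted)
    report = FilterReport(
        n_input_events=n_input,
        n_unmixing_excluded=n_excluded,
        n_efo_dropped=n_efo_dropped,
        n_short_trace_dropped=n_short_dropped,
        n_kept=len(kept),
        n_traces_out=len(centroids),
    )
    return centroids, report
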