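"""Localisation data model and tabular I/O.

MINFLUX localisation data are represented as a flat table with one row per
(event, iteration): each blink event of a molecule trace carries a final
position in nm, an effective photon-emission frequency (efo, kHz) and a
short series of per-iteration detection-channel-ratio (DCR) readings with
their effective photon counts (ech).  The on-disk form is the "MFX-CSV"
dialect: comma-separated UTF-8 with header columns

    trace_id, event_index, iter_index, x_nm, y_nm, efo_khz, dcr, ech

where x/y/efo are repeated identically on every iteration row of one event.
Coordinates are continuous 2-D nm values with arbitrary origin; there is no
pixel grid and z is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IterationReading",
    "LocalisationEvent",
    "LocalisationTable",
    "ROI",
    "FormatError",
    "ValidationError",
    "read_localisations",
    "write_localisations",
    "clip_to_roi",
]

#: Mandatory columns of the MFX-CSV dialect, in canonical order.
MFX_CSV_COLUMNS = (
    "trace_id",
    "event_index",
    "iter_index",
    "x_nm",
    "y_nm",
    "efo_khz",
    "dcr",
    "ech",
)


class FormatError(ValueError):
    """The file does not conform to the declared dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A row violates a data-model invariant (reported with its line number)."""


@dataclass(frozen=True)
class IterationReading:
    """One HeadStart-iteration channel readout of a localisation event.

    Parameters
    ----------
    iter_index
        0-based position of the iteration within the event.
    dcr
        Detection channel ratio, the fraction of photons detected in the
        far spectral window; dimensionless, in [0, 1].
    ech
        Effective photon count at the MINFLUX pattern offset for this
        iteration; non-negative integer.  Used as the weight when DCR
        readings are pooled.
    """

    iter_index: int
    dcr: float
    ech: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.dcr <= 1.0:
            raise ValidationError(f"dcr must be in [0, 1], got {self.dcr}")
        if self.ech < 0:
            raise ValidationError(f"ech must be non-negative, got {self.ech}")


@dataclass(frozen=True)
class LocalisationEvent:
    """A single blink event: final position, efo and its iteration readings."""

    trace_id: str
    event_index: int
    x: float
    y: float
    efo: float
    iterations: tuple[IterationReading, ...]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"non-finite coordinates ({self.x}, {self.y}) "
                f"for trace {self.trace_id!r} event {self.event_index}"
            )
        if not math.isfinite(self.efo) or self.efo <= 0:
            raise ValidationError(
                f"efo must be finite and > 0, got {self.efo} "
                f"for trace {self.trace_id!r} event {self.event_index}"
            )
        if len(self.iterations) < 1:
            raise ValidationError(
                f"event {self.trace_id!r}/{self.event_index} has no iterations"
            )


@dataclass
class LocalisationTable:
    """A set of localisation events plus free-form metadata.

    Internally the events are held as a pandas DataFrame with one row per
    (event, iteration) in MFX-CSV column order, sorted by trace then event
    then iteration.  ``events()`` yields structured per-event views.
    """

    frame: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MFX_CSV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        self.frame = (
            self.frame.loc[:, list(MFX_CSV_COLUMNS)]
            .astype(
                {
                    "trace_id": str,
                    "event_index": np.int64,
                    "iter_index": np.int64,
                    "x_nm": float,
                    "y_nm": float,
                    "efo_khz": float,
                    "ech": np.int64,
                    "dcr": float,
                }
            )
            .sort_values(["trace_id", "event_index", "iter_index"], kind="stable")
            .reset_index(drop=True)
        )

    # -- accessors -----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        if self.frame.empty:
            return 0
        return self.frame.groupby(["trace_id", "event_index"], sort=False).ngroups

    @property
    def n_traces(self) -> int:
        return self.frame["trace_id"].nunique()

    def events(self) -> Iterator[LocalisationEvent]:
        """Yield events ordered by trace then event index."""
        for (tid, eidx), grp in self.frame.groupby(
            ["trace_id", "event_index"], sort=True
        ):
            first = grp.iloc[0]
            yield LocalisationEvent(
                trace_id=str(tid),
                event_index=int(eidx),
                x=float(first.x_nm),
                y=float(first.y_nm),
                efo=float(first.efo_khz),
                iterations=tuple(
                    IterationReading(int(r.iter_index), float(r.dcr), int(r.ech))
                    for r in grp.itertuples()
                ),
            )

    @classmethod
    def from_events(
        cls, events: Sequence[LocalisationEvent], metadata: dict | None = None
    ) -> "LocalisationTable":
        rows = [
            (e.trace_id, e.event_index, it.iter_index, e.x, e.y, e.efo, it.dcr, it.ech)
            for e in events
            for it in e.iterations
        ]
        frame = pd.DataFrame(rows, columns=list(MFX_CSV_COLUMNS))
        return cls(frame, dict(metadata or {}))

    def validate(self) -> None:
        """Check all data-model invariants; raise ValidationError on the first breach."""
        _validate_frame(self.frame)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest, closed on all bounds (nm)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate ROI: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised closed-interval membership test."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


def clip_to_roi(points: np.ndarray, roi: ROI) -> np.ndarray:
    """Return the subset of ``points`` (n, 2) inside ``roi``, order preserved.

    Bounds are closed: points exactly on the ROI boundary are kept.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    mask = roi.contains(pts[:, 0], pts[:, 1])
    return pts[mask]


# -- reading / writing ------------------------------------------------


def _validate_frame(frame: pd.DataFrame, line_offset: int = 0) -> None:
    """Raise ValidationError naming the first offending CSV line.

    ``line_offset`` maps a frame row to its 1-based file line (header = 1),
    so errors cite the line a user can open; 0 means the frame is in-memory.
    """

    def _line(row_pos: int) -> str:
        if line_offset:
            return f" (line {row_pos + line_offset})"
        return f" (row {row_pos})"

    checks = [
        (~frame["dcr"].between(0.0, 1.0), "dcr outside [0, 1]"),
        (frame["ech"] < 0, "negative ech"),
        (~np.isfinite(frame["x_nm"]) | ~np.isfinite(frame["y_nm"]),
         "non-finite coordinate"),
        (~np.isfinite(frame["efo_khz"]) | (frame["efo_khz"] <= 0),
         "efo must be finite and > 0"),
    ]
    for bad, message in checks:
        if bad.any():
            pos = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"{message}{_line(pos)}")

    dup = frame.duplicated(["trace_id", "event_index", "iter_index"])
    if dup.any():
        pos = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(f"duplicate (trace_id, event_index, iter_index){_line(pos)}")

    # x/y/efo must repeat identically across the iteration rows of one event
    grp = frame.groupby(["trace_id", "event_index"], sort=False)
    for col in ("x_nm", "y_nm", "efo_khz"):
        if (grp[col].nunique() > 1).any():
            raise ValidationError(f"{col} varies within a single event")


def read_localisations(
    path: str | Path,
    dialect: str = "mfx-csv",
    efo_unit: str = "khz",
    metadata_path: str | Path | None = None,
) -> LocalisationTable:
    """Read an MFX-CSV localisation file.

    Parameters
    ----------
    path
        CSV file with the mandatory MFX-CSV header.
    dialect
        Only ``"mfx-csv"`` is supported.
    efo_unit
        ``"khz"`` (native) or ``"hz"``; Hz input is converted to kHz on read.
    metadata_path
        Optional sidecar ``key: value`` text file (FOV extent, channel names).
    """
    if dialect != "mfx-csv":
        raise FormatError(f"unknown dialect {dialect!r}")
    if efo_unit not in ("khz", "hz"):
        raise FormatError(f"efo_unit must be 'khz' or 'hz', got {efo_unit!r}")

    frame = pd.read_csv(path)
    missing = [c for c in MFX_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    if not frame.empty:
        if efo_unit == "hz":
            frame["efo_khz"] = frame["efo_khz"] / 1000.0
        # header is line 1, first data row is line 2
        _validate_frame(frame, line_offset=2)

    metadata: dict[str, str] = {}
    if metadata_path is not None:
        for raw in Path(metadata_path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, value = raw.partition(":")
            metadata[key.strip()] = value.strip()

    return LocalisationTable(frame, metadata)


def write_localisations(
    table: LocalisationTable,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write ``table`` as MFX-CSV; round-trips exactly through read_localisations."""
    table.validate()
    out = table.frame.copy()
    # default (shortest round-trippable) float repr: read(write(t)) == t exactly
    out.to_csv(path, index=False)
    if metadata_path is not None and table.metadata:
        Path(metadata_path).write_text(
            "".join(f"{k}: {v}\n" for k, v in table.metadata.items())
        )
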