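"""Synthetic two-colour MINFLUX localisation generator with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, without simulating the acquisition physics itself:

* two dye populations with distinct true far-channel probabilities
  (detection channel ratio, DCR), observed through binomial photon
  partitioning so that low-photon readings are noisier;
* per-molecule blinking traces of variable length, each event localised
  with Gaussian precision ``loc_sigma`` about the molecule position;
* molecules grouped into spatial clusters, and clusters arranged as
  inter-colour pairs at a configurable true centre separation — the
  quantity the nearest-neighbour pipeline estimates;
* background traces scattered uniformly over the field of view and a
  small fraction of traces with intermediate DCR, populating the
  'not defined' colour category;
* per-event emission frequencies (efo, kHz) drawn log-normally so that a
  controlled tail straddles the 80 kHz filter threshold.

Every trace is recorded in a :class:`SimulationTruth` table so that colour
calling, filtering, clustering and distance estimation can all be scored
against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .io import MFX_CSV_COLUMNS, ROI, LocalisationTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "truth_nn_distance",
    "read_truth",
    "write_truth",
]

TRUTH_COLUMNS = (
    "trace_id",
    "true_colour",
    "molecule_id",
    "cluster_id",
    "pair_id",
    "true_x_nm",
    "true_y_nm",
    "cluster_x_nm",
    "cluster_y_nm",
    "pair_separation_nm",
)


# -- samplers ---------------------------------------------------------
#
# Scalar config fields double as distribution means; a dict spec selects a
# different law.  Keeping the spec YAML-serialisable keeps configs auditable.


def _draw_separation(spec: Any, rng: np.random.Generator, n: int) -> np.ndarray:
    """Pair-separation sampler: scalar -> constant; {'dist': 'uniform', low, high}."""
    if isinstance(spec, dict):
        if spec.get("dist") == "uniform":
            return rng.uniform(spec["low"], spec["high"], size=n)
        if spec.get("dist") == "fixed":
            return np.full(n, float(spec["value"]))
        raise ValueError(f"unknown pair_separation spec {spec!r}")
    return np.full(n, float(spec))


def _draw_counts(
    spec: Any, rng: np.random.Generator, n: int, *, shifted: bool
) -> np.ndarray:
    """Count sampler for molecules per cluster / localisations per trace.

    Scalar ``m`` means Poisson with mean ``m`` truncated to >= 1
    (``shifted=False``) or the shifted law 1 + Poisson(m - 1)
    (``shifted=True``, used for trace lengths).  ``{'dist': 'fixed',
    'value': k}`` pins the count exactly.
    """
    if isinstance(spec, dict):
        if spec.get("dist") == "fixed":
            return np.full(n, int(spec["value"]), dtype=np.int64)
        if spec.get("dist") == "poisson":
            spec = float(spec["mean"])
        else:
            raise ValueError(f"unknown count spec {spec!r}")
    mean = float(spec)
    if shifted:
        return 1 + rng.poisson(max(mean - 1.0, 0.0), size=n)
    return np.maximum(rng.poisson(mean, size=n), 1)


def _lognormal(
    rng: np.random.Generator, median: np.ndarray, gsd: np.ndarray, n: int
) -> np.ndarray:
    """Log-normal draw parameterised by median and geometric SD."""
    return median * np.exp(np.log(gsd) * rng.standard_normal(n))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic acquisition.

    Defaults reflect the experimental configuration the pipeline targets:
    a final-iteration minimum photon threshold of 150 photons per reading,
    a localisation precision of a few nm, dye DCR centres well separated in
    [0, 1], and an efo distribution with roughly 10% of events above the
    80 kHz filter threshold.
    """

    seed: int = 0
    fov: ROI = field(default_factory=lambda: ROI(0.0, 0.0, 20_000.0, 20_000.0))
    n_pairs: int = 50
    #: true centre-to-centre distance of each inter-colour cluster pair (nm)
    pair_separation: Any = 28.0
    #: SD of molecule positions about their cluster centre (nm)
    cluster_sigma: float = 15.0
    #: mean molecules per cluster (Poisson, truncated >= 1) or fixed spec
    molecules_per_cluster: Any = 15
    #: localisations per trace; scalar m -> 1 + Poisson(m - 1)
    locs_per_trace: Any = 7
    #: per-event localisation precision (nm)
    loc_sigma: float = 3.0
    #: iteration readings per event
    n_iterations: int = 4
    #: mean effective photon count per iteration reading
    photons_per_iteration: float = 150.0
    #: true far-channel probabilities of the two dyes
    dcr_mean_a: float = 0.30
    dcr_mean_b: float = 0.65
    #: efo law per dye: (median kHz, geometric SD); ~10% of events > 80 kHz
    efo_lognormal_a: tuple[float, float] = (40.0, 1.717)
    efo_lognormal_b: tuple[float, float] = (40.0, 1.717)
    #: efo law of background traces, mostly above the 80 kHz threshold
    efo_lognormal_background: tuple[float, float] = (95.0, 1.6)
    #: fraction of all traces placed uniformly in the FOV as background
    background_trace_fraction: float = 0.05
    #: fraction of all traces with intermediate DCR ('not defined' fodder)
    undefined_dye_fraction: float = 0.02
    max_placement_retries: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.dcr_mean_a < self.dcr_mean_b < 1.0:
            raise ValueError("require 0 < dcr_mean_a < dcr_mean_b < 1")
        if self.n_pairs < 0 or self.n_iterations < 1:
            raise ValueError("counts must be non-negative (n_iterations >= 1)")
        if not isinstance(self.pair_separation, dict) and self.pair_separation <= 0:
            raise ValueError("pair_separation must be > 0")
        frac = self.background_trace_fraction + self.undefined_dye_fraction
        if not 0.0 <= frac < 1.0:
            raise ValueError("background + undefined fractions must be in [0, 1)")

    # -- (de)serialisation for YAML configs ---------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["fov"] = [self.fov.x_min, self.fov.y_min, self.fov.x_max, self.fov.y_max]
        for key in ("efo_lognormal_a", "efo_lognormal_b", "efo_lognormal_background"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "fov" in d and not isinstance(d["fov"], ROI):
            d["fov"] = ROI(*map(float, d["fov"]))
        for key in ("efo_lognormal_a", "efo_lognormal_b", "efo_lognormal_background"):
            if key in d:
                d[key] = tuple(map(float, d[key]))
        return cls(**d)


@dataclass
class SimulationTruth:
    """Per-trace ground truth: dye colour, molecule position, cluster and pair.

    ``frame`` has one row per trace (columns :data:`TRUTH_COLUMNS`);
    background and intermediate traces carry ``cluster_id = pair_id = -1``
    and NaN pair separation.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"truth table missing column(s): {', '.join(missing)}")
        if self.frame["trace_id"].duplicated().any():
            raise ValueError("truth table has duplicate trace_id")

    def colour_of(self) -> pd.Series:
        """trace_id -> true_colour mapping."""
        return self.frame.set_index("trace_id")["true_colour"]


def truth_nn_distance(truth: SimulationTruth) -> np.ndarray:
    """True centre separation of every cluster pair, ordered by pair id.

    This is the quantity the pipeline's cross-colour nearest-neighbour
    analysis estimates, used as the oracle in recovery tests.
    """
    paired = truth.frame[truth.frame["pair_id"] >= 0]
    if paired.empty:
        return np.empty(0)
    per_pair = paired.groupby("pair_id")["pair_separation_nm"].first().sort_index()
    return per_pair.to_numpy()


def simulate(config: SimulationConfig) -> tuple[LocalisationTable, SimulationTruth]:
    """Generate a localisation table and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    fov = config.fov

    # --- cluster-pair geometry ---------------------------------------
    separations = _draw_separation(config.pair_separation, rng, config.n_pairs)
    centres_a = np.empty((config.n_pairs, 2))
    centres_b = np.empty((config.n_pairs, 2))
    for i in range(config.n_pairs):
        for attempt in range(config.max_placement_retries + 1):
            ax = rng.uniform(fov.x_min, fov.x_max)
            ay = rng.uniform(fov.y_min, fov.y_max)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            bx = ax + separations[i] * math.cos(theta)
            by = ay + separations[i] * math.sin(theta)
            if fov.contains(bx, by):
                centres_a[i] = (ax, ay)
                centres_b[i] = (bx, by)
                break
        else:
            raise RuntimeError(
                f"could not place pair {i} inside the FOV after "
                f"{config.max_placement_retries} retries"
            )

    # --- per-trace (= per-molecule) records --------------------------
    trace_rows: list[tuple] = []  # colour, p_true, mol_x, mol_y, mol, clu, pair, sep
    mol_counter = 0
    for i in range(config.n_pairs):
        for colour, centre, cluster_id in (
            ("A", centres_a[i], 2 * i),
            ("B", centres_b[i], 2 * i + 1),
        ):
            n_mol = int(_draw_counts(config.molecules_per_cluster, rng, 1,
                                     shifted=False)[0])
            offsets = rng.normal(0.0, config.cluster_sigma, size=(n_mol, 2))
            p = config.dcr_mean_a if colour == "A" else config.dcr_mean_b
            for k in range(n_mol):
                trace_rows.append(
                    (colour, p, centre[0] + offsets[k, 0], centre[1] + offsets[k, 1],
                     mol_counter, cluster_id, i, separations[i], centre[0], centre[1])
                )
                mol_counter += 1

    n_signal = len(trace_rows)
    f_bg = config.background_trace_fraction
    f_und = config.undefined_dye_fraction
    n_total_target = n_signal / (1.0 - f_bg - f_und) if n_signal else 0.0
    n_bg = int(round(n_total_target * f_bg))
    n_und = int(round(n_total_target * f_und))

    p_intermediate = 0.5 * (config.dcr_mean_a + config.dcr_mean_b)
    for _ in range(n_bg):
        x = rng.uniform(fov.x_min, fov.x_max)
        y = rng.uniform(fov.y_min, fov.y_max)
        p = rng.uniform(0.05, 0.95)  # background has no single dye identity
        trace_rows.append(("background", p, x, y, mol_counter, -1, -1,
                           float("nan"), float("nan"), float("nan")))
        mol_counter += 1
    for _ in range(n_und):
        x = rng.uniform(fov.x_min, fov.x_max)
        y = rng.uniform(fov.y_min, fov.y_max)
        trace_rows.append(("intermediate", p_intermediate, x, y, mol_counter, -1, -1,
                           float("nan"), float("nan"), float("nan")))
        mol_counter += 1

    n_traces = len(trace_rows)
    if n_traces == 0:
        empty = pd.DataFrame(columns=list(MFX_CSV_COLUMNS))
        truth = pd.DataFrame(columns=list(TRUTH_COLUMNS))
        return (
            LocalisationTable(empty, _fov_metadata(config)),
            SimulationTruth(truth),
        )

    colours = np.array([r[0] for r in trace_rows])
    p_true = np.array([r[1] for r in trace_rows])
    mol_xy = np.array([(r[2], r[3]) for r in trace_rows])
    trace_ids = np.array([f"T{idx:06d}" for idx in range(n_traces)])

    # --- events -------------------------------------------------------
    n_locs = _draw_counts(config.locs_per_trace, rng, n_traces, shifted=True)
    trace_rep = np.repeat(np.arange(n_traces), n_locs)
    n_events = len(trace_rep)
    event_index = np.concatenate([np.arange(k) for k in n_locs])
    ev_xy = mol_xy[trace_rep] + rng.normal(0.0, config.loc_sigma, size=(n_events, 2))

    efo_params = {
        "A": config.efo_lognormal_a,
        "B": config.efo_lognormal_b,
        "background": config.efo_lognormal_background,
        "intermediate": config.efo_lognormal_a,
    }
    ev_colour = colours[trace_rep]
    median = np.array([efo_params[c][0] for c in ev_colour])
    gsd = np.array([efo_params[c][1] for c in ev_colour])
    efo = _lognormal(rng, median, gsd, n_events)

    # --- iteration readings: binomial photon partitioning -------------
    n_iter = config.n_iterations
    ev_rep = np.repeat(np.arange(n_events), n_iter)
    iter_index = np.tile(np.arange(n_iter), n_events)
    ech = rng.poisson(config.photons_per_iteration, size=len(ev_rep))
    far = rng.binomial(ech, p_true[trace_rep][ev_rep])
    dcr = np.where(ech > 0, far / np.maximum(ech, 1), 0.0)

    frame = pd.DataFrame(
        {
            "trace_id": trace_ids[trace_rep][ev_rep],
            "event_index": event_index[ev_rep],
            "iter_index": iter_index,
            "x_nm": ev_xy[ev_rep, 0],
            "y_nm": ev_xy[ev_rep, 1],
            "efo_khz": efo[ev_rep],
            "dcr": dcr,
            "ech": ech,
        }
    )

    truth_frame = pd.DataFrame(
        {
            "trace_id": trace_ids,
            "true_colour": colours,
            "molecule_id": [r[4] for r in trace_rows],
            "cluster_id": [r[5] for r in trace_rows],
            "pair_id": [r[6] for r in trace_rows],
            "true_x_nm": mol_xy[:, 0],
            "true_y_nm": mol_xy[:, 1],
            "cluster_x_nm": [r[8] for r in trace_rows],
            "cluster_y_nm": [r[9] for r in trace_rows],
            "pair_separation_nm": [r[7] for r in trace_rows],
        }
    )

    return (
        LocalisationTable(frame, _fov_metadata(config)),
        SimulationTruth(truth_frame),
    )


def _fov_metadata(config: SimulationConfig) -> dict[str, str]:
    fov = config.fov
    return {
        "fov_nm": f"{fov.x_min},{fov.y_min},{fov.x_max},{fov.y_max}",
        "channels": "A,B",
        "seed": str(config.seed),
    }


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    truth.frame.loc[:, list(TRUTH_COLUMNS)].to_csv(path, index=False)


def read_truth(path: str | Path) -> SimulationTruth:
    return SimulationTruth(pd.read_csv(path, dtype={"trace_id": str}))
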