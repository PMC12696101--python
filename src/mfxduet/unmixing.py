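"""Two-colour spectral unmixing from detection channel ratios.

Each localisation event carries several iteration readings of the detection
channel ratio (DCR), each with an effective photon count (ech).  Colour
assignment proceeds in four steps:

1. pool the selected iterations' DCR values into one value per event,
   weighted by ech — photon weighting downweights background-dominated,
   low-photon readings;
2. fit a two-component univariate Gaussian mixture to the pooled values by
   expectation–maximisation;
3. assign each event to a colour when its posterior for one component
   exceeds 0.95 (strictly), otherwise mark it ``not_defined``;
4. assign each trace the modal event colour; traces whose mode is
   ``not_defined``, or tied, are ``excluded`` from two-colour analysis.

The component with the lower DCR mean is reported as colour ``A`` and the
higher as colour ``B`` (the red-shifted dye); mapping to user-facing dye
names belongs in configuration, not here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .io import LocalisationEvent, LocalisationTable

__all__ = [
    "COLOUR_A",
    "COLOUR_B",
    "NOT_DEFINED",
    "EXCLUDED",
    "PooledDCR",
    "ColourModel",
    "DegenerateFitError",
    "pooled_dcr",
    "pooled_dcr_table",
    "fit_dcr_mixture",
    "localisation_posteriors",
    "assign_event_colour",
    "assign_trace_colour",
    "unmix_table",
]

logger = logging.getLogger(__name__)

COLOUR_A = "A"
COLOUR_B = "B"
NOT_DEFINED = "not_defined"
EXCLUDED = "excluded"

#: lower bound on component SDs (DCR units); prevents component collapse
SIGMA_FLOOR = 1e-3


class DegenerateFitError(RuntimeError):
    """Mixture fit collapsed; the sample may be single-population."""


@dataclass(frozen=True)
class PooledDCR:
    """Photon-weighted mean DCR of one event over the selected iterations."""

    trace_id: str
    event_index: int
    value: float
    total_ech: int


@dataclass(frozen=True)
class ColourModel:
    """Fitted two-component univariate Gaussian mixture over pooled DCR.

    Components are ordered by mean (``means[0] < means[1]``); component 0
    maps to colour A, component 1 to colour B.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    converged: bool
    log_likelihood: float
    n_points: int
    n_iter: int
    log_likelihood_history: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not self.means[0] < self.means[1]:
            raise ValueError("components must be ordered by mean")
        if min(self.sds) <= 0:
            raise ValueError("component SDs must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["log_likelihood_history"] = list(self.log_likelihood_history)
        for key in ("weights", "means", "sds"):
            d[key] = list(d[key])
        return d


# -- iteration selection ----------------------------------------------


def _selected_mask(iter_index: np.ndarray, selector, n_iters_per_event) -> np.ndarray:
    """Boolean mask over iteration rows for the pooling selector.

    ``selector`` is ``"all"`` (default), ``"headstart"`` (every iteration
    but the final one of each event) or an explicit iterable of iteration
    indices.
    """
    if selector == "all" or selector is None:
        return np.ones(len(iter_index), dtype=bool)
    if selector == "headstart":
        return iter_index < np.asarray(n_iters_per_event) - 1
    indices = set(int(i) for i in selector)
    return np.isin(iter_index, list(indices))


def pooled_dcr(event: LocalisationEvent, selector="all") -> PooledDCR:
    """Photon-weighted mean DCR of one event: sum(dcr*ech) / sum(ech).

    Iterations with ``ech = 0`` carry zero weight and contribute nothing.
    Raises ``ValueError`` if no selected iteration has photons; callers
    pooling whole tables drop such events with a warning instead.
    """
    idx = np.array([it.iter_index for it in event.iterations])
    dcr = np.array([it.dcr for it in event.iterations])
    ech = np.array([it.ech for it in event.iterations], dtype=float)
    mask = _selected_mask(idx, selector, len(event.iterations))
    if not mask.any():
        raise ValueError("selector excludes every iteration of the event")
    total = ech[mask].sum()
    if total == 0:
        raise ValueError(
            f"event {event.trace_id!r}/{event.event_index}: all selected "
            "iterations have zero photons"
        )
    value = float((dcr[mask] * ech[mask]).sum() / total)
    return PooledDCR(event.trace_id, event.event_index, value, int(total))


def pooled_dcr_table(table: LocalisationTable, selector="all") -> pd.DataFrame:
    """Pool DCR per event over a whole table (vectorised).

    Returns one row per event with columns ``trace_id, event_index, x_nm,
    y_nm, efo_khz, pooled_dcr, total_ech``.  Events whose selected
    iterations carry zero photons in total are dropped with a warning.
    """
    f = table.frame
    if f.empty:
        return pd.DataFrame(
            columns=["trace_id", "event_index", "x_nm", "y_nm", "efo_khz",
                     "pooled_dcr", "total_ech"]
        )
    n_per_event = f.groupby(["trace_id", "event_index"])["iter_index"].transform(
        "count"
    )
    mask = _selected_mask(f["iter_index"].to_numpy(), selector, n_per_event.to_numpy())
    sel = f[mask].copy()
    sel["wdcr"] = sel["dcr"] * sel["ech"]
    agg = (
        sel.groupby(["trace_id", "event_index"], as_index=False)
        .agg(
            x_nm=("x_nm", "first"),
            y_nm=("y_nm", "first"),
            efo_khz=("efo_khz", "first"),
            wdcr=("wdcr", "sum"),
            total_ech=("ech", "sum"),
        )
    )
    zero = agg["total_ech"] == 0
    if zero.any():
        logger.warning(
            "dropping %d event(s) with zero total photons in selected iterations",
            int(zero.sum()),
        )
        agg = agg[~zero]
    agg["pooled_dcr"] = agg["wdcr"] / agg["total_ech"]
    return agg.drop(columns="wdcr").reset_index(drop=True)


# -- Gaussian mixture fit ---------------------------------------------


def fit_dcr_mixture(
    values: Sequence[float] | np.ndarray,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    sigma_floor: float = SIGMA_FLOOR,
) -> ColourModel:
    """Fit a two-component 1-D Gaussian mixture to pooled DCR values by EM.

    Initialisation is deterministic: means at the 25th/75th percentiles,
    equal weights, pooled SD for both components; ``seed`` is accepted for
    interface stability but no randomised restart is needed.  The
    log-likelihood is checked to be non-decreasing at every EM step.

    Raises
    ------
    DegenerateFitError
        If a component captures fewer than two points or both components
        collapse onto the same location — the sample may be
        single-population.
    """
    del seed  # deterministic initialisation; kept for interface stability
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need at least 4 pooled DCR values (2 per component)")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("pooled DCR values must lie in [0, 1]")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    sigma = np.full(2, max(float(np.std(x)), sigma_floor))
    pi = np.array([0.5, 0.5])

    ll_history: list[float] = []
    converged = False
    log_resp = None
    for _ in range(max_iter):
        log_resp, ll = _e_step(x, pi, mu, sigma)
        if ll_history and ll < ll_history[-1] - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_history[-1]} -> {ll}"
            )
        if ll_history and abs(ll - ll_history[-1]) < tol:
            ll_history.append(ll)
            converged = True
            break
        ll_history.append(ll)
        pi, mu, sigma = _m_step(x, log_resp, sigma_floor)

    order = np.argsort(mu)
    pi, mu, sigma = pi[order], mu[order], sigma[order]

    n_eff = pi * len(x)
    if n_eff.min() < 2.0 or abs(mu[1] - mu[0]) <= sigma_floor:
        raise DegenerateFitError(
            "mixture fit degenerate (component captured < 2 points or the "
            "components coincide); the sample may be single-population"
        )

    return ColourModel(
        weights=(float(pi[0]), float(pi[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sigma[0]), float(sigma[1])),
        converged=converged,
        log_likelihood=float(ll_history[-1]),
        n_points=len(x),
        n_iter=len(ll_history),
        log_likelihood_history=tuple(ll_history),
    )


def _component_logpdf(x: np.ndarray, pi, mu, sigma) -> np.ndarray:
    """(n, 2) array of log(pi_k * phi(x; mu_k, sigma_k)); -inf for pi_k = 0."""
    out = np.full((len(x), 2), -np.inf)
    for k in range(2):
        if pi[k] > 0:
            out[:, k] = np.log(pi[k]) + norm.logpdf(x, mu[k], sigma[k])
    return out


def _e_step(x, pi, mu, sigma):
    log_joint = _component_logpdf(x, pi, mu, sigma)
    log_norm = logsumexp(log_joint, axis=1)
    return log_joint - log_norm[:, None], float(log_norm.sum())


def _m_step(x, log_resp, sigma_floor):
    resp = np.exp(log_resp)
    nk = resp.sum(axis=0)
    pi = nk / nk.sum()
    mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
    var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(nk, 1e-300)
    sigma = np.maximum(np.sqrt(var), sigma_floor)
    return pi, mu, sigma


# -- posteriors and labels --------------------------------------------


def localisation_posteriors(
    model: ColourModel, values: float | np.ndarray
) -> np.ndarray:
    """Posterior component memberships for pooled DCR value(s).

    Returns an (n, 2) array of (posterior_A, posterior_B) rows summing to 1;
    computed in log space so well-separated values do not underflow.
    """
    x = np.atleast_1d(np.asarray(values, dtype=float))
    log_joint = _component_logpdf(x, model.weights, model.means, model.sds)
    log_post = log_joint - logsumexp(log_joint, axis=1)[:, None]
    return np.exp(log_post)


def assign_event_colour(
    posteriors: Sequence[float] | np.ndarray, threshold: float = 0.95
) -> str:
    """Label one event: A or B when that posterior strictly exceeds the
    threshold, otherwise ``not_defined``."""
    p1, p2 = float(posteriors[0]), float(posteriors[1])
    if abs(p1 + p2 - 1.0) > 1e-9:
        raise ValueError("posteriors must sum to 1")
    if p1 > threshold:
        return COLOUR_A
    if p2 > threshold:
        return COLOUR_B
    return NOT_DEFINED


def assign_trace_colour(event_labels: Iterable[str]) -> str:
    """Majority vote over a trace's event labels.

    The trace takes the modal category; if the mode is ``not_defined`` or
    the top categories tie, the trace is ``excluded`` from two-colour data.
    Invariant under permutation of the labels.
    """
    counts = Counter(event_labels)
    if not counts:
        raise ValueError("trace has no event labels")
    top = counts.most_common()
    best_label, best_n = top[0]
    tied = [lab for lab, n in top if n == best_n]
    if len(tied) > 1 or best_label == NOT_DEFINED:
        return EXCLUDED
    return best_label


def unmix_table(
    table: LocalisationTable,
    selector="all",
    threshold: float = 0.95,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ColourModel]:
    """Run the full unmixing chain on a localisation table.

    Returns the per-event frame (one row per event, with ``pooled_dcr``,
    ``posterior_b``, ``event_label`` and the trace-level ``trace_label``
    broadcast onto every event) and the fitted :class:`ColourModel`.
    """
    events = pooled_dcr_table(table, selector)
    model = fit_dcr_mixture(events["pooled_dcr"].to_numpy(), seed=seed)
    post = localisation_posteriors(model, events["pooled_dcr"].to_numpy())
    events = events.copy()
    events["posterior_b"] = post[:, 1]
    labels = np.full(len(events), NOT_DEFINED, dtype=object)
    labels[post[:, 0] > threshold] = COLOUR_A
    labels[post[:, 1] > threshold] = COLOUR_B
    events["event_label"] = labels
    trace_label = (
        events.groupby("trace_id")["event_label"]
        .agg(assign_trace_colour)
        .rename("trace_label")
    )
    events = events.merge(trace_label, on="trace_id", how="left")
    return events, model
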