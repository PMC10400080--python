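"""Edge time series (cofluctuation) and their relation to state dynamics.

The cofluctuation of two parcels at TR t is |z_i(t)·z_j(t)|, the absolute
element-wise product of their z-scored signals — a time-resolved,
unsigned edge weight.  Averaging over all P(P−1)/2 edges gives a global
cofluctuation (synchrony) time course; averaging the edge series within
a window around decoded state-transition onsets shows how synchrony
behaves as the brain switches states (empirically: a transient dip just
before the switch).  Edges are grouped into cortico-cortical,
cortico-subcortical, and subcortico-subcortical categories from the
parcel category tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hmm_core import StateSequence
from .null_stats import NullDistribution, null_band, permutation_pvalue
from .timeseries_io import ParcelTimeSeries

__all__ = [
    "EdgeTimeSeries",
    "AlignedCofluctuation",
    "edge_timeseries",
    "covariance_strength",
    "global_cofluctuation",
    "cofluctuation_by_state",
    "align_to_transitions",
    "transition_onsets",
    "aligned_transition_null",
]

EDGE_CATEGORIES = ("cortico-cortical", "cortico-subcortical", "subcortico-subcortical")


@dataclass
class EdgeTimeSeries:
    """E×T nonnegative cofluctuation values for all parcel pairs (i < j)."""

    values: np.ndarray  # E×T, |z_i·z_j|
    edge_index: list[tuple[int, int]]
    edge_category: list[str] | None = None

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class AlignedCofluctuation:
    """Transition-aligned mean cofluctuation, overall and per edge category."""

    offsets: np.ndarray  # window offsets relative to the new state's onset
    grand_mean: np.ndarray  # mean over edges and transitions, per offset
    per_category: dict[str, np.ndarray]  # category → per-offset means
    n_transitions: int


def _edge_pairs(P: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(P) for j in range(i + 1, P)]


def _categorize(pairs, categories) -> list[str]:
    out = []
    for i, j in pairs:
        sub = (categories[i] == "subcortical") + (categories[j] == "subcortical")
        out.append(EDGE_CATEGORIES[sub])
    return out


def edge_timeseries(ts: ParcelTimeSeries, tol: float = 1e-6) -> EdgeTimeSeries:
    """Cofluctuation |z_i·z_j| for every parcel pair of a z-normalized run.

    Edge ordering is (i, j) with i < j, row-major.  The input must already
    be within-run z-normalized (column means below ``tol``); otherwise the
    products would mix scale with coupling.
    """
    z = ts.values
    if np.any(np.abs(z.mean(axis=0)) > tol):
        raise ValueError(
            "input is not z-normalized; apply timeseries_io.znormalize first"
        )
    pairs = _edge_pairs(ts.n_parcels)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    values = np.abs(z[:, i_idx] * z[:, j_idx]).T  # E×T
    cats = _categorize(pairs, ts.parcel_categories) if ts.parcel_categories else None
    return EdgeTimeSeries(values, pairs, cats)


def covariance_strength(covariances: np.ndarray) -> np.ndarray:
    """Per-state sum of |cov_ij| over the off-diagonal pairs (i < j), once each.

    High values mean strongly coupled parcels within the state; the "base"
    state is characterized by a low value.
    """
    covs = np.asarray(covariances, dtype=float)
    if covs.ndim == 2:
        covs = covs[None]
    K, P, _ = covs.shape
    iu = np.triu_indices(P, k=1)
    return np.array([np.sum(np.abs(covs[k][iu])) for k in range(K)])


def global_cofluctuation(edges: EdgeTimeSeries) -> np.ndarray:
    """Per-TR mean cofluctuation over all edges (a global synchrony index)."""
    return edges.values.mean(axis=0)


def cofluctuation_by_state(global_cf: np.ndarray, seq: StateSequence) -> np.ndarray:
    """Mean global cofluctuation per occupied state (NaN for absent states)."""
    global_cf = np.asarray(global_cf, dtype=float).ravel()
    if global_cf.size != seq.T:
        raise ValueError("cofluctuation and state sequence lengths differ")
    out = np.full(seq.K, np.nan)
    for k in range(seq.K):
        mask = seq.labels == k
        if mask.any():
            out[k] = global_cf[mask].mean()
    return out


def transition_onsets(seq: StateSequence) -> list[np.ndarray]:
    """Per-run indices t (run-local) where the state differs from t−1."""
    return [np.flatnonzero(np.diff(run) != 0) + 1 for run in seq.runs()]


def _windows(series_T: int, onsets: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Onsets whose full window [t+lo, t+hi] lies inside a run of length series_T."""
    return onsets[(onsets + lo >= 0) & (onsets + hi < series_T)]


def align_to_transitions(
    edges: EdgeTimeSeries | np.ndarray,
    seq: StateSequence,
    window: tuple[int, int] = (-3, 3),
    onsets_per_run: list[np.ndarray] | None = None,
) -> AlignedCofluctuation:
    """Average cofluctuation in a window around state-transition onsets.

    A transition's onset is the first TR of the new state; the default
    window spans −3..+3 TRs about that onset.  Windows clipped by a run
    edge are dropped.  Accepts either an :class:`EdgeTimeSeries` (giving
    per-category traces too) or a plain T-vector such as the global
    cofluctuation.
    """
    lo, hi = window
    if lo > 0 or hi < 0 or lo > hi:
        raise ValueError("window must bracket the onset (lo ≤ 0 ≤ hi)")
    if isinstance(edges, EdgeTimeSeries):
        values = edges.values  # E×T
        categories = edges.edge_category
    else:
        values = np.asarray(edges, dtype=float).reshape(1, -1)
        categories = None
    if values.shape[1] != seq.T:
        raise ValueError("edge series and state sequence lengths differ")

    if onsets_per_run is None:
        onsets_per_run = transition_onsets(seq)
    offsets = np.arange(lo, hi + 1)
    sums = np.zeros((values.shape[0], offsets.size))
    n_kept = 0
    stops = list(seq.run_boundary_index[1:]) + [seq.T]
    for (start, stop), onsets in zip(
        zip(seq.run_boundary_index, stops), onsets_per_run
    ):
        run_len = stop - start
        for t in _windows(run_len, np.asarray(onsets, dtype=int), lo, hi):
            sums += values[:, start + t + lo : start + t + hi + 1]
            n_kept += 1
    if n_kept == 0:
        warnings.warn("no usable transitions in the window; empty result")
        per_edge = np.full_like(sums, np.nan)
    else:
        per_edge = sums / n_kept

    grand = per_edge.mean(axis=0)
    per_cat: dict[str, np.ndarray] = {}
    if categories is not None:
        cats = np.asarray(categories)
        for c in EDGE_CATEGORIES:
            mask = cats == c
            if mask.any():
                per_cat[c] = per_edge[mask].mean(axis=0)
    return AlignedCofluctuation(offsets, grand, per_cat, n_kept)


def aligned_transition_null(
    edges: EdgeTimeSeries | np.ndarray,
    seq: StateSequence,
    window: tuple[int, int] = (-3, 3),
    n_iter: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null for the aligned trace: shuffle transition-onset times within run.

    Each iterate draws, per run, as many fake onsets (uniform, without
    replacement) as the real decoded transitions, and recomputes the
    aligned grand mean.  Returns (per-offset p-values, band lo, band hi),
    the band being mean ± 1.96 sd of the null at each offset.
    """
    rng = np.random.default_rng(seed)
    observed = align_to_transitions(edges, seq, window)
    real_onsets = transition_onsets(seq)
    stops = list(seq.run_boundary_index[1:]) + [seq.T]
    run_lens = [b - a for a, b in zip(seq.run_boundary_index, stops)]
    null_traces = np.empty((n_iter, observed.offsets.size))
    for it in range(n_iter):
        fake = [
            rng.choice(np.arange(1, n), size=min(len(o), n - 1), replace=False)
            for o, n in zip(real_onsets, run_lens)
        ]
        null_traces[it] = align_to_transitions(edges, seq, window, fake).grand_mean
    pvals = np.array(
        [
            permutation_pvalue(
                observed.grand_mean[i], NullDistribution(null_traces[:, i])
            )
            for i in range(observed.offsets.size)
        ]
    )
    bands = np.array(
        [null_band(NullDistribution(null_traces[:, i])) for i in range(observed.offsets.size)]
    )
    return pvals, bands[:, 0], bands[:, 1]
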