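"""Ground-truth-known synthetic datasets with the structure the pipeline assumes.

Generates multi-subject, multi-run parcel time series from a K-state
Gaussian HMM with full state covariances, state-coupled behavioral
(attention) traces passed through the hemodynamic response kernel, and
interleaved ABAB narrative event structures.  Everything is reproducible
from (seed, parameters), and the writers emit exactly the TSV/JSON formats
of :mod:`~brainstates.timeseries_io`, so the synthetic path exercises the
real readers.

These simulations emulate the statistical skeleton of naturalistic fMRI —
state-conditional mean/covariance structure, Markov switching, stimulus
locking across subjects — not its nuisance structure: there is no scanner
drift, no motion, and no within-state temporal autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hmm_core import HMMParameters, StateSequence
from .timeseries_io import (
    BehavioralTrace,
    EventBoundaries,
    ManifestEntry,
    ParcelTimeSeries,
    RunManifest,
    hrf_convolve,
    save_manifest,
    save_parcel_timeseries,
)

__all__ = [
    "GroundTruth",
    "GroupDataset",
    "sample_hmm_params",
    "simulate_run",
    "simulate_group",
    "simulate_event_structure",
    "simulate_attention_trace",
    "write_group",
]

COV_RIDGE = 0.1  # ridge keeping random full covariances positive-definite


@dataclass
class GroundTruth:
    """Generating parameters and true state sequences of a synthetic group."""

    params: HMMParameters
    state_sequences: list[StateSequence]
    behavior_effects: np.ndarray | None
    seed: int


@dataclass
class GroupDataset:
    """In-memory synthetic group: runs, manifest, and its ground truth."""

    runs: list[ParcelTimeSeries]
    manifest: RunManifest
    truth: GroundTruth


def sample_hmm_params(
    K: int,
    P: int,
    mean_separation: float = 2.0,
    self_prob: float = 0.9,
    cov_style: str = "random_full",
    seed: int | None = None,
) -> HMMParameters:
    """Draw generating HMM parameters with controllable decoding difficulty.

    State means sit on a sphere of radius mean_separation·sqrt(P)/2 about
    the origin, arranged as a randomly oriented regular simplex (K ≤ P+1)
    so that *every* pairwise mean distance equals
    mean_separation·sqrt(P/2)·sqrt(K/(K−1)) — one knob really does control
    decoding difficulty, with no lucky/unlucky draws of near-coincident
    states.  (For K > P+1, where no simplex fits, directions are drawn at
    random instead.)  The transition matrix
    has diagonal ``self_prob`` and uniform off-diagonal mass; the initial
    distribution is uniform.  Covariances are either identity ("diagonal")
    or random symmetric positive-definite A·Aᵀ/P + 0.1·I ("random_full"),
    giving each state its own coupling structure.
    """
    if K < 1 or P < 2:
        raise ValueError("need K ≥ 1 and P ≥ 2")
    if not (0 < self_prob < 1) and K > 1:
        raise ValueError("self_prob must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    if K == 1:
        means = np.zeros((1, P))
        trans = np.array([[1.0]])
    else:
        if K <= P + 1:
            # regular simplex with unit circumradius, randomly rotated into R^P
            simplex = np.eye(K) - 1.0 / K
            simplex /= np.linalg.norm(simplex, axis=1, keepdims=True)
            u, s, _ = np.linalg.svd(simplex, full_matrices=False)
            coords = u[:, : K - 1] * s[: K - 1]  # K×(K−1), geometry preserved
            basis, _ = np.linalg.qr(rng.standard_normal((P, K - 1)))
            directions = coords @ basis.T
        else:
            directions = rng.standard_normal((K, P))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        means = directions * (mean_separation * np.sqrt(P) / 2.0)
        trans = np.full((K, K), (1.0 - self_prob) / (K - 1))
        np.fill_diagonal(trans, self_prob)

    covs = np.empty((K, P, P))
    for k in range(K):
        if cov_style == "diagonal":
            covs[k] = np.eye(P)
        elif cov_style == "random_full":
            A = rng.standard_normal((P, P))
            covs[k] = A @ A.T / P + COV_RIDGE * np.eye(P)
        else:
            raise ValueError(f"unknown cov_style: {cov_style!r}")
        if np.linalg.eigvalsh(covs[k])[0] <= 0:  # ridge guarantees this; belt and braces
            raise RuntimeError("covariance construction not positive definite")

    params = HMMParameters(means, covs, trans, np.full(K, 1.0 / K))
    params.validate()
    return params


def sample_hub_hmm_params(
    P: int = 25,
    mean_separation: float = 2.0,
    base_self_prob: float = 0.5,
    other_self_prob: float = 0.9,
    p_to_base: float = 0.08,
    base_variance: float = 0.3,
    seed: int | None = None,
) -> HMMParameters:
    """Four-state model with a desynchronized "base" hub state (state 3).

    Emulates the architecture reported for naturalistic fMRI: three
    functionally specialized states with distinct mean activity patterns
    and distinct full covariances, plus a base state with near-baseline
    (zero) mean and weak, decoupled covariance (``base_variance``·I) that
    acts as a transition hub — specialized states exit mostly into the
    base state (``p_to_base`` vs. 0.01 to each other specialized state),
    and the base state dwells briefly (``base_self_prob``) before feeding
    the next specialized state.  Because the hub is the least synchronized
    state and most transitions pass through it, global cofluctuation dips
    just before transition onsets, the signature this model is built to
    exhibit.
    """
    rng = np.random.default_rng(seed)
    K = 4
    means = np.zeros((K, P))
    dirs = rng.standard_normal((3, P))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    means[:3] = dirs * (mean_separation * np.sqrt(P) / 2.0)
    covs = np.empty((K, P, P))
    for k in range(3):
        A = rng.standard_normal((P, P))
        covs[k] = A @ A.T / P + COV_RIDGE * np.eye(P)
    covs[3] = base_variance * np.eye(P)
    trans = np.zeros((K, K))
    for k in range(3):
        trans[k, k] = other_self_prob
        trans[k, 3] = p_to_base
        for j in range(3):
            if j != k:
                trans[k, j] = (1.0 - other_self_prob - p_to_base) / 2.0
    trans[3, 3] = base_self_prob
    trans[3, :3] = (1.0 - base_self_prob) / 3.0
    params = HMMParameters(means, covs, trans, np.full(K, 0.25))
    params.validate()
    return params


def _sample_states(
    params: HMMParameters,
    T: int,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> np.ndarray:
    labels = np.empty(T, dtype=int)
    labels[0] = (
        initial_state
        if initial_state is not None
        else rng.choice(params.K, p=params.initial)
    )
    # inverse-CDF sampling against the per-state transition CDFs
    cdf = np.cumsum(params.transition, axis=1)
    u = rng.random(T)
    for t in range(1, T):
        labels[t] = np.searchsorted(cdf[labels[t - 1]], u[t])
    return labels


def simulate_run(
    params: HMMParameters,
    T: int,
    seed: int | None = None,
    subject_id: str = "sub-01",
    run_id: str = "run-01",
    tr: float = 1.0,
    initial_state: int | None = None,
    states: np.ndarray | None = None,
    n_subcortical: int = 0,
) -> tuple[ParcelTimeSeries, StateSequence]:
    """Simulate one run: Markov state path + state-conditional Gaussian draws."""
    if T < 2:
        raise ValueError("T must be ≥ 2")
    rng = np.random.default_rng(seed)
    labels = (
        np.asarray(states, dtype=int)
        if states is not None
        else _sample_states(params, T, rng, initial_state)
    )
    P = params.P
    values = np.empty((T, P))
    chol = [np.linalg.cholesky(params.covariances[k]) for k in range(params.K)]
    noise = rng.standard_normal((T, P))
    for k in range(params.K):
        mask = labels == k
        values[mask] = params.means[k] + noise[mask] @ chol[k].T
    n_cortical = P - n_subcortical
    categories = ["cortical"] * n_cortical + ["subcortical"] * n_subcortical
    ts = ParcelTimeSeries(
        values=values,
        tr=tr,
        subject_id=subject_id,
        run_id=run_id,
        parcel_labels=[f"parcel{i:02d}" for i in range(P)],
        parcel_categories=categories,
    )
    return ts, StateSequence(labels, K=params.K)


def simulate_group(
    params: HMMParameters,
    n_subjects: int,
    runs_per_subject: int = 1,
    T: int = 600,
    seed: int | None = None,
    shared_sequence: bool = False,
    tr: float = 1.0,
    n_subcortical: int = 0,
) -> GroupDataset:
    """Simulate a group of subjects from shared generating parameters.

    With ``shared_sequence`` every subject follows the *same* state path per
    run (emulating stimulus-driven synchrony during movie watching), while
    observation noise stays independent; otherwise each subject-run draws
    its own path.
    """
    if n_subjects < 1 or runs_per_subject < 1:
        raise ValueError("counts must be ≥ 1")
    rng = np.random.default_rng(seed)
    shared_paths = (
        [_sample_states(params, T, rng) for _ in range(runs_per_subject)]
        if shared_sequence
        else None
    )
    runs: list[ParcelTimeSeries] = []
    seqs: list[StateSequence] = []
    entries: list[ManifestEntry] = []
    for s in range(n_subjects):
        for r in range(runs_per_subject):
            sid, rid = f"sub-{s + 1:02d}", f"run-{r + 1:02d}"
            ts, seq = simulate_run(
                params,
                T,
                seed=int(rng.integers(2**31 - 1)),
                subject_id=sid,
                run_id=rid,
                tr=tr,
                states=shared_paths[r] if shared_paths is not None else None,
                n_subcortical=n_subcortical,
            )
            runs.append(ts)
            seqs.append(seq)
            entries.append(ManifestEntry(sid, rid, f"{sid}_{rid}.tsv"))
    truth = GroundTruth(params, seqs, None, seed if seed is not None else -1)
    return GroupDataset(runs, RunManifest(entries), truth)


def write_group(dataset: GroupDataset, outdir) -> Path:
    """Write all runs + manifest in the package's TSV/JSON formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for run, entry in zip(dataset.runs, dataset.manifest.entries):
        save_parcel_timeseries(run, outdir / entry.path)
    return save_manifest(dataset.manifest, outdir / "manifest.tsv")


def simulate_event_structure(
    n_events: int,
    min_len: int,
    max_len: int,
    pattern: str = "ABAB",
    seed: int | None = None,
    total_T: int | None = None,
) -> EventBoundaries:
    """Interleaved narrative events: ``n_events`` with alternating A/B labels.

    Event lengths are drawn uniform-integer in [min_len, max_len]; the
    n_events − 1 boundaries are the cumulative onsets of events 2..n.
    """
    if n_events < 2:
        raise ValueError("need at least two events")
    if min_len > max_len or min_len < 1:
        raise ValueError("need 1 ≤ min_len ≤ max_len")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_len, max_len + 1, size=n_events)
    if total_T is not None and lengths.sum() > total_T:
        raise ValueError(
            f"events total {lengths.sum()} TRs but the run has only {total_T}"
        )
    if pattern == "ABAB":
        labels = ["A" if i % 2 == 0 else "B" for i in range(n_events)]
    else:
        labels = [pattern] * n_events
    boundaries = np.cumsum(lengths)[:-1]
    return EventBoundaries(boundary_trs=boundaries, story_labels=labels)


def simulate_attention_trace(
    true_states: StateSequence,
    effects,
    noise_sd: float = 0.5,
    tr: float = 1.0,
    seed: int | None = None,
    convolve: bool = True,
    kind: str = "engagement",
) -> BehavioralTrace:
    """State-coupled behavioral trace: effects[state_t] + noise, HRF, z-norm.

    ``effects`` gives each state's mean attention level; the raw trace is
    optionally convolved with the canonical HRF (matching how behavior is
    related to BOLD-locked state sequences) and z-normalized.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size != true_states.K:
        raise ValueError("need one effect per state")
    rng = np.random.default_rng(seed)
    raw = effects[true_states.labels] + noise_sd * rng.standard_normal(true_states.T)
    trace = BehavioralTrace(raw, tr=tr, kind=kind)
    if convolve:
        trace = hrf_convolve(trace)
    sd = trace.values.std(ddof=1)
    if sd == 0:
        raise ValueError("attention trace is constant; cannot z-normalize")
    z = (trace.values - trace.values.mean()) / sd
    return BehavioralTrace(z, tr=tr, kind=kind, hrf_convolved=trace.hrf_convolved)
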