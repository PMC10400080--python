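"""State dynamics at narrative event boundaries and their link to attention.

Three families of analysis, each with a circular-shift null:

* boundary-aligned occurrence — the probability of each state at offsets
  −2..+20 TR around narrative event boundaries, against boundaries
  circular-shifted within run;
* boundary-conditioned transitions — which state a designated target
  state (e.g. the DMN state) is entered *from*, split by whether the
  transition falls in a post-boundary window (default 5–15 TR at 1 s TR,
  scaled by round(5 s/tr)..round(15 s/tr) otherwise);
* attention by state — the mean of a per-TR attention proxy (inverted RT
  variability or engagement ratings, HRF-convolved and z-scored) during
  each state's occupancy, against circular-shifted traces.

Paired contrasts across subjects use an exact/Monte-Carlo sign-permutation
test of the subject-level differences; multiple comparisons are handled
with BH-FDR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .hmm_core import StateSequence
from .null_stats import NullDistribution, circular_shift, fdr_bh, null_band, permutation_pvalue
from .state_metrics import fractional_occupancy
from .timeseries_io import BehavioralTrace, EventBoundaries

__all__ = [
    "AlignedOccurrence",
    "boundary_aligned_occurrence",
    "group_aligned_occurrence",
    "boundary_occurrence_null",
    "boundary_transition_classification",
    "attention_by_state",
    "attention_by_state_group",
    "blockwise_occupancy",
    "sign_permutation_test",
    "boundary_window_trs",
]


@dataclass
class AlignedOccurrence:
    """Per-state occurrence probability at offsets around event boundaries."""

    offsets: np.ndarray
    per_state_prob: np.ndarray  # K × n_offsets; columns sum to 1 where defined
    n_boundaries: int


def boundary_window_trs(tr: float) -> tuple[int, int]:
    """Post-boundary transition window in TRs: round(5 s/tr)..round(15 s/tr)."""
    return int(round(5.0 / tr)), int(round(15.0 / tr))


# ---------------------------------------------------------------------------
# boundary-aligned state occurrence
# ---------------------------------------------------------------------------


def _aligned_counts(
    labels: np.ndarray, K: int, boundaries: np.ndarray, offsets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(K × n_offsets occurrence counts, per-offset valid-boundary counts)."""
    T = labels.size
    counts = np.zeros((K, offsets.size))
    n_valid = np.zeros(offsets.size)
    for b in boundaries:
        t = b + offsets
        ok = (t >= 0) & (t < T)
        counts[labels[t[ok]], np.flatnonzero(ok)] += 1
        n_valid += ok
    return counts, n_valid


def boundary_aligned_occurrence(
    seq: StateSequence,
    boundaries: EventBoundaries,
    window: tuple[int, int] = (-2, 20),
) -> AlignedOccurrence:
    """Per-state occurrence probability around event boundaries (one subject).

    For each offset in the window, the proportion of boundaries at which
    each state occupied that TR.  Offsets falling outside the run at a
    particular boundary are dropped for that boundary only.  At every
    offset with data the probabilities sum to 1 across states.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    b = boundaries.boundary_trs
    if b.size and (b.min() < 0 or b.max() >= seq.T):
        raise ValueError("boundaries fall outside the run extent")
    counts, n_valid = _aligned_counts(seq.labels, seq.K, b, offsets)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(n_valid > 0, counts / n_valid, np.nan)
    return AlignedOccurrence(offsets, probs, int(b.size))


def group_aligned_occurrence(
    seqs: list[StateSequence],
    boundaries: EventBoundaries | list[EventBoundaries],
    window: tuple[int, int] = (-2, 20),
) -> AlignedOccurrence:
    """Within-subject boundary average, then across-subject average."""
    if isinstance(boundaries, EventBoundaries):
        boundaries = [boundaries] * len(seqs)
    per_subject = [
        boundary_aligned_occurrence(s, b, window).per_state_prob
        for s, b in zip(seqs, boundaries)
    ]
    probs = np.nanmean(per_subject, axis=0)
    return AlignedOccurrence(
        np.arange(window[0], window[1] + 1), probs, boundaries[0].boundary_trs.size
    )


def boundary_occurrence_null(
    seqs: StateSequence | list[StateSequence],
    boundaries: EventBoundaries | list[EventBoundaries],
    window: tuple[int, int] = (-2, 20),
    n_iter: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
) -> dict:
    """Chance distribution from circular-shifted boundary indices.

    Each iterate rotates every subject's boundary TRs by a random offset
    (mod run length) and recomputes the group-aligned occurrence.  Returns
    per-state, per-offset two-tailed p-values, BH-FDR adjusted over
    offsets within each state, plus the mean ± 1.96 sd null bands.
    """
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    if isinstance(boundaries, EventBoundaries):
        boundaries = [boundaries] * len(seqs)
    rng = np.random.default_rng(seed)
    observed = group_aligned_occurrence(seqs, boundaries, window)
    K, W = observed.per_state_prob.shape

    null = np.empty((n_iter, K, W))
    for it in range(n_iter):
        shifted = []
        for s, b in zip(seqs, boundaries):
            off = rng.integers(1, s.T)
            shifted.append(
                EventBoundaries(
                    np.sort((b.boundary_trs + off) % s.T),
                    b.story_labels,
                    b.hemodynamic_delay_tr,
                )
            )
        null[it] = group_aligned_occurrence(seqs, shifted, window).per_state_prob

    pvals = np.empty((K, W))
    lo = np.empty((K, W))
    hi = np.empty((K, W))
    for k in range(K):
        for w in range(W):
            nd = NullDistribution(null[:, k, w])
            pvals[k, w] = permutation_pvalue(observed.per_state_prob[k, w], nd)
            lo[k, w], hi[k, w] = null_band(nd)
    fdr = np.empty_like(pvals)
    reject = np.empty_like(pvals, dtype=bool)
    for k in range(K):  # FDR over time points, per state
        fdr[k], reject[k] = fdr_bh(pvals[k], q)
    return {
        "observed": observed,
        "p": pvals,
        "fdr_p": fdr,
        "reject": reject,
        "band_lo": lo,
        "band_hi": hi,
    }


# ---------------------------------------------------------------------------
# boundary-conditioned transitions into a target state
# ---------------------------------------------------------------------------


def boundary_transition_classification(
    seqs: list[StateSequence],
    boundaries: EventBoundaries | list[EventBoundaries],
    target_state: int,
    window: tuple[int, int] | None = None,
    tr: float = 1.0,
    n_perm: int = 10000,
    seed: int | None = None,
    q: float = 0.05,
) -> dict:
    """Which states feed a target state at vs. away from event boundaries.

    Every transition *into* ``target_state`` is labeled "boundary" if its
    onset falls window[0]..window[1] TRs after some event boundary, else
    "non-boundary".  Per subject and class, the source-state proportions
    are computed (they sum to 1 within a class); the boundary vs.
    non-boundary difference per source state is tested across subjects
    with a sign-permutation test, BH-FDR over the K−1 source states.
    Subjects lacking transitions in a class are excluded (with a warning)
    from the paired contrast.
    """
    if isinstance(boundaries, EventBoundaries):
        boundaries = [boundaries] * len(seqs)
    if window is None:
        window = boundary_window_trs(tr)
    lo, hi = window
    K = seqs[0].K
    if not (0 <= target_state < K):
        raise ValueError("target_state out of range")
    sources = [k for k in range(K) if k != target_state]

    props = {"boundary": [], "non_boundary": []}
    for seq, b in zip(seqs, boundaries):
        counts = {"boundary": np.zeros(K), "non_boundary": np.zeros(K)}
        offset = 0
        for run in seq.runs():
            trans = np.flatnonzero(np.diff(run) != 0) + 1
            for t in trans[run[trans] == target_state]:
                t_global = t + offset
                near = np.any(
                    (t_global - b.boundary_trs >= lo) & (t_global - b.boundary_trs <= hi)
                )
                counts["boundary" if near else "non_boundary"][run[t - 1]] += 1
            offset += run.size
        for cls in props:
            total = counts[cls].sum()
            props[cls].append(counts[cls] / total if total > 0 else np.full(K, np.nan))

    prop_b = np.asarray(props["boundary"])[:, sources]
    prop_nb = np.asarray(props["non_boundary"])[:, sources]
    paired = np.isfinite(prop_b).all(axis=1) & np.isfinite(prop_nb).all(axis=1)
    if paired.sum() < len(seqs):
        warnings.warn(
            f"{len(seqs) - int(paired.sum())} subject(s) lack transitions in a class; excluded"
        )
    diffs = prop_b[paired] - prop_nb[paired]
    if diffs.shape[0] == 0:
        warnings.warn("no subject has transitions in both classes; contrast undefined")
        pvals = np.full(len(sources), np.nan)
        fdr = np.full(len(sources), np.nan)
        reject = np.zeros(len(sources), dtype=bool)
    else:
        pvals = np.array(
            [
                sign_permutation_test(diffs[:, i], n_perm=n_perm, seed=seed)
                for i in range(len(sources))
            ]
        )
        fdr, reject = fdr_bh(pvals, q)
    return {
        "sources": sources,
        "boundary_proportions": prop_b,
        "non_boundary_proportions": prop_nb,
        "p": pvals,
        "fdr_p": fdr,
        "reject": reject,
    }


# ---------------------------------------------------------------------------
# attention by state
# ---------------------------------------------------------------------------


def attention_by_state(trace: BehavioralTrace, seq: StateSequence) -> np.ndarray:
    """Mean attention level during each state's occupancy (NaN if absent)."""
    v = trace.values
    if v.size != seq.T:
        raise ValueError("trace and state sequence lengths differ")
    out = np.full(seq.K, np.nan)
    for k in range(seq.K):
        mask = seq.labels == k
        if mask.any():
            out[k] = v[mask].mean()
    return out


def attention_by_state_group(
    traces: list[BehavioralTrace],
    seqs: list[StateSequence],
    n_iter: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
) -> dict:
    """Group attention-by-state means with a circular-shift null.

    The per-subject state means are averaged across subjects (each state
    over the subjects in which it occurred).  The null circular-shifts
    each subject's *trace* relative to its state sequence and recomputes
    the group means; per-state two-tailed p-values are BH-FDR corrected
    over the K states.
    """
    rng = np.random.default_rng(seed)
    K = seqs[0].K
    observed = np.nanmean([attention_by_state(t, s) for t, s in zip(traces, seqs)], axis=0)
    null = np.empty((n_iter, K))
    for it in range(n_iter):
        per_subj = []
        for t, s in zip(traces, seqs):
            shifted = circular_shift(t.values, rng=rng)
            per_subj.append(
                attention_by_state(
                    BehavioralTrace(shifted, tr=t.tr, kind=t.kind, hrf_convolved=t.hrf_convolved),
                    s,
                )
            )
        null[it] = np.nanmean(per_subj, axis=0)
    pvals = np.array(
        [permutation_pvalue(observed[k], NullDistribution(null[:, k])) for k in range(K)]
    )
    fdr, reject = fdr_bh(pvals, q)
    return {"means": observed, "p": pvals, "fdr_p": fdr, "reject": reject, "null": null}


# ---------------------------------------------------------------------------
# block-wise occupancy
# ---------------------------------------------------------------------------


def blockwise_occupancy(
    seqs: list[StateSequence],
    block_table: list[tuple[int, int, str]],
    n_perm: int = 10000,
    seed: int | None = None,
    q: float = 0.05,
) -> dict:
    """Per-block-type fractional occupancy and paired cross-type contrasts.

    ``block_table`` lists non-overlapping (start_tr, end_tr, label)
    intervals (end exclusive).  Occupancy is computed per subject within
    each block type (pooling that type's blocks); for each pair of block
    types, the per-state occupancy difference across subjects is tested
    with a sign-permutation test, BH-FDR over the K states.
    """
    blocks = sorted(block_table)
    for (a0, b0, _), (a1, _, _) in zip(blocks, blocks[1:]):
        if a1 < b0:
            raise ValueError("blocks overlap")
    labels = sorted({lab for _, _, lab in blocks})
    K = seqs[0].K

    occ: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for seq in seqs:
        for lab in labels:
            trs = np.concatenate(
                [np.arange(a, b) for a, b, l in blocks if l == lab]
            )
            if trs.size == 0 or trs.max() >= seq.T:
                raise ValueError(f"empty or out-of-range block type {lab!r}")
            sub = StateSequence(seq.labels[trs], K=K)
            occ[lab].append(fractional_occupancy(sub))
    occ_arr = {lab: np.asarray(v) for lab, v in occ.items()}

    contrasts = {}
    for la, lb in itertools.combinations(labels, 2):
        diffs = occ_arr[la] - occ_arr[lb]
        pvals = np.array(
            [sign_permutation_test(diffs[:, k], n_perm=n_perm, seed=seed) for k in range(K)]
        )
        fdr, reject = fdr_bh(pvals, q)
        contrasts[(la, lb)] = {
            "mean_diff": diffs.mean(axis=0),
            "p": pvals,
            "fdr_p": fdr,
            "reject": reject,
        }
    return {"occupancy": occ_arr, "contrasts": contrasts}


# ---------------------------------------------------------------------------
# paired sign-permutation test
# ---------------------------------------------------------------------------


def sign_permutation_test(
    diffs, n_perm: int = 10000, seed: int | None = None, exact_limit: int = 14
) -> float:
    """Two-tailed sign-permutation test of paired differences against 0.

    The statistic is the mean difference; under the null each subject's
    difference is sign-symmetric.  All 2^n sign flips are enumerated when
    n ≤ ``exact_limit`` (exact p), otherwise ``n_perm`` random flips with
    the add-one correction.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    d = d[np.isfinite(d)]
    n = d.size
    if n == 0:
        raise ValueError("no finite paired differences")
    observed = abs(d.mean())
    if n <= exact_limit:
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
        stats = np.abs(signs @ d) / n
        return float(np.mean(stats >= observed - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stats = np.abs(signs @ d) / n
    return float((np.count_nonzero(stats >= observed - 1e-12) + 1) / (n_perm + 1))
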