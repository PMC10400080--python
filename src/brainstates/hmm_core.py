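"""Gaussian-emission hidden Markov model: estimation, decoding, selection.

The model: at each TR the brain occupies one of K discrete latent states;
observed parcel activity y_t is drawn from a state-specific multivariate
Gaussian N(mu_s, Sigma_s) with a *full* covariance (states differ in their
coupling structure, not just their mean pattern), and states follow a
first-order Markov chain with transition matrix A (rows sum to 1).

Estimation is expectation-maximization over the forward-backward
recursions, initialized from k-means cluster statistics; decoding is the
Viterbi algorithm.  Multi-run data are handled by restarting the forward
recursion with the initial distribution at every run boundary and by never
counting transitions across a boundary.  The number of states K is chosen
by leave-one-subject-out cross-validation scored with the
Calinski–Harabasz criterion on the held-out subject's decoded labels.
Surrogate (null) models are obtained by independently circular-shifting
each parcel's time course, which destroys cross-parcel covariance while
preserving each parcel's autocorrelation, and refitting.

All densities are evaluated in log space; forward-backward uses the
scaled (normalized) recursions, so likelihoods of long concatenations do
not underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .null_stats import circular_shift
from .timeseries_io import ParcelTimeSeries, concatenate_runs, znormalize

__all__ = [
    "HMMParameters",
    "StateSequence",
    "PosteriorMatrix",
    "InitializationError",
    "NumericalError",
    "kmeans_init",
    "forward_backward",
    "em_fit",
    "fit_with_restarts",
    "viterbi_decode",
    "calinski_harabasz",
    "select_K",
    "fit_surrogate_ensemble",
    "save_hmm_parameters",
    "load_hmm_parameters",
    "save_state_sequence",
    "load_state_sequence",
    "match_states",
    "relabel",
]

RIDGE = 1e-6  # covariance floor added at every M-step
CH_CAP = 1e12  # sentinel for an infinite Calinski–Harabasz score


class InitializationError(RuntimeError):
    """k-means initialization could not produce K non-empty clusters."""


class NumericalError(RuntimeError):
    """A covariance became singular / a density non-finite during fitting."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class HMMParameters:
    """K state means/covariances, transition matrix, initial distribution."""

    means: np.ndarray  # K×P
    covariances: np.ndarray  # K×P×P
    transition: np.ndarray  # K×K, rows sum to 1
    initial: np.ndarray  # K
    log_likelihood: float = float("nan")
    log_likelihood_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.initial = np.asarray(self.initial, dtype=float).ravel()
        K, P = self.means.shape
        if self.covariances.shape != (K, P, P):
            raise ValueError("covariances must be K×P×P")
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K×K")
        if self.initial.shape != (K,):
            raise ValueError("initial must have length K")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def P(self) -> int:
        return self.means.shape[1]

    def validate(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=atol):
            raise ValueError("initial distribution must sum to 1")
        for k in range(self.K):
            if not np.allclose(self.covariances[k], self.covariances[k].T, atol=1e-8):
                raise ValueError(f"covariance of state {k} is not symmetric")
            if np.linalg.eigvalsh(self.covariances[k])[0] <= 0:
                raise ValueError(f"covariance of state {k} is not positive definite")


@dataclass
class StateSequence:
    """Decoded (or simulated) per-TR state labels over concatenated runs."""

    labels: np.ndarray
    K: int
    run_boundary_index: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.labels.size == 0:
            raise ValueError("empty state sequence")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValueError("labels out of range [0, K)")
        if not self.run_boundary_index or self.run_boundary_index[0] != 0:
            raise ValueError("run_boundary_index must start at 0")

    @property
    def T(self) -> int:
        return self.labels.size

    def runs(self) -> list[np.ndarray]:
        """Per-run label vectors."""
        stops = list(self.run_boundary_index[1:]) + [self.T]
        return [self.labels[a:b] for a, b in zip(self.run_boundary_index, stops)]


@dataclass
class PosteriorMatrix:
    """Per-TR posterior state probabilities gamma (T×K, rows sum to 1)."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")


def _segments(T: int, boundaries) -> list[tuple[int, int]]:
    starts = list(boundaries) if boundaries else [0]
    stops = starts[1:] + [T]
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------


def _emission_logprob(data: np.ndarray, params: HMMParameters) -> np.ndarray:
    """T×K matrix of log N(y_t | mu_k, Sigma_k)."""
    T, P = data.shape
    out = np.empty((T, params.K))
    for k in range(params.K):
        try:
            L = np.linalg.cholesky(params.covariances[k])
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular covariance for state {k}") from exc
        diff = data - params.means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (maha + logdet + P * np.log(2 * np.pi))
    if not np.all(np.isfinite(out)):
        raise NumericalError("non-finite emission log-density")
    return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def kmeans_init(
    data: np.ndarray,
    K: int,
    seed: int | None = None,
    run_boundary_index: list[int] | None = None,
    max_retries: int = 5,
) -> HMMParameters:
    """Initialize HMM parameters from k-means cluster statistics.

    Means/covariances come from the hard cluster assignments; transition and
    initial probabilities from the assignment sequence with add-one
    smoothing (boundary-crossing pairs excluded).  k-means itself uses 10
    internal restarts; an empty cluster triggers a bounded re-seed.
    """
    data = np.asarray(data, dtype=float)
    T, P = data.shape
    if K < 1:
        raise ValueError("K must be ≥ 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        km = KMeans(n_clusters=K, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(data)
        counts = np.bincount(labels, minlength=K)
        if np.all(counts > 0):
            break
    else:
        raise InitializationError(f"could not obtain {K} non-empty clusters")

    means = np.empty((K, P))
    covs = np.empty((K, P, P))
    for k in range(K):
        members = data[labels == k]
        means[k] = members.mean(axis=0)
        if members.shape[0] > P:
            covs[k] = np.cov(members.T, ddof=0) + RIDGE * np.eye(P)
        else:  # too few members for a stable full covariance
            covs[k] = np.eye(P)

    trans = np.ones((K, K))  # add-one smoothing
    init = np.ones(K)
    for a, b in _segments(T, run_boundary_index):
        seg = labels[a:b]
        init[seg[0]] += 1
        np.add.at(trans, (seg[:-1], seg[1:]), 1)
    trans /= trans.sum(axis=1, keepdims=True)
    init /= init.sum()
    return HMMParameters(means, covs, trans, init)


# ---------------------------------------------------------------------------
# forward-backward / EM
# ---------------------------------------------------------------------------


def forward_backward(
    data: np.ndarray,
    params: HMMParameters,
    run_boundary_index: list[int] | None = None,
) -> tuple[PosteriorMatrix, np.ndarray, float]:
    """Scaled forward-backward over (possibly multi-run) data.

    Returns (posteriors gamma, summed pairwise-state expectations xi K×K
    excluding boundary-crossing pairs, total log-likelihood).
    """
    data = np.asarray(data, dtype=float)
    T, _ = data.shape
    K = params.K
    logB = _emission_logprob(data, params)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])  # scaled emission likelihoods

    A = params.transition
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    loglik = float(np.sum(shift))

    for a, b in _segments(T, run_boundary_index):
        n = b - a
        alpha = np.empty((n, K))
        c = np.empty(n)  # per-step normalizers
        alpha[0] = params.initial * B[a]
        c[0] = alpha[0].sum()
        if c[0] <= 0:
            raise NumericalError("zero forward probability at a run start")
        alpha[0] /= c[0]
        for t in range(1, n):
            alpha[t] = (alpha[t - 1] @ A) * B[a + t]
            c[t] = alpha[t].sum()
            if c[t] <= 0:
                raise NumericalError(f"zero forward probability at t={a + t}")
            alpha[t] /= c[t]
        loglik += float(np.sum(np.log(c)))

        beta = np.ones(K)
        gamma[b - 1] = alpha[n - 1]
        for t in range(n - 2, -1, -1):
            bb = B[a + t + 1] * beta
            xi = (alpha[t][:, None] * A * bb[None, :]) / c[t + 1]
            xi_sum += xi
            beta = (A @ bb) / c[t + 1]
            g = alpha[t] * beta
            gamma[a + t] = g / g.sum()

    return PosteriorMatrix(gamma), xi_sum, loglik


def em_fit(
    data: np.ndarray,
    run_boundary_index: list[int] | None = None,
    K: int = 4,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-4,
    init: HMMParameters | None = None,
) -> HMMParameters:
    """EM estimation of a K-state full-covariance Gaussian HMM.

    Iterates until the log-likelihood gain falls below ``tol`` or
    ``max_iter`` is reached.  The per-iteration log-likelihood trace is
    stored on the returned parameters and is non-decreasing (EM guarantee,
    numerical slack 1e-6).
    """
    data = np.asarray(data, dtype=float)
    T, P = data.shape
    params = init if init is not None else kmeans_init(data, K, seed, run_boundary_index)
    starts = [a for a, _ in _segments(T, run_boundary_index)]
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        post, xi_sum, ll = forward_backward(data, params, run_boundary_index)
        trace.append(ll)
        gamma = post.gamma

        # M-step
        w = gamma.sum(axis=0)  # expected state counts
        means = (gamma.T @ data) / w[:, None]
        covs = np.empty((K, P, P))
        for k in range(K):
            diff = data - means[k]
            covs[k] = (diff.T * gamma[:, k]) @ diff / w[k] + RIDGE * np.eye(P)
        trans = xi_sum + 1e-12
        trans /= trans.sum(axis=1, keepdims=True)
        initial = gamma[starts].sum(axis=0)
        initial /= initial.sum()
        params = HMMParameters(means, covs, trans, initial)

        if ll - prev < tol:
            break
        prev = ll

    params.log_likelihood = trace[-1]
    params.log_likelihood_trace = np.asarray(trace)
    return params


def fit_with_restarts(
    data: np.ndarray,
    run_boundary_index: list[int] | None = None,
    K: int = 4,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> HMMParameters:
    """Run EM from ``n_restarts`` k-means seeds; keep the highest likelihood."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be ≥ 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31 - 1, size=n_restarts)
    best: HMMParameters | None = None
    errors: list[Exception] = []
    for s in seeds:
        try:
            fit = em_fit(data, run_boundary_index, K, int(s), max_iter, tol)
        except (NumericalError, InitializationError) as exc:
            errors.append(exc)
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise NumericalError(f"all {n_restarts} restarts failed: {errors[-1]}")
    return best


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def viterbi_decode(
    data: np.ndarray,
    params: HMMParameters,
    run_boundary_index: list[int] | None = None,
) -> StateSequence:
    """Most probable state path per run (log-space Viterbi).

    Ties are broken toward the lowest state index.
    """
    data = np.asarray(data, dtype=float)
    T, _ = data.shape
    K = params.K
    logB = _emission_logprob(data, params)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        logpi = np.log(params.initial)
    labels = np.empty(T, dtype=int)
    boundaries = [a for a, _ in _segments(T, run_boundary_index)]
    for a, b in _segments(T, run_boundary_index):
        n = b - a
        delta = np.empty((n, K))
        psi = np.zeros((n, K), dtype=int)
        delta[0] = logpi + logB[a]
        for t in range(1, n):
            cand = delta[t - 1][:, None] + logA
            psi[t] = np.argmax(cand, axis=0)  # first max → lowest index
            delta[t] = cand[psi[t], np.arange(K)] + logB[a + t]
        path = np.empty(n, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(n - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]
        labels[a:b] = path
    return StateSequence(labels, K=K, run_boundary_index=boundaries)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def calinski_harabasz(data: np.ndarray, labels: np.ndarray, cap: float = CH_CAP) -> float:
    """Calinski–Harabasz score [tr(B)/(k−1)] / [tr(W)/(N−k)].

    B and W are the between/within-cluster scatter matrices about the grand
    mean.  A zero within-scatter (perfectly tight clusters) returns ``cap``.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=int).ravel()
    N = data.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("Calinski–Harabasz needs at least two distinct labels")
    grand = data.mean(axis=0)
    trB = 0.0
    trW = 0.0
    for u in uniq:
        members = data[labels == u]
        mu = members.mean(axis=0)
        trB += members.shape[0] * float(np.sum((mu - grand) ** 2))
        trW += float(np.sum((members - mu) ** 2))
    if trW == 0.0:
        return cap
    return min(cap, (trB / (k - 1)) / (trW / (N - k)))


def _group_by_subject(runs: list[ParcelTimeSeries]) -> dict[str, list[ParcelTimeSeries]]:
    groups: dict[str, list[ParcelTimeSeries]] = {}
    for r in runs:
        groups.setdefault(r.subject_id, []).append(r)
    return groups


def select_K(
    runs: list[ParcelTimeSeries],
    candidate_Ks=range(2, 11),
    seed: int | None = None,
    n_restarts: int = 3,
    max_iter: int = 50,
    tol: float = 1e-2,
    normalize: bool = True,
) -> tuple[int, dict[int, np.ndarray]]:
    """Choose K by leave-one-subject-out cross-validated Calinski–Harabasz.

    For each fold and candidate K: fit on all-but-one subject, Viterbi-decode
    the held-out subject, and score the held-out observations against the
    decoded hard labels.  The K with the largest fold-mean score wins; ties
    go to the smallest K.  A K whose folds cannot all be scored (fit failure
    or a single-state decoding) is excluded with a warning.

    Selection uses a short EM schedule per fold (default 50 iterations,
    loose tolerance): the Calinski–Harabasz score depends on the decoded
    hard labels, which stabilize long before the likelihood fully
    converges, and the cross-validated comparison across K is what matters.

    Returns (chosen K, {K: per-fold scores}).
    """
    groups = _group_by_subject(runs)
    subjects = list(groups)
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out selection needs ≥ 3 subjects")
    prep = {
        s: concatenate_runs([znormalize(r) if normalize else r for r in rs])
        for s, rs in groups.items()
    }
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(2**31 - 1, size=(len(subjects), len(list(candidate_Ks))))

    scores: dict[int, np.ndarray] = {}
    for j, K in enumerate(candidate_Ks):
        per_fold = np.full(len(subjects), np.nan)
        for i, held_out in enumerate(subjects):
            train_mats, train_bounds, offset = [], [], 0
            for s in subjects:
                if s == held_out:
                    continue
                mat, bounds = prep[s]
                train_mats.append(mat)
                train_bounds.extend(b + offset for b in bounds)
                offset += mat.shape[0]
            train = np.vstack(train_mats)
            test, test_bounds = prep[held_out]
            try:
                fit = fit_with_restarts(
                    train, train_bounds, K, n_restarts, int(fold_seeds[i, j]),
                    max_iter, tol,
                )
                decoded = viterbi_decode(test, fit, test_bounds)
                per_fold[i] = calinski_harabasz(test, decoded.labels)
            except (NumericalError, InitializationError, ValueError) as exc:
                warnings.warn(f"K={K}, fold {held_out}: {exc}; K marked invalid")
                per_fold[:] = np.nan
                break
        scores[K] = per_fold

    means = {K: np.nanmean(v) if np.all(np.isfinite(v)) else np.nan for K, v in scores.items()}
    valid = [K for K, m in means.items() if np.isfinite(m)]
    if not valid:
        raise RuntimeError("no candidate K produced valid cross-validated scores")
    best_score = max(means[K] for K in valid)
    chosen = min(K for K in valid if means[K] == best_score)
    return chosen, scores


# ---------------------------------------------------------------------------
# surrogate (null) models
# ---------------------------------------------------------------------------


def fit_surrogate_ensemble(
    data: np.ndarray,
    run_boundary_index: list[int] | None = None,
    K: int = 4,
    n_iter: int = 1000,
    seed: int | None = None,
    max_em_iter: int = 100,
    n_restarts: int = 1,
    tol: float = 1e-2,
    decode: bool = False,
) -> list[HMMParameters] | list[tuple[HMMParameters, StateSequence]]:
    """Fit HMMs to per-parcel circular-shifted surrogates of the data.

    Independently rotating each parcel's time course (within run) destroys
    cross-parcel covariance while preserving marginals and autocorrelation;
    refitting the HMM on each surrogate yields the chance distribution of
    any state-level statistic.  Failed iterates are skipped with a warning.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_iter):
        shifted = circular_shift(data, rng=rng, run_boundaries=run_boundary_index)
        try:
            fit = fit_with_restarts(
                shifted, run_boundary_index, K, n_restarts,
                int(rng.integers(2**31 - 1)), max_em_iter, tol,
            )
        except (NumericalError, InitializationError) as exc:
            warnings.warn(f"surrogate iterate {i} failed: {exc}")
            continue
        if decode:
            out.append((fit, viterbi_decode(shifted, fit, run_boundary_index)))
        else:
            out.append(fit)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_hmm_parameters(params: HMMParameters, path) -> "Path":
    """Write fitted parameters as JSON (nested arrays)."""
    import json
    from pathlib import Path

    path = Path(path)
    payload = {
        "K": params.K,
        "means": params.means.tolist(),
        "covariances": params.covariances.tolist(),
        "transition": params.transition.tolist(),
        "initial": params.initial.tolist(),
        "log_likelihood": None
        if np.isnan(params.log_likelihood)
        else params.log_likelihood,
    }
    path.write_text(json.dumps(payload))
    return path


def load_hmm_parameters(path) -> HMMParameters:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    return HMMParameters(
        means=np.asarray(d["means"]),
        covariances=np.asarray(d["covariances"]),
        transition=np.asarray(d["transition"]),
        initial=np.asarray(d["initial"]),
        log_likelihood=float("nan") if d["log_likelihood"] is None else d["log_likelihood"],
    )


def save_state_sequence(seq: StateSequence, path) -> "Path":
    """Single-column TSV of labels + JSON sidecar with K and run offsets."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savetxt(path, seq.labels[:, None], fmt="%d", header="state", comments="")
    path.with_suffix(".json").write_text(
        json.dumps({"K": seq.K, "run_boundary_index": list(seq.run_boundary_index)})
    )
    return path


def load_state_sequence(path) -> StateSequence:
    import json
    from pathlib import Path

    path = Path(path)
    labels = np.loadtxt(path, dtype=int, skiprows=1)
    meta = json.loads(path.with_suffix(".json").read_text())
    return StateSequence(labels, K=meta["K"], run_boundary_index=meta["run_boundary_index"])


# ---------------------------------------------------------------------------
# label matching utilities
# ---------------------------------------------------------------------------


def match_states(est_means: np.ndarray, ref_means: np.ndarray) -> np.ndarray:
    """Optimal assignment perm such that est state k matches ref state perm[k].

    Minimizes total squared distance between matched means (Hungarian
    algorithm); used to undo the label-permutation ambiguity of mixture
    fits before comparing parameters or sequences.
    """
    est = np.atleast_2d(est_means)
    ref = np.atleast_2d(ref_means)
    cost = np.sum((est[:, None, :] - ref[None, :, :]) ** 2, axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(est.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def relabel(params: HMMParameters, perm: np.ndarray) -> HMMParameters:
    """Apply a state permutation: new state perm[k] ← old state k."""
    perm = np.asarray(perm, dtype=int)
    inv = np.argsort(perm)
    return HMMParameters(
        means=params.means[inv],
        covariances=params.covariances[inv],
        transition=params.transition[np.ix_(inv, inv)],
        initial=params.initial[inv],
        log_likelihood=params.log_likelihood,
    )
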