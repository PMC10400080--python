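"""Diffusion-map connectivity gradients and state projections.

A group-average functional connectome (parcel × parcel Pearson
correlations) is sparsified row-wise at a quantile threshold, converted to
a cosine-similarity affinity, and decomposed with a diffusion-map
embedding (anisotropic normalization alpha).  The resulting gradients are
the principal axes of connectome variation; latent states are situated in
gradient space by averaging each gradient's loadings weighted by the
state's mean activity pattern.  The module also quantifies how much raw
time-series variance the gradient axes capture, and tests whether the
observed states are unusually spread out / extreme in gradient space
relative to surrogate-HMM states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.metrics.pairwise import cosine_similarity

from .null_stats import NullDistribution, fdr_bh, permutation_pvalue
from .timeseries_io import ParcelTimeSeries, concatenate_runs, znormalize

__all__ = [
    "GradientEmbedding",
    "functional_connectome",
    "diffusion_embedding",
    "project_states",
    "state_distance_test",
    "explained_timeseries_variance",
]


@dataclass
class GradientEmbedding:
    coordinates: np.ndarray  # P×G
    eigenvalues: np.ndarray  # G (non-trivial, descending)
    variance_ratio: np.ndarray  # eigenvalue_g / sum of all non-trivial eigenvalues
    alpha: float
    threshold_quantile: float


def functional_connectome(runs: list[ParcelTimeSeries], normalize: bool = True) -> np.ndarray:
    """Group-mean P×P Pearson correlation matrix, diagonal zeroed.

    Per subject: z-normalize each run, concatenate the subject's runs,
    correlate; then average the subject matrices.
    """
    groups: dict[str, list[ParcelTimeSeries]] = {}
    for r in runs:
        groups.setdefault(r.subject_id, []).append(r)
    mats = []
    for rs in groups.values():
        data, _ = concatenate_runs([znormalize(r) if normalize else r for r in rs])
        mats.append(np.corrcoef(data.T))
    fc = np.mean(mats, axis=0)
    np.fill_diagonal(fc, 0.0)
    return fc


def diffusion_embedding(
    fc: np.ndarray,
    threshold_quantile: float = 0.90,
    alpha: float = 0.5,
    n_components: int = 2,
) -> GradientEmbedding:
    """Diffusion-map embedding of a thresholded, cosine-affinity connectome.

    Per row, entries below that row's ``threshold_quantile`` quantile are
    zeroed (negatives are clipped to 0 first); the affinity is the cosine
    similarity between thresholded rows.  The affinity is then
    anisotropically normalized (W / d^alpha outer d^alpha), row-normalized
    into a Markov matrix, and eigendecomposed; the trivial constant
    eigenvector is dropped.  Coordinates use diffusion time t=0 (no
    eigenvalue scaling), with each component's sign fixed so its
    largest-magnitude loading is positive.
    """
    fc = np.asarray(fc, dtype=float)
    P = fc.shape[0]
    if P < 3 or fc.shape != (P, P):
        raise ValueError("fc must be a P×P matrix with P ≥ 3")
    X = np.clip(fc, 0.0, None)
    thresh = np.quantile(X, threshold_quantile, axis=1, keepdims=True)
    X = np.where(X >= thresh, X, 0.0)
    W = cosine_similarity(X)
    np.fill_diagonal(W, 0.0)

    n_comp, comp_labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp_labels)
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components, sizes {sizes.tolist()})"
        )

    d = W.sum(axis=1)
    W_alpha = W / np.outer(d**alpha, d**alpha)
    d2 = W_alpha.sum(axis=1)
    # symmetric conjugate of the Markov matrix → real spectrum via eigh
    S = W_alpha / np.sqrt(np.outer(d2, d2))
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the Markov matrix
    psi = evecs / np.sqrt(d2)[:, None]
    # drop the trivial (constant) first component
    evals, psi = evals[1:], psi[:, 1:]
    nontrivial = evals[evals > 0]
    ratios = evals[:n_components] / nontrivial.sum()

    coords = psi[:, :n_components].copy()
    for g in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, g])), g] < 0:
            coords[:, g] *= -1
    return GradientEmbedding(
        coordinates=coords,
        eigenvalues=evals[:n_components],
        variance_ratio=ratios,
        alpha=alpha,
        threshold_quantile=threshold_quantile,
    )


def project_states(state_means: np.ndarray, coordinates: np.ndarray) -> np.ndarray:
    """Situate states in gradient space: K×G matrix of mean element-wise products.

    coordinate_kg = mean over parcels of gradient_pg · mean_kp.  A state
    with a zero (baseline) activity pattern lands at the origin.
    """
    means = np.atleast_2d(np.asarray(state_means, dtype=float))
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if means.shape[1] != coords.shape[0]:
        raise ValueError("state means and gradient coordinates disagree on P")
    return means @ coords / coords.shape[0]


def _mean_pairwise_distance(coords: np.ndarray) -> float:
    K = coords.shape[0]
    d = [
        float(np.linalg.norm(coords[i] - coords[j]))
        for i in range(K)
        for j in range(i + 1, K)
    ]
    return float(np.mean(d))


def state_distance_test(
    state_coords: np.ndarray,
    null_coords: list[np.ndarray],
    q: float = 0.05,
) -> dict:
    """Are states unusually spread out / extreme in gradient space?

    ``null_coords`` is an ensemble of K×G coordinate sets from surrogate
    HMMs.  Tests (i) the mean pairwise Euclidean distance between states
    against the null ensemble's, two-tailed; (ii) each state's position on
    each axis against the pooled null positions on that axis, two-tailed
    with BH-FDR over the K×G comparisons.
    """
    coords = np.atleast_2d(np.asarray(state_coords, dtype=float))
    if not null_coords:
        raise ValueError("null ensemble is empty")
    K, G = coords.shape
    null_dist = NullDistribution(
        [_mean_pairwise_distance(np.atleast_2d(c)) for c in null_coords],
        statistic_name="mean_pairwise_state_distance",
    )
    observed = _mean_pairwise_distance(coords)
    p_distance = permutation_pvalue(observed, null_dist)

    pooled = {g: NullDistribution(np.concatenate([np.atleast_2d(c)[:, g] for c in null_coords]))
              for g in range(G)}
    extremity_p = np.array(
        [[permutation_pvalue(coords[k, g], pooled[g]) for g in range(G)] for k in range(K)]
    )
    adj, reject = fdr_bh(extremity_p.ravel(), q)
    return {
        "mean_distance": observed,
        "null_mean_distance": float(np.mean(null_dist.values)),
        "p_distance": p_distance,
        "extremity_p": extremity_p,
        "extremity_fdr_p": adj.reshape(K, G),
        "extremity_reject": reject.reshape(K, G),
    }


def explained_timeseries_variance(
    runs: list[ParcelTimeSeries],
    coordinates: np.ndarray,
    normalize: bool = True,
) -> tuple[np.ndarray, float]:
    """Variance of the parcel time series captured by the gradient axes.

    All subjects' runs are concatenated; the series is projected onto each
    gradient (mean over parcels of gradient loading × activity); r²_g is
    the mean over parcels of the squared Pearson correlation between each
    parcel series and projected series g.  Returns (per-gradient r²,
    their sum).
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    data = np.vstack(
        [(znormalize(r) if normalize else r).values for r in runs]
    )
    if data.shape[1] != coords.shape[0]:
        raise ValueError("runs and gradient coordinates disagree on P")
    projected = data @ coords / coords.shape[0]  # T×G
    r2 = np.empty(coords.shape[1])
    for g in range(coords.shape[1]):
        proj = projected[:, g]
        if proj.std() == 0:
            raise ValueError(f"projected series for gradient {g} is constant")
        c = np.corrcoef(np.column_stack([proj, data]).T)[0, 1:]
        r2[g] = float(np.mean(c**2))
    return r2, float(r2.sum())
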