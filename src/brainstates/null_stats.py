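"""Circular-shift surrogates, permutation p-values, and FDR correction.

Every inferential statement in the pipeline is made against a surrogate
(null) distribution obtained by circularly rotating a time series — the
state sequence, the behavioral trace, the boundary indices, or the parcel
signals themselves, depending on the analysis.  Rotation preserves the
autocorrelation and marginal distribution of the series while destroying
its temporal alignment with everything else, which is exactly the null
hypothesis these analyses test against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NullDistribution",
    "circular_shift",
    "permutation_pvalue",
    "null_band",
    "fdr_bh",
    "save_null_distribution",
    "load_null_distribution",
    "zstat_vs_null",
]


@dataclass
class NullDistribution:
    """Realizations of a statistic under a permutation/surrogate scheme."""

    values: np.ndarray
    statistic_name: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("null distribution must contain at least one value")

    @property
    def n_iter(self) -> int:
        return int(self.values.size)


def _segment_bounds(T: int, run_boundaries) -> list[tuple[int, int]]:
    """(start, stop) pairs for each run segment of a length-T concatenation."""
    if run_boundaries is None:
        return [(0, T)]
    starts = list(run_boundaries)
    if not starts or starts[0] != 0:
        raise ValueError("run_boundaries must start with offset 0")
    stops = starts[1:] + [T]
    return list(zip(starts, stops))


def circular_shift(
    series: np.ndarray,
    offsets: int | np.ndarray | None = None,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    run_boundaries=None,
) -> np.ndarray:
    """Rotate a 1-D series or each column of a T×P matrix along time.

    With ``offsets=None`` a uniformly random offset in [1, T_run-1] is drawn
    independently per column and per run segment (0 is excluded so every
    surrogate differs from the original).  Explicit offsets are taken modulo
    the segment length, so 0 and T act as the identity.  Shifts never cross
    run boundaries: each run segment is rotated on its own.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("series must be 1-D or 2-D (time × channels)")
    T, P = x.shape
    if T < 2:
        raise ValueError("need at least two time points to shift")
    if rng is None:
        rng = np.random.default_rng(seed)

    out = np.empty_like(x)
    for start, stop in _segment_bounds(T, run_boundaries):
        n = stop - start
        if offsets is None:
            offs = rng.integers(1, max(n, 2), size=P)
        else:
            offs = np.broadcast_to(np.asarray(offsets, dtype=int), (P,))
        for j in range(P):
            out[start:stop, j] = np.roll(x[start:stop, j], int(offs[j]) % n)
    return out[:, 0] if squeeze else out


def permutation_pvalue(observed: float, null: NullDistribution, tails: str = "two") -> float:
    """Add-one permutation p-value, two-tailed by default.

    p = min(1, 2 * min[(1 + #{null ≥ obs}) / (n+1), (1 + #{null ≤ obs}) / (n+1)]).
    One-tailed variants ("greater"/"less") use the corresponding single count.
    """
    v = null.values
    n = v.size
    hi = (1 + np.count_nonzero(v >= observed)) / (n + 1)
    lo = (1 + np.count_nonzero(v <= observed)) / (n + 1)
    if tails == "two":
        return float(min(1.0, 2.0 * min(hi, lo)))
    if tails == "greater":
        return float(min(1.0, hi))
    if tails == "less":
        return float(min(1.0, lo))
    raise ValueError(f"unknown tails: {tails!r}")


def null_band(null: NullDistribution, width: float = 1.96) -> tuple[float, float]:
    """Mean ± width·sd band of a null distribution (default 1.96)."""
    if null.n_iter < 2:
        raise ValueError("need at least two null realizations for a band")
    m = float(np.mean(null.values))
    s = float(np.std(null.values, ddof=1))
    return (m - width * s, m + width * s)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, rejection mask at q)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def save_null_distribution(null: NullDistribution, path) -> "Path":
    """Single-column TSV of realizations + JSON sidecar (name, n_iter, seed)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savetxt(path, null.values[:, None], header="value", comments="")
    path.with_suffix(".json").write_text(
        json.dumps(
            {"statistic_name": null.statistic_name, "n_iter": null.n_iter, "seed": null.seed}
        )
    )
    return path


def load_null_distribution(path) -> NullDistribution:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return NullDistribution(
        np.loadtxt(path, skiprows=1),
        statistic_name=meta["statistic_name"],
        seed=meta["seed"],
    )


def zstat_vs_null(observed: float, null: NullDistribution) -> float:
    """(observed − null mean) / null sd."""
    s = float(np.std(null.values, ddof=1)) if null.n_iter > 1 else 0.0
    if s == 0.0:
        raise ValueError("null distribution has zero standard deviation")
    return float((observed - np.mean(null.values)) / s)
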