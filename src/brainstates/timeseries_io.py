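"""Parcel time-series I/O and preprocessing.

Data model: one fMRI run is a T×P matrix (rows = volumes at a fixed TR,
columns = parcels, i.e. brain regions/networks whose voxel signals were
averaged upstream).  Runs are stored as TSV with a header row of parcel
labels plus a JSON sidecar holding tr/subject/run metadata; a manifest TSV
lists the runs of a group dataset in concatenation order.

Preprocessing implemented here, in the order the analysis uses it:
within-run z-normalization (sample sd, ddof=1), concatenation across runs
with recorded run offsets, canonical double-gamma HRF construction and
convolution for behavioral traces, and conversion of per-trial response
times into a TR-resolution "RT variability" attention proxy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "ParcelTimeSeries",
    "RunManifest",
    "ManifestEntry",
    "BehavioralTrace",
    "EventBoundaries",
    "DataFormatError",
    "DegenerateDataError",
    "IncompatibleRunsError",
    "load_parcel_timeseries",
    "save_parcel_timeseries",
    "load_manifest",
    "save_manifest",
    "load_event_boundaries",
    "save_event_boundaries",
    "znormalize",
    "znormalize_matrix",
    "concatenate_runs",
    "canonical_hrf",
    "hrf_convolve",
    "rt_variability_trace",
]

PARCEL_CATEGORIES = ("cortical", "subcortical")


class DataFormatError(ValueError):
    """A file or matrix does not match the declared layout."""


class DegenerateDataError(ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class IncompatibleRunsError(ValueError):
    """Runs that should share parcels/TR do not."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ParcelTimeSeries:
    """One subject-run of parcellated BOLD data (T time points × P parcels)."""

    values: np.ndarray
    tr: float
    subject_id: str
    run_id: str
    parcel_labels: list[str]
    parcel_categories: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("values must be a 2-D (time × parcel) matrix")
        T, P = self.values.shape
        if T < 2 or P < 2:
            raise DataFormatError(f"need T ≥ 2 and P ≥ 2, got T={T}, P={P}")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("values contain non-finite entries")
        if self.tr <= 0:
            raise DataFormatError("tr must be positive")
        self.parcel_labels = [str(s) for s in self.parcel_labels]
        if len(self.parcel_labels) != P:
            raise DataFormatError("number of parcel labels must equal P")
        if len(set(self.parcel_labels)) != P:
            raise DataFormatError("parcel labels must be unique")
        if self.parcel_categories is not None:
            if len(self.parcel_categories) != P:
                raise DataFormatError("need one category per parcel")
            bad = set(self.parcel_categories) - set(PARCEL_CATEGORIES)
            if bad:
                raise DataFormatError(f"unknown parcel categories: {sorted(bad)}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    run_id: str
    path: str
    condition: str = ""


@dataclass
class RunManifest:
    """Ordered list of subject-runs defining the concatenation order."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.run_id) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise DataFormatError("(subject_id, run_id) pairs must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.subject_id, None)
        return list(seen)


@dataclass
class BehavioralTrace:
    """A per-TR behavioral time course paired with a run (z-units after prep)."""

    values: np.ndarray
    tr: float
    kind: str = "engagement"  # or "rt_variability_inverted"
    hrf_convolved: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise DataFormatError("trace needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("trace contains non-finite values after interpolation")
        if self.tr <= 0:
            raise DataFormatError("tr must be positive")


@dataclass
class EventBoundaries:
    """Narrative event boundaries of a run, as TR indices of new-event onsets."""

    boundary_trs: np.ndarray
    story_labels: list[str]  # one per EVENT (len == n_boundaries + 1)
    hemodynamic_delay_tr: int = 5

    def __post_init__(self) -> None:
        self.boundary_trs = np.asarray(self.boundary_trs, dtype=int).ravel()
        if np.any(np.diff(self.boundary_trs) <= 0):
            raise DataFormatError("boundaries must be strictly increasing")
        if self.hemodynamic_delay_tr < 0:
            raise DataFormatError("hemodynamic delay must be ≥ 0")
        if len(self.story_labels) != self.boundary_trs.size + 1:
            raise DataFormatError(
                "need one story label per event (= number of boundaries + 1)"
            )

    @property
    def n_events(self) -> int:
        return self.boundary_trs.size + 1


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_parcel_timeseries(ts: ParcelTimeSeries, path) -> Path:
    """Write a run as TSV (header = parcel labels) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=ts.parcel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "tr": ts.tr,
        "subject_id": ts.subject_id,
        "run_id": ts.run_id,
        "parcel_categories": ts.parcel_categories,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_parcel_timeseries(
    path,
    manifest_entry: ManifestEntry | None = None,
    expected_parcels: int | None = None,
) -> ParcelTimeSeries:
    """Read a run TSV (+ sidecar); validate shape against the declared P.

    If the file is found transposed relative to the declared parcel count
    (rows = parcels instead of rows = time), it is flipped with a warning
    baked into the error path: an outright column-count mismatch raises
    :class:`DataFormatError`, naming both counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    mat = df.to_numpy()
    if not np.issubdtype(mat.dtype, np.number) or np.any(~np.isfinite(mat)):
        bad = np.argwhere(~np.isfinite(df.apply(pd.to_numeric, errors="coerce").to_numpy()))
        r, c = (bad[0] + [2, 1]) if bad.size else (0, 0)  # 1-based, +header row
        raise DataFormatError(f"non-numeric or missing cell near row {r}, column {c} of {path}")
    labels = list(df.columns)
    if expected_parcels is not None and mat.shape[1] != expected_parcels:
        if mat.shape[0] == expected_parcels:
            mat = mat.T
            labels = [f"p{i}" for i in range(mat.shape[1])]
        else:
            raise DataFormatError(
                f"{path}: file has {mat.shape[1]} columns but {expected_parcels} parcels declared"
            )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ParcelTimeSeries(
        values=mat,
        tr=float(meta.get("tr", 1.0)),
        subject_id=manifest_entry.subject_id if manifest_entry else meta.get("subject_id", "sub"),
        run_id=manifest_entry.run_id if manifest_entry else meta.get("run_id", "run"),
        parcel_labels=labels,
        parcel_categories=meta.get("parcel_categories"),
    )


def save_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"subject_id": e.subject_id, "run_id": e.run_id, "path": e.path, "condition": e.condition}
            for e in manifest.entries
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def load_manifest(path) -> RunManifest:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = [
        ManifestEntry(r.subject_id, r.run_id, r.path, r.condition) for r in df.itertuples()
    ]
    return RunManifest(entries)


def save_event_boundaries(ev: EventBoundaries, path) -> Path:
    """Two-column TSV (boundary_tr, story_label), one row per event.

    The first row carries the start-of-run (tr 0) so each event's story
    label round-trips; boundary_trs on load exclude that first row.
    """
    path = Path(path)
    trs = np.concatenate([[0], ev.boundary_trs])
    pd.DataFrame({"boundary_tr": trs, "story_label": ev.story_labels}).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_event_boundaries(path, hemodynamic_delay_tr: int = 5) -> EventBoundaries:
    df = pd.read_csv(path, sep="\t")
    return EventBoundaries(
        boundary_trs=df["boundary_tr"].to_numpy()[1:],
        story_labels=[str(s) for s in df["story_label"]],
        hemodynamic_delay_tr=hemodynamic_delay_tr,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def znormalize_matrix(values: np.ndarray, labels=None) -> np.ndarray:
    """Column-wise z-normalization with sample sd (ddof=1)."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = labels[zero[0]] if labels is not None else f"column {zero[0]}"
        raise DegenerateDataError(f"zero-variance parcel: {name}")
    return (values - mu) / sd


def znormalize(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Within-run z-normalization of every parcel time course."""
    return replace(ts, values=znormalize_matrix(ts.values, ts.parcel_labels))


def concatenate_runs(
    runs: list[ParcelTimeSeries], manifest: RunManifest | None = None
) -> tuple[np.ndarray, list[int]]:
    """Stack runs in order; return (T_total×P matrix, run start offsets).

    The offsets let downstream code exclude cross-run transitions and restart
    HMM forward recursions at each run's first volume.
    """
    if not runs:
        raise IncompatibleRunsError("no runs to concatenate")
    ref = runs[0]
    for r in runs[1:]:
        if r.parcel_labels != ref.parcel_labels:
            raise IncompatibleRunsError("runs have different parcel labels/ordering")
        if r.tr != ref.tr:
            raise IncompatibleRunsError("runs have different TRs")
    boundaries, offset = [], 0
    for r in runs:
        boundaries.append(offset)
        offset += r.n_timepoints
    return np.vstack([r.values for r in runs]), boundaries


def canonical_hrf(
    tr: float,
    duration: float = 32.0,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel sampled at ``tr``.

    h(t) = Γpdf(t; 6, 1) − Γpdf(t; 16, 1)/6 on t ∈ [0, duration), scaled to a
    unit peak.  The response mode sits at 5 s with the post-stimulus
    undershoot near 15 s, the standard shape used to project behavioral
    events onto BOLD dynamics.  The kernel is causal: it has no support
    before t = 0.
    """
    if tr <= 0:
        raise DataFormatError("tr must be positive")
    if duration < 16:
        raise DataFormatError("duration must cover at least 16 s of the response")
    t = np.arange(0.0, duration, tr)
    h = _stats.gamma.pdf(t, peak_shape) - undershoot_ratio * _stats.gamma.pdf(
        t, undershoot_shape
    )
    return h / np.max(h)


def hrf_convolve(trace: BehavioralTrace, duration: float = 32.0) -> BehavioralTrace:
    """Convolve a behavioral trace with the canonical HRF (output length = T)."""
    if trace.hrf_convolved:
        raise ValueError("trace is already HRF-convolved; refusing to convolve twice")
    kernel = canonical_hrf(trace.tr, duration)
    out = np.convolve(trace.values, kernel)[: trace.values.size]
    return BehavioralTrace(out, tr=trace.tr, kind=trace.kind, hrf_convolved=True)


def _fill_nans_linear(x: np.ndarray) -> np.ndarray:
    """1-D linear interpolation over NaN gaps; edges take the nearest valid value."""
    x = x.astype(float).copy()
    ok = np.isfinite(x)
    if ok.sum() == 0:
        raise DegenerateDataError("all trials missing")
    idx = np.arange(x.size)
    x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x


def rt_variability_trace(
    rts,
    trial_duration: float,
    tr: float,
    invert: bool = True,
    n_trs: int | None = None,
) -> BehavioralTrace:
    """Per-trial response times → TR-resolution attention proxy.

    Pipeline: missing/incorrect trials (NaN) filled by 1-D linear
    interpolation (edges: nearest valid value) → linear detrend → RT
    variability = absolute deviation from the post-detrend mean → linear
    resampling from the trial grid onto the TR grid when trial_duration ≠ tr
    → the subject's mean RT variability prepended as the first-TR value →
    z-normalized → sign-inverted when ``invert`` (so larger = more attentive).
    """
    rts = np.asarray(rts, dtype=float).ravel()
    if np.isfinite(rts).sum() < 2:
        raise DegenerateDataError("need at least two non-missing trials")
    filled = _fill_nans_linear(rts)
    detrended = _signal.detrend(filled, type="linear")
    deviance = np.abs(detrended - detrended.mean())

    if trial_duration != tr:
        trial_times = np.arange(deviance.size) * trial_duration
        if n_trs is None:
            n_out = int(np.floor(trial_times[-1] / tr)) + 1
        else:
            n_out = n_trs - 1  # one slot reserved for the prepended mean
        tr_times = np.arange(n_out) * tr
        deviance = np.interp(tr_times, trial_times, deviance)
    elif n_trs is not None:
        deviance = deviance[: n_trs - 1]

    series = np.concatenate([[deviance.mean()], deviance])
    sd = series.std(ddof=1)
    if sd <= 1e-12:
        raise DegenerateDataError("RT variability is constant; cannot z-normalize")
    z = (series - series.mean()) / sd
    if invert:
        z = -z
    return BehavioralTrace(
        z, tr=tr, kind="rt_variability_inverted" if invert else "rt_variability"
    )
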