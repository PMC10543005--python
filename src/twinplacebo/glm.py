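"""Minimal first-level GLM for the pain task runs.

Builds the run-level design matrix — 12 stimulus-condition regressors
(3 levels x 2 modalities x 2 treatment conditions), 4 cue regressors, one
rating regressor, all convolved with a canonical double-gamma HRF — plus a
cosine high-pass drift basis, a 24-column motion block, an optional mean-CSF
column, and one indicator column per censored frame (the first frames of the
run and detected signal spikes).  Betas are then estimated per voxel by
ordinary least squares.

Conventions:

* HRF: SPM-style double gamma (response peak 6, undershoot 16, unit
  dispersions, peak/undershoot ratio 6, 32 s support), sampled at the TR and
  normalized to unit peak.
* High-pass: discrete cosine basis with cutoff *period* 180 s (0.0056 Hz).
* Censoring by indicator columns, which is numerically equivalent to
  deleting the censored rows from the fit but keeps a single solve.
* Spike detection: robust z (median/MAD) of the global mean signal; this is
  a documented, configurable stand-in for a scanner-specific detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "GLMConfig",
    "STIMULUS_LABELS",
    "CUE_LABELS",
    "canonical_hrf",
    "build_design_matrix",
    "detect_spikes",
    "fit_glm",
    "read_events",
]

#: the 12 stimulus conditions of the 3 x 2 x 2 factorial
STIMULUS_LABELS = [
    f"stim_{m}_{c}_{l}"
    for m in ("thermal", "mechanical")
    for c in ("control", "placebo")
    for l in ("low", "medium", "high")
]
CUE_LABELS = [f"cue_{m}_{c}" for m in ("thermal", "mechanical") for c in ("control", "placebo")]
RATING_LABEL = "rating"


@dataclass(frozen=True)
class GLMConfig:
    tr: float = 0.46
    n_volumes: int = 550
    drift_cutoff: float = 180.0  # seconds (high-pass cutoff period)
    n_censor_lead: int = 8
    hrf_peak: float = 6.0
    hrf_undershoot: float = 16.0
    hrf_ratio: float = 6.0
    hrf_length: float = 32.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.drift_cutoff <= 2 * self.tr:
            raise ValueError("drift_cutoff must exceed 2*tr")
        if self.n_censor_lead < 0:
            raise ValueError("n_censor_lead must be >= 0")


def canonical_hrf(config: GLMConfig, dt: float | None = None) -> np.ndarray:
    """Double-gamma impulse response sampled at ``dt`` (default the TR).

    h(t) = Gamma(peak, 1).pdf(t) - Gamma(undershoot, 1).pdf(t) / ratio,
    normalized to unit peak; h(0) = 0 because both shapes exceed 1.
    """
    dt = config.tr if dt is None else dt
    t = np.arange(0.0, config.hrf_length + dt / 2, dt)
    h = gamma_dist.pdf(t, config.hrf_peak) - gamma_dist.pdf(t, config.hrf_undershoot) / config.hrf_ratio
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF parameters")
    return h / peak


def _cosine_drift(config: GLMConfig) -> np.ndarray:
    """Discrete cosine high-pass basis up to frequency 1/drift_cutoff.

    The number of columns is floor(2 * T / cutoff) for a run of duration
    T = n_volumes * tr (the k-th basis function has k half-cycles).
    """
    n = config.n_volumes
    duration = n * config.tr
    n_basis = int(np.floor(2.0 * duration / config.drift_cutoff))
    v = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * v + 1) / (2.0 * n))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _convolved_regressor(
    events: pd.DataFrame, label: str, config: GLMConfig, hrf: np.ndarray
) -> np.ndarray:
    """Boxcar for one label on the volume grid, convolved with the HRF."""
    box = np.zeros(config.n_volumes)
    sel = events[events["trial_type"] == label]
    for onset, duration in zip(sel["onset"], sel["duration"]):
        lo = int(np.floor(onset / config.tr))
        hi = int(np.ceil((onset + duration) / config.tr))
        box[lo : min(hi, config.n_volumes)] = 1.0
    return np.convolve(box, hrf)[: config.n_volumes]


def _validate_events(events: pd.DataFrame, config: GLMConfig) -> None:
    run_end = config.n_volumes * config.tr
    if (events["onset"] < 0).any() or (events["onset"] > run_end).any():
        raise ValueError("event onsets must lie within the run")
    if (events["duration"] <= 0).any():
        raise ValueError("event durations must be positive")
    for label, sub in events.groupby("trial_type"):
        sub = sub.sort_values("onset")
        ends = (sub["onset"] + sub["duration"]).to_numpy()[:-1]
        starts = sub["onset"].to_numpy()[1:]
        if np.any(starts < ends - 1e-9):
            raise ValueError(f"overlapping events with identical label {label!r}")


def build_design_matrix(
    events: pd.DataFrame,
    config: GLMConfig,
    motion: np.ndarray | None = None,
    spike_frames: np.ndarray | None = None,
    csf: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the full first-level design matrix and its column legend.

    ``events`` needs columns onset, duration, trial_type; one HRF-convolved
    task column is emitted per label actually present (out of the 12
    stimulus labels, 4 cue labels and the rating label), followed by an
    intercept, the cosine drift basis, the motion block, the optional mean
    CSF column, and one one-hot indicator per censored frame (lead frames
    union spikes).
    """
    if events.empty:
        events = pd.DataFrame(columns=["onset", "duration", "trial_type"])
    else:
        _validate_events(events, config)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != config.n_volumes:
            raise ValueError("motion block row count must equal n_volumes")

    hrf = canonical_hrf(config)
    columns: list[np.ndarray] = []
    names: list[str] = []

    present = set(events["trial_type"]) if len(events) else set()
    for label in [*STIMULUS_LABELS, *CUE_LABELS, RATING_LABEL]:
        if label in present:
            columns.append(_convolved_regressor(events, label, config, hrf))
            names.append(label)

    unknown = present - set(STIMULUS_LABELS) - set(CUE_LABELS) - {RATING_LABEL}
    if unknown:
        raise ValueError(f"unknown event labels: {sorted(unknown)}")

    columns.append(np.ones(config.n_volumes))
    names.append("intercept")

    drift = _cosine_drift(config)
    for k in range(drift.shape[1]):
        columns.append(drift[:, k])
        names.append(f"drift_cos{k + 1}")

    if motion is not None:
        for k in range(motion.shape[1]):
            columns.append(motion[:, k])
            names.append(f"motion_{k + 1}")
    if csf is not None:
        csf = np.asarray(csf, dtype=float)
        if csf.shape[0] != config.n_volumes:
            raise ValueError("csf regressor length must equal n_volumes")
        columns.append(csf)
        names.append("csf_mean")

    censored = set(range(config.n_censor_lead))
    if spike_frames is not None:
        censored |= {int(f) for f in np.asarray(spike_frames).ravel()}
    for frame in sorted(censored):
        if frame >= config.n_volumes:
            raise ValueError(f"censor frame {frame} outside the run")
        ind = np.zeros(config.n_volumes)
        ind[frame] = 1.0
        columns.append(ind)
        names.append(f"censor_{frame}")

    return np.column_stack(columns), names


def detect_spikes(data: np.ndarray, z_threshold: float = 3.5) -> np.ndarray:
    """Frames whose global-mean robust z (median/MAD) exceeds the threshold.

    Stand-in for a scanner-specific spike detector; configurable threshold,
    default 3.5.  A constant global signal (MAD = 0) yields no spikes and a
    warning.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 10:
        raise ValueError("need a voxels x time matrix with at least 10 frames")
    g = data.mean(axis=0)
    med = np.median(g)
    mad = np.median(np.abs(g - med))
    if mad == 0:
        warnings.warn("global signal has zero MAD; no spikes detectable", stacklevel=2)
        return np.empty(0, dtype=int)
    z = (g - med) / (1.4826 * mad)
    return np.flatnonzero(np.abs(z) > z_threshold)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns involved in a rank deficiency (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)]
    bad = list(bad) + list(piv[len(diag):])
    return [names[i] for i in sorted(bad)]


@dataclass
class GLMFit:
    betas: np.ndarray            # voxels x columns
    residual_variance: np.ndarray  # per voxel, df-corrected
    names: list[str] = field(default_factory=list)

    def beta_map(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


def fit_glm(data: np.ndarray, design: np.ndarray, names: list[str] | None = None) -> GLMFit:
    """Per-voxel OLS.  ``data`` is voxels x time; ``design`` is time x p."""
    data = np.asarray(data, dtype=float)
    design = np.asarray(design, dtype=float)
    if data.shape[1] != design.shape[0]:
        raise ValueError("data time dimension must match design rows")
    names = names or [f"col_{i}" for i in range(design.shape[1])]

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")

    betas, _, _, _ = np.linalg.lstsq(design, data.T, rcond=None)
    resid = data.T - design @ betas
    dof = design.shape[0] - design.shape[1]
    rvar = (resid**2).sum(axis=0) / max(dof, 1)
    return GLMFit(betas=betas.T, residual_variance=rvar, names=list(names))


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv (onset, duration, trial_type)."""
    events = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "trial_type"} - set(events.columns)
    if missing:
        raise ValueError(f"events file missing columns {sorted(missing)}")
    return events
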