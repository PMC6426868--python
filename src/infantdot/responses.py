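"""FIR least-squares deconvolution of per-condition responses.

The design matrix holds one lagged onset indicator per condition and lag
(default lags -5..30 s at the 1 Hz analysis rate, one event per stimulus
block).  Ordinary least squares on the unmasked samples yields one response
time course per condition per channel; with non-overlapping epochs and no
noise this reduces exactly to the trigger-locked epoch average.  Responses
are baseline-corrected by subtracting the [-1, 0] s pre-stimulus mean, and
the response magnitude is the mean over the 2-18 s post-onset window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .datagen import ChannelRecording
from .errors import ConfigError, EstimationError


@dataclass
class ResponseSet:
    """Per-condition response time courses on a uniform lag grid.

    ``courses`` maps condition to a (n_lags, n_channels) array; after
    reconstruction channels may be voxels instead.
    """

    lags_s: np.ndarray
    courses: dict[str, np.ndarray]
    n_reps: dict[str, int] = field(default_factory=dict)
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    magnitude_window_s: tuple[float, float] = (2.0, 18.0)
    baseline_corrected: bool = False

    def map(self, fn) -> "ResponseSet":
        """Apply a linear per-course transform (e.g. image reconstruction)."""
        return ResponseSet(
            lags_s=self.lags_s.copy(),
            courses={c: fn(v) for c, v in self.courses.items()},
            n_reps=dict(self.n_reps),
            baseline_window_s=self.baseline_window_s,
            magnitude_window_s=self.magnitude_window_s,
            baseline_corrected=self.baseline_corrected,
        )

    def save(self, path) -> None:
        """HDF5 group per condition (lags x channels) with JSON metadata."""
        with h5py.File(path, "w") as f:
            f.create_dataset("lags_s", data=self.lags_s)
            g = f.create_group("courses")
            for cond, arr in self.courses.items():
                g.create_dataset(cond, data=arr)
            meta = {
                "n_reps": self.n_reps,
                "baseline_window_s": list(self.baseline_window_s),
                "magnitude_window_s": list(self.magnitude_window_s),
                "baseline_corrected": self.baseline_corrected,
            }
            f.create_dataset("metadata", data=np.bytes_(json.dumps(meta)))

    @classmethod
    def load(cls, path) -> "ResponseSet":
        with h5py.File(path, "r") as f:
            meta = json.loads(f["metadata"][()].decode())
            return cls(
                lags_s=np.asarray(f["lags_s"]),
                courses={c: np.asarray(v) for c, v in f["courses"].items()},
                n_reps=meta["n_reps"],
                baseline_window_s=tuple(meta["baseline_window_s"]),
                magnitude_window_s=tuple(meta["magnitude_window_s"]),
                baseline_corrected=meta["baseline_corrected"],
            )


def deconvolve_responses(
    rec: ChannelRecording,
    triggers: list[tuple[float, str]] | None = None,
    lag_range_s: tuple[float, float] = (-5.0, 30.0),
    bad_mask: np.ndarray | None = None,
    signal: np.ndarray | None = None,
) -> ResponseSet:
    """FIR-OLS deconvolution of condition responses from log-amplitude.

    ``triggers`` defaults to the recording's own; ``bad_mask`` rows are
    dropped from the fit.  ``signal`` overrides the analyzed channel data
    (default: mean-removed log of the amplitudes, sign-flipped so a local
    absorption/HbT increase yields a positive response under the Rytov
    convention).
    """
    t = rec.times_s
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ConfigError("deconvolution requires a uniform time base; resample first")
    dt = float(dt[0])
    triggers = rec.triggers if triggers is None else triggers
    if signal is None:
        x = np.log(rec.amplitudes)
        y = -(x - x.mean(axis=1, keepdims=True)).T  # (n_t, n_ch)
    else:
        y = np.asarray(signal, float).T

    lags = np.arange(
        int(np.floor(lag_range_s[0] / dt)), int(np.floor(lag_range_s[1] / dt)) + 1
    )
    conditions = sorted({c for _, c in triggers})
    n_t = t.size
    n_lags = lags.size
    # lagged onset indicators plus an intercept absorbing the signal mean
    X = np.zeros((n_t, len(conditions) * n_lags + 1))
    X[:, -1] = 1.0
    n_reps = {}
    for ci, cond in enumerate(conditions):
        onsets = np.array([tt for tt, c in triggers if c == cond])
        n_reps[cond] = onsets.size
        onset_idx = np.rint((onsets - t[0]) / dt).astype(int)
        for li, lag in enumerate(lags):
            rows = onset_idx + lag
            rows = rows[(rows >= 0) & (rows < n_t)]
            X[rows, ci * n_lags + li] += 1.0

    keep = np.ones(n_t, bool) if bad_mask is None else ~np.asarray(bad_mask, bool)
    Xk, yk = X[keep], y[keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < X.shape[1]:
        raise EstimationError(
            f"rank-deficient deconvolution design (rank {rank} < {X.shape[1]}) "
            f"for conditions {conditions}; triggers too coincident or too few samples"
        )
    beta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
    courses = {
        cond: beta[ci * n_lags : (ci + 1) * n_lags] for ci, cond in enumerate(conditions)
    }
    return ResponseSet(lags_s=lags * dt, courses=courses, n_reps=n_reps)


def baseline_correct(responses: ResponseSet) -> ResponseSet:
    """Subtract each course's mean over the [-1, 0] s pre-stimulus window."""
    a, b = responses.baseline_window_s
    sel = (responses.lags_s >= a - 1e-9) & (responses.lags_s <= b + 1e-9)
    if not sel.any():
        raise ConfigError(f"lag range lacks the baseline window [{a}, {b}] s")
    out = responses.map(lambda v: v - v[sel].mean(axis=0, keepdims=True))
    out.baseline_corrected = True
    return out


def window_magnitude(
    responses: ResponseSet, window_s: tuple[float, float] | None = None
) -> dict[str, np.ndarray]:
    """Mean response over the magnitude window (default [2, 18] s), per
    condition and channel; the scalar summary used for all statistics."""
    a, b = window_s or responses.magnitude_window_s
    lags = responses.lags_s
    if a < lags[0] - 1e-9 or b > lags[-1] + 1e-9:
        raise ConfigError(f"window [{a}, {b}] s outside lag range [{lags[0]}, {lags[-1]}] s")
    sel = (lags >= a - 1e-9) & (lags <= b + 1e-9)
    return {cond: v[sel].mean(axis=0) for cond, v in responses.courses.items()}
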