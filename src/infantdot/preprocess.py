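"""Channel-level signal processing.

The processing chain mirrors standard optical-imaging practice for block
designs: resample the irregular native frames to a common 1 Hz base (linear
interpolation), zero-phase bandpass with -3 dB points at 0.007 and 0.2 Hz,
superficial signal regression (SSR) against the mean of the short
(< 12 mm) channels, amplitude-threshold artifact detection at 3.5-7 channel
standard deviations (with an L-curve-knee automatic choice), and exclusion
of stimulus triggers whose epochs overlap flagged samples.  A recording is
included for group analysis only when every condition keeps at least five
artifact-free repetitions.

All steps after resampling operate on log-amplitude, the natural domain of
the Rytov forward model; outputs keep the exponentiated (positive)
amplitude representation so stages compose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .datagen import ChannelRecording
from .errors import ConfigError
from .hemodynamics import CONDITIONS


@dataclass
class PreprocessConfig:
    target_rate_hz: float = 1.0
    band_lo_hz: float = 0.007
    band_hi_hz: float = 0.2
    ssr_sds_mm: float = 12.0
    artifact_k: float | str = "auto"  # in [3.5, 7] or "auto"
    artifact_k_range: tuple[float, float] = (3.5, 7.0)
    min_reps_per_condition: int = 5
    epoch_span_s: tuple[float, float] = (-1.0, 18.0)
    ssr_missing: str = "error"  # or "warn"

    def __post_init__(self):
        nyq = self.target_rate_hz / 2.0
        if not 0 < self.band_lo_hz < self.band_hi_hz < nyq:
            raise ConfigError("need 0 < band_lo < band_hi < Nyquist at the target rate")
        if self.artifact_k != "auto":
            lo, hi = self.artifact_k_range
            if not lo <= float(self.artifact_k) <= hi:
                raise ConfigError(f"artifact_k must be in [{lo}, {hi}] or 'auto'")


def resample_to_common_base(
    rec: ChannelRecording, target_rate_hz: float = 1.0
) -> ChannelRecording:
    """Linear interpolation of every channel onto a shared uniform grid.

    The grid covers the recording span at ``target_rate_hz``; triggers and
    annotations are unchanged.  Upsampling beyond 10x the native rate is
    rejected as a configuration mistake.
    """
    t = rec.times_s
    if t.size < 2:
        raise ConfigError("need at least two samples to resample")
    native_rate = (t.size - 1) / (t[-1] - t[0])
    if target_rate_hz > 10 * native_rate:
        raise ConfigError(
            f"target rate {target_rate_hz} Hz exceeds 10x the native rate {native_rate:.3f} Hz"
        )
    dt = 1.0 / target_rate_hz
    new_t = np.arange(np.ceil(t[0] / dt) * dt, t[-1] + 1e-9, dt)
    new_amp = np.empty((rec.amplitudes.shape[0], new_t.size))
    for i, row in enumerate(rec.amplitudes):
        new_amp[i] = np.interp(new_t, t, row)
    triggers = [(tt, c) for tt, c in rec.triggers if new_t[0] <= tt <= new_t[-1]]
    return rec.copy_with(amplitudes=new_amp, times_s=new_t, triggers=triggers)


def _adjusted_butter(order: int, edge_hz: float, fs: float, btype: str):
    """Butterworth section whose forward-backward gain is -3 dB at the edge.

    filtfilt squares the magnitude response, so the design cutoff is moved
    off the requested edge until the measured |H|^2 at the edge equals
    10^(-3/20).  The cutoff is found by bisection on the digital response
    (the analog-prototype formula is off near Nyquist because of bilinear
    warping).
    """
    target = 10 ** (-3.0 / 20.0)  # amplitude gain after filtfilt

    def gain_at_edge(wc: float) -> float:
        sos = sps.butter(order, wc, btype=btype, fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[2 * np.pi * edge_hz / fs])
        return float(np.abs(h[0]) ** 2)

    lo, hi = edge_hz / 4.0, min(edge_hz * 4.0, 0.499 * fs)
    for _ in range(60):
        wc = 0.5 * (lo + hi)
        g = gain_at_edge(wc)
        # gain at the edge increases with wc for lowpass, decreases for highpass
        if (g < target) == (btype == "lowpass"):
            lo = wc
        else:
            hi = wc
    return sps.butter(order, 0.5 * (lo + hi), btype=btype, fs=fs, output="sos")


def bandpass(
    rec: ChannelRecording,
    lo_hz: float = 0.007,
    hi_hz: float = 0.2,
    order: int = 2,
) -> ChannelRecording:
    """Zero-phase bandpass of log-amplitude with -3 dB points at the edges.

    Implemented as separate forward-backward Butterworth high- and low-pass
    stages with edge-corrected design cutoffs, so the measured -3 dB points
    land on ``lo_hz``/``hi_hz`` and the mid-band gain stays within 5% of 1.
    DC is removed.  Warns when the recording is shorter than ~3 periods of
    the low cutoff.
    """
    t = rec.times_s
    fs = 1.0 / np.median(np.diff(t))
    if (t[-1] - t[0]) < 3.0 / lo_hz:
        warnings.warn(
            f"recording ({t[-1] - t[0]:.0f} s) is shorter than 3 periods of "
            f"{lo_hz} Hz; filter transients may dominate",
            stacklevel=2,
        )
    x = np.log(rec.amplitudes)
    x = x - x.mean(axis=1, keepdims=True)
    sos_hi = _adjusted_butter(order, lo_hz, fs, "highpass")
    sos_lo = _adjusted_butter(order, hi_hz, fs, "lowpass")
    y = sps.sosfiltfilt(sos_hi, x, axis=1)
    y = sps.sosfiltfilt(sos_lo, y, axis=1)
    return rec.copy_with(amplitudes=np.exp(y))


def superficial_signal_regression(
    rec: ChannelRecording, sds_mm: float = 12.0, on_missing: str = "error"
) -> ChannelRecording:
    """Regress the short-channel mean out of every channel.

    The regressor is the average log-amplitude of channels with SDS below
    ``sds_mm``; each channel's least-squares projection onto (intercept,
    regressor) is subtracted, leaving residuals uncorrelated with the
    regressor.  With no short channels, behavior follows ``on_missing``:
    ``"error"`` (default) or ``"warn"`` (mean-centered pass-through).
    """
    sds = rec.sds_mm
    short = sds < sds_mm
    x = np.log(rec.amplitudes)
    if not short.any():
        if on_missing == "error":
            raise ConfigError(f"no channels with SDS < {sds_mm} mm for SSR")
        warnings.warn("no short channels; SSR reduced to mean removal", stacklevel=2)
        g = np.zeros(x.shape[1])
    else:
        g = x[short].mean(axis=0)
    design = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x - (design @ beta).T
    return rec.copy_with(amplitudes=np.exp(resid))


def subtract_stimulus_locked_average(rec: ChannelRecording) -> ChannelRecording:
    """Remove each channel's trigger-locked epoch average from the data.

    Used before artifact thresholding: strong evoked responses would
    otherwise trip the amplitude threshold and reject their own epochs,
    while genuine movement artifacts, being asynchronous to the stimuli,
    are diluted by the across-repetition averaging and survive.
    """
    if not rec.triggers:
        return rec
    t = rec.times_s
    x = np.log(rec.amplitudes)
    resid = x.copy()
    lag_lo, lag_hi, dlag = -5.0, 35.0, 1.0
    lags = np.arange(lag_lo, lag_hi + 1e-9, dlag)
    conditions = sorted({c for _, c in rec.triggers})
    for cond in conditions:
        onsets = [tt for tt, c in rec.triggers if c == cond]
        # average response on the lag grid across repetitions
        acc = np.zeros((x.shape[0], lags.size))
        cnt = np.zeros(lags.size)
        for o in onsets:
            rel = t - o
            sel = (rel >= lag_lo) & (rel <= lag_hi)
            if not sel.any():
                continue
            idx = np.clip(np.rint((rel[sel] - lag_lo) / dlag).astype(int), 0, lags.size - 1)
            np.add.at(acc, (slice(None), idx), x[:, sel])
            np.add.at(cnt, idx, 1.0)
        good = cnt > 0
        avg = np.zeros_like(acc)
        avg[:, good] = acc[:, good] / cnt[good]
        avg -= avg.mean(axis=1, keepdims=True)
        for o in onsets:
            rel = t - o
            sel = (rel >= lag_lo) & (rel <= lag_hi)
            if not sel.any():
                continue
            resid[:, sel] -= np.array(
                [np.interp(rel[sel], lags, avg[ch]) for ch in range(x.shape[0])]
            )
    return rec.copy_with(amplitudes=np.exp(resid))


def _knee_of_curve(k_grid: np.ndarray, counts: np.ndarray) -> float:
    """Knee of the (k, flagged-count) curve: the point farthest from the
    chord joining its endpoints after axis normalization (Kneedle-style)."""
    if counts[0] == counts[-1]:
        return float(k_grid[-1])  # flat curve: most conservative threshold
    kx = (k_grid - k_grid[0]) / (k_grid[-1] - k_grid[0])
    cy = (counts - counts[-1]) / (counts[0] - counts[-1])
    # signed distance below the chord y = 1 - x; the knee maximizes it
    dist = (1.0 - kx) - cy
    return float(k_grid[int(np.argmax(dist))])


def detect_artifacts(
    rec: ChannelRecording,
    k: float | str = "auto",
    external_annotations: list[tuple[float, float, str]] | None = None,
    window_s: float = 25.0,
    k_range: tuple[float, float] = (3.5, 7.0),
) -> tuple[np.ndarray, float]:
    """Bad-sample mask from amplitude thresholding plus external annotations.

    A sample is flagged when any channel's high-pass-filtered log-amplitude
    exceeds ``k`` times that channel's standard deviation, or when it falls
    inside an externally annotated bad interval.  The high-pass is removal
    of a centered ``window_s`` moving average: unlike a recursive filter it
    has no edge transients that would masquerade as artifacts at the
    recording boundaries, and second-scale movement transients pass it
    unattenuated.  Detection is best run on the native frames, before
    interpolation redistributes sample variance.  ``k="auto"`` scans the
    3.5-7 range and picks the curvature knee of the (k, flagged-count)
    curve.  Returns ``(mask, chosen_k)``.
    """
    t = rec.times_s
    dt = float(np.median(np.diff(t)))
    size = max(3, int(round(window_s / dt)) | 1)
    x = np.log(rec.amplitudes)
    hp_signed = x - uniform_filter1d(x, size=size, axis=1, mode="reflect")
    hp = np.abs(hp_signed)
    # robust per-channel scale (MAD-consistent SD): the artifacts being
    # hunted must not inflate their own detection threshold
    med = np.median(hp_signed, axis=1, keepdims=True)
    sd = 1.4826 * np.median(np.abs(hp_signed - med), axis=1, keepdims=True)
    sd[sd == 0] = np.inf

    def threshold_mask(kk: float) -> np.ndarray:
        return (hp > kk * sd).any(axis=0)

    if k == "auto":
        lo, hi = k_range
        k_grid = np.arange(lo, hi + 1e-9, 0.25)
        counts = np.array([threshold_mask(kk).sum() for kk in k_grid], float)
        chosen = _knee_of_curve(k_grid, counts)
    else:
        lo, hi = k_range
        chosen = float(k)
        if not lo <= chosen <= hi:
            raise ConfigError(f"k must be in [{lo}, {hi}] or 'auto'")
    mask = threshold_mask(chosen)

    annotations = list(rec.annotations)
    if external_annotations:
        annotations += list(external_annotations)
    for onset, dur, _label in annotations:
        mask |= (t >= onset) & (t <= onset + dur)
    return mask, chosen


@dataclass
class InclusionVerdict:
    passed: bool
    reps_per_condition: dict[str, int]
    min_reps: int


def exclude_triggers(
    triggers: list[tuple[float, str]],
    mask: np.ndarray,
    times_s: np.ndarray,
    epoch_span_s: tuple[float, float] = (-1.0, 18.0),
    min_reps: int = 5,
    conditions=CONDITIONS,
) -> tuple[list[tuple[float, str]], InclusionVerdict]:
    """Keep triggers whose epochs overlap no flagged sample.

    The recording passes inclusion when every condition retains at least
    ``min_reps`` clean repetitions.
    """
    a, b = epoch_span_s
    retained = []
    for t, cond in triggers:
        overlap = (times_s >= t + a) & (times_s <= t + b)
        if not mask[overlap].any():
            retained.append((t, cond))
    reps = {c: sum(1 for _, cond in retained if cond == c) for c in conditions}
    verdict = InclusionVerdict(
        passed=all(n >= min_reps for n in reps.values()),
        reps_per_condition=reps,
        min_reps=min_reps,
    )
    return retained, verdict


def project_mask(
    mask: np.ndarray, times_from: np.ndarray, times_to: np.ndarray
) -> np.ndarray:
    """Carry a bad-sample mask from one time base to another: a target
    sample is flagged when it falls within one source frame of a flagged
    source sample."""
    frac = np.interp(times_to, times_from, mask.astype(float))
    return frac > 0.2


def preprocess_recording(
    rec: ChannelRecording,
    config: PreprocessConfig | None = None,
    artifact_detection: bool = True,
    ssr: bool = True,
) -> tuple[ChannelRecording, np.ndarray, dict]:
    """Full chain: artifact mask (native frames) -> resample -> bandpass ->
    SSR -> trigger exclusion.

    Returns the processed recording, the bad-sample mask on the resampled
    grid, and a log dict (chosen k, retained triggers, inclusion verdict).
    ``artifact_detection=False`` restricts the mask to annotated intervals
    (useful on noise-free calibration data, where the hemodynamic response
    itself would trip the amplitude threshold); ``ssr=False`` skips the
    superficial regression.
    """
    cfg = config or PreprocessConfig()
    if artifact_detection:
        native_mask, chosen_k = detect_artifacts(
            subtract_stimulus_locked_average(rec),
            cfg.artifact_k,
            k_range=cfg.artifact_k_range,
        )
    else:
        native_mask = np.zeros(rec.times_s.size, bool)
        for onset, dur, _lab in rec.annotations:
            native_mask |= (rec.times_s >= onset) & (rec.times_s <= onset + dur)
        chosen_k = float("nan")
    out = resample_to_common_base(rec, cfg.target_rate_hz)
    mask = project_mask(native_mask, rec.times_s, out.times_s)
    out = bandpass(out, cfg.band_lo_hz, cfg.band_hi_hz)
    if ssr:
        out = superficial_signal_regression(out, cfg.ssr_sds_mm, on_missing=cfg.ssr_missing)
    retained, verdict = exclude_triggers(
        out.triggers, mask, out.times_s, cfg.epoch_span_s, cfg.min_reps_per_condition
    )
    log = {
        "artifact_k": chosen_k,
        "n_flagged_samples": int(mask.sum()),
        "retained_triggers": len(retained),
        "inclusion": verdict,
    }
    return out.copy_with(triggers=retained), mask, log
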