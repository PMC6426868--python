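"""Synthetic channel-data generator.

Known voxel activations are forward-projected through the sensitivity
matrix (Rytov convention: log-amplitude = -J . dmu_a) and combined with the
nuisance structure the preprocessing stage is designed to remove: a shared
superficial/global physiological signal whose coupling grows as the
source-detector separation shrinks, slow drift, an aliased cardiac line,
photon (shot) noise, and movement artifacts with ground-truth annotations.

Amplitudes are generated on the instrument's native ~1.2 s frame grid with
small timing jitter, so resampling to a common 1 Hz base does real work.
Per-channel baseline intensity is 1 (arbitrary units): the instrument this
emulates adjusts detector gain per source-detector pair, so absolute
intensity carries no information and photon noise is modeled directly in
the log domain, increasing with separation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps

from .errors import ParseError, SpecError, ValidationError
from .hemodynamics import CanonicalHRF, HabituationProfile, StimulusSchedule, simulate_response
from .phantom import HeadModel, SensitivityMatrix


@dataclass
class ChannelRecording:
    """Per source-detector-pair amplitude time series with triggers."""

    amplitudes: np.ndarray  # (n_channels, n_times), strictly positive
    times_s: np.ndarray  # (n_times,), strictly increasing
    triggers: list[tuple[float, str]]
    channels: list[tuple[int, int, float]]  # (source, detector, SDS mm)
    wavelength_nm: float = 798.0
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, float))
        self.times_s = np.asarray(self.times_s, float)
        self.validate()

    def validate(self) -> None:
        if self.amplitudes.shape[0] != len(self.channels):
            raise ValidationError(
                f"{self.amplitudes.shape[0]} amplitude rows for {len(self.channels)} channels"
            )
        if self.amplitudes.shape[1] != self.times_s.size:
            raise ValidationError("amplitude columns do not match time samples")
        if not np.all(self.amplitudes > 0):
            raise ValidationError("amplitudes must be strictly positive")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("times must be strictly increasing")
        t0, t1 = self.times_s[0], self.times_s[-1]
        for t, cond in self.triggers:
            if not t0 <= t <= t1:
                raise ValidationError(
                    f"trigger at {t:.2f} s ({cond}) outside recording span [{t0:.2f}, {t1:.2f}]"
                )

    @property
    def sds_mm(self) -> np.ndarray:
        return np.array([c[2] for c in self.channels])

    def copy_with(self, **kw) -> "ChannelRecording":
        fields = dict(
            amplitudes=self.amplitudes,
            times_s=self.times_s,
            triggers=list(self.triggers),
            channels=list(self.channels),
            wavelength_nm=self.wavelength_nm,
            annotations=list(self.annotations),
        )
        fields.update(kw)
        return ChannelRecording(**fields)


@dataclass
class GaussianBlob:
    """Spherical Gaussian activation, peak amplitude in uM HbT at response peak."""

    center_mm: tuple[float, float, float]
    sigma_mm: float
    peak_hbt_um: float


@dataclass
class ActivationSpec:
    """Ground-truth activation and noise structure for one synthetic subject.

    ``activation`` maps condition name to a list of blobs (restricted to GM
    at rasterization).  Noise amplitudes are in log-amplitude units; the
    artifact rate is events per minute with amplitude ``artifact_amp_k``
    times each channel's clean signal SD.
    """

    activation: dict[str, list[GaussianBlob]] = field(default_factory=dict)
    extinction_hbt_per_mm_mM: float = 0.1
    amplitude_scale: float = 1.0  # subject-level response gain
    global_amp: float = 0.0
    global_band_hz: tuple[float, float] = (0.01, 0.1)
    coupling_scale_mm: float = 20.0  # superficial coupling ~ exp(-SDS/scale)
    cardiac_amp: float = 0.0
    cardiac_freq_hz: float = 1.2
    drift_sd: float = 0.0
    shot_noise_sd: float = 0.0
    artifact_rate_per_min: float = 0.0
    artifact_amp_k: float = 10.0
    artifact_duration_s: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "global_amp",
            "cardiac_amp",
            "drift_sd",
            "shot_noise_sd",
            "artifact_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")


def rasterize_activation(
    head: HeadModel, blobs: list[GaussianBlob]
) -> np.ndarray:
    """Voxel HbT map (uM at response peak) for a list of blobs, GM-masked.

    Raises :class:`SpecError` when a blob center falls outside the grid.
    """
    vs = head.voxel_size_mm
    nx, ny, nz = head.grid_shape
    ax = (np.arange(nx) + 0.5) * vs
    ay = (np.arange(ny) + 0.5) * vs
    az = (np.arange(nz) + 0.5) * vs
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    out = np.zeros(head.grid_shape)
    extent = head.extent_mm
    for blob in blobs:
        c = np.asarray(blob.center_mm, float)
        if np.any(c < 0) or np.any(c > extent):
            raise SpecError(f"activation center {tuple(c)} outside grid extent {tuple(extent)}")
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        out += blob.peak_hbt_um * np.exp(-d2 / (2.0 * blob.sigma_mm**2))
    return out * head.mask("gm")


def _band_limited_noise(n: int, fs_hz: float, band_hz, rng) -> np.ndarray:
    """Unit-SD noise band-limited to ``band_hz`` (Hz) at sampling rate fs."""
    white = rng.standard_normal(n)
    nyq = fs_hz / 2.0
    lo, hi = band_hz
    hi = min(hi, 0.95 * nyq)
    if lo >= hi:
        return np.zeros(n)
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(
    head: HeadModel,
    S: SensitivityMatrix,
    schedule: StimulusSchedule,
    spec: ActivationSpec,
    hrf: CanonicalHRF | None = None,
    habituation: HabituationProfile | None = None,
    frame_interval_s: float = 1.2,
    frame_jitter_s: float = 0.04,
    tail_s: float = 40.0,
) -> ChannelRecording:
    """Forward-simulate one recording; bit-identical for identical inputs."""
    if S.grid_shape != head.grid_shape:
        raise SpecError("sensitivity matrix grid does not match the head model")
    hrf = hrf or CanonicalHRF()
    rng = np.random.default_rng(spec.seed)

    duration = schedule.end_s + tail_s
    n_frames = int(duration / frame_interval_s)
    intervals = frame_interval_s + frame_jitter_s * rng.uniform(-1, 1, n_frames)
    times = np.cumsum(intervals) - intervals[0]
    n_ch = len(S.channel_index)
    sds = np.array([c[2] for c in S.channel_index])
    log_amp = np.zeros((n_ch, n_frames))

    # Activation: channel signature (J projection of the voxel map) times the
    # unit-peak HbT time course of each condition, via Beer-Lambert.
    dt_fine = 0.1
    for cond, blobs in spec.activation.items():
        hbt_map_um = rasterize_activation(head, blobs)
        resp = simulate_response(
            schedule, habituation, hrf, dt=dt_fine, condition=cond
        )
        course = resp["hbt"]
        peak = np.abs(course).max()
        if peak == 0:
            continue
        course = np.interp(times, resp["t"], course / peak)
        # uM -> mM -> mu_a (1/mm)
        dmua_map = hbt_map_um * 1e-3 * spec.extinction_hbt_per_mm_mM
        signature = S.forward(dmua_map)  # (n_ch,)
        log_amp -= spec.amplitude_scale * np.outer(signature, course)

    # Shared global/superficial physiology, coupled more strongly into short
    # channels, plus an aliased cardiac line.
    coupling = np.exp(-sds / spec.coupling_scale_mm)
    fs = 1.0 / frame_interval_s
    if spec.global_amp > 0:
        g = spec.global_amp * _band_limited_noise(n_frames, fs, spec.global_band_hz, rng)
        log_amp += np.outer(coupling, g)
    if spec.cardiac_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        card = spec.cardiac_amp * np.sin(2 * np.pi * spec.cardiac_freq_hz * times + phase)
        log_amp += np.outer(coupling, card)

    if spec.drift_sd > 0:
        steps = rng.standard_normal((n_ch, n_frames))
        drift = np.cumsum(steps, axis=1) / np.sqrt(n_frames)
        log_amp += spec.drift_sd * drift

    if spec.shot_noise_sd > 0:
        # photon noise grows with attenuation, i.e. with separation
        sd_ch = spec.shot_noise_sd * (sds / 30.0)
        log_amp += sd_ch[:, None] * rng.standard_normal((n_ch, n_frames))

    annotations: list[tuple[float, float, str]] = []
    if spec.artifact_rate_per_min > 0:
        n_events = rng.poisson(spec.artifact_rate_per_min * duration / 60.0)
        sd_clean = log_amp.std(axis=1)
        sd_clean[sd_clean == 0] = spec.shot_noise_sd or 1e-3
        lo, hi = spec.artifact_duration_s
        for _ in range(n_events):
            onset = float(rng.uniform(0, duration - hi))
            dur = float(rng.uniform(lo, hi))
            sel = (times >= onset) & (times < onset + dur)
            signs = rng.choice([-1.0, 1.0], size=n_ch)
            log_amp[:, sel] += (spec.artifact_amp_k * sd_clean * signs)[:, None]
            annotations.append((onset, dur, "movement"))
        annotations.sort()

    triggers = [(o, c) for o, c in schedule.blocks if times[0] <= o <= times[-1]]
    return ChannelRecording(
        amplitudes=np.exp(log_amp),
        times_s=times,
        triggers=triggers,
        channels=list(S.channel_index),
        wavelength_nm=S.metadata.get("wavelength_nm", 798.0),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Persistence: TSV directory dialect and SNIRF-style HDF5 dialect.
# ---------------------------------------------------------------------------

def write_recording(rec: ChannelRecording, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _write_tsv(rec, path)
    elif dialect == "snirf":
        _write_snirf(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path, dialect: str | None = None) -> ChannelRecording:
    if dialect is None:
        dialect = "tsv" if os.path.isdir(path) else "snirf"
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "snirf":
        return _read_snirf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_tsv(rec: ChannelRecording, path) -> None:
    os.makedirs(path, exist_ok=True)
    names = [f"S{s}-D{d}" for s, d, _ in rec.channels]
    with open(os.path.join(path, "amplitudes.tsv"), "w") as fh:
        fh.write("time_s\t" + "\t".join(names) + "\n")
        for j, t in enumerate(rec.times_s):
            row = "\t".join(repr(float(v)) for v in rec.amplitudes[:, j])
            fh.write(f"{float(t)!r}\t{row}\n")
    with open(os.path.join(path, "channels.tsv"), "w") as fh:
        fh.write("source\tdetector\tsds_mm\twavelength_nm\n")
        for s, d, sds in rec.channels:
            fh.write(f"{s}\t{d}\t{float(sds)!r}\t{float(rec.wavelength_nm)!r}\n")
    with open(os.path.join(path, "triggers.tsv"), "w") as fh:
        fh.write("time_s\tcondition\n")
        for t, c in rec.triggers:
            fh.write(f"{float(t)!r}\t{c}\n")
    with open(os.path.join(path, "annotations.tsv"), "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for o, d, lab in rec.annotations:
            fh.write(f"{float(o)!r}\t{float(d)!r}\t{lab}\n")


def _parse_float(text: str, path, lineno: int, fieldname: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad {fieldname} value {text!r}") from exc


def _read_tsv(path) -> ChannelRecording:
    amp_path = os.path.join(path, "amplitudes.tsv")
    chan_path = os.path.join(path, "channels.tsv")
    channels = []
    wavelength = 798.0
    with open(chan_path) as fh:
        fh.readline()
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{chan_path}:{i}: expected 4 fields, got {len(parts)}")
            channels.append(
                (int(parts[0]), int(parts[1]), _parse_float(parts[2], chan_path, i, "sds_mm"))
            )
            wavelength = _parse_float(parts[3], chan_path, i, "wavelength_nm")
    times, rows = [], []
    with open(amp_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "time_s" or len(header) != len(channels) + 1:
            raise ParseError(f"{amp_path}:1: header does not match channels.tsv")
        for i, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(channels) + 1:
                raise ParseError(f"{amp_path}:{i}: expected {len(channels) + 1} fields")
            times.append(_parse_float(parts[0], amp_path, i, "time_s"))
            rows.append([_parse_float(p, amp_path, i, "amplitude") for p in parts[1:]])
    triggers = []
    with open(os.path.join(path, "triggers.tsv")) as fh:
        fh.readline()
        for i, line in enumerate(fh, start=2):
            t, c = line.rstrip("\n").split("\t")
            triggers.append((float(t), c))
    annotations = []
    annot_path = os.path.join(path, "annotations.tsv")
    if os.path.exists(annot_path):
        with open(annot_path) as fh:
            fh.readline()
            for line in fh:
                o, d, lab = line.rstrip("\n").split("\t")
                annotations.append((float(o), float(d), lab))
    return ChannelRecording(
        amplitudes=np.array(rows).T,
        times_s=np.array(times),
        triggers=triggers,
        channels=channels,
        wavelength_nm=wavelength,
        annotations=annotations,
    )


def _write_snirf(rec: ChannelRecording, path) -> None:
    """SNIRF-style HDF5 layout (continuous-wave amplitude, one wavelength)."""
    conditions = sorted({c for _, c in rec.triggers})
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.amplitudes.T)
        data.create_dataset("time", data=rec.times_s)
        for i, (s, d, sds) in enumerate(rec.channels, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=s + 1)
            ml.create_dataset("detectorIndex", data=d + 1)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("sourceDetectorDistance", data=float(sds))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([rec.wavelength_nm]))
        for k, cond in enumerate(conditions, start=1):
            stim = nirs.create_group(f"stim{k}")
            stim.create_dataset("name", data=np.bytes_(cond))
            onsets = np.array([t for t, c in rec.triggers if c == cond])
            stim.create_dataset(
                "data", data=np.column_stack([onsets, np.full_like(onsets, 11.0), np.ones_like(onsets)])
            )
        if rec.annotations:
            ann = f.create_group("annotations")
            ann.create_dataset("onset_s", data=np.array([a[0] for a in rec.annotations]))
            ann.create_dataset("duration_s", data=np.array([a[1] for a in rec.annotations]))
            ann.create_dataset(
                "label", data=np.array([a[2] for a in rec.annotations], dtype="S32")
            )


def _read_snirf(path) -> ChannelRecording:
    try:
        with h5py.File(path, "r") as f:
            data = f["nirs/data1"]
            amplitudes = np.asarray(data["dataTimeSeries"]).T
            times = np.asarray(data["time"])
            channels = []
            i = 1
            while f"measurementList{i}" in data:
                ml = data[f"measurementList{i}"]
                channels.append(
                    (
                        int(ml["sourceIndex"][()]) - 1,
                        int(ml["detectorIndex"][()]) - 1,
                        float(ml["sourceDetectorDistance"][()]),
                    )
                )
                i += 1
            wavelength = float(np.asarray(f["nirs/probe/wavelengths"])[0])
            triggers = []
            k = 1
            while f"nirs/stim{k}" in f:
                stim = f[f"nirs/stim{k}"]
                name = stim["name"][()].decode()
                for row in np.atleast_2d(np.asarray(stim["data"])):
                    triggers.append((float(row[0]), name))
                k += 1
            triggers.sort()
            annotations = []
            if "annotations" in f:
                ann = f["annotations"]
                annotations = [
                    (float(o), float(d), lab.decode())
                    for o, d, lab in zip(ann["onset_s"], ann["duration_s"], ann["label"])
                ]
    except (KeyError, OSError) as exc:
        raise ParseError(f"cannot parse SNIRF-style file {path}: {exc}") from exc
    return ChannelRecording(
        amplitudes=amplitudes,
        times_s=times,
        triggers=triggers,
        channels=channels,
        wavelength_nm=wavelength,
        annotations=annotations,
    )
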