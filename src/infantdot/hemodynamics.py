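"""Stimulus schedules and habituated canonical hemodynamic responses.

The experiment presents 11 s blocks of four short spoken phrases in one of
four emotional conditions (neutral, happy, angry, sad), separated by rests
randomized between 20 and 30 s.  The neuronal drive is modeled as a boxcar
train: four phrase boxcars per block whose amplitudes decay with a
habituation profile (default 1, 0.6, 0.3, 0.2).  Hemodynamics follow the
adult canonical double-gamma HRF; the HbO2 kernel is the base kernel shifted
by -1 s, the HbR kernel is the base kernel scaled by -1/6, and
HbT = HbO2 + HbR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError

CONDITIONS = ("neutral", "happy", "angry", "sad")


@dataclass
class StimulusSchedule:
    """Block onsets/conditions for one recording session."""

    blocks: list[tuple[float, str]]  # (onset s, condition)
    block_duration_s: float = 11.0
    phrases_per_block: int = 4
    rest_bounds_s: tuple[float, float] = (20.0, 30.0)
    seed: int | None = None

    @property
    def onsets(self) -> np.ndarray:
        return np.array([b[0] for b in self.blocks])

    @property
    def conditions(self) -> list[str]:
        return [b[1] for b in self.blocks]

    @property
    def end_s(self) -> float:
        return max(o for o, _ in self.blocks) + self.block_duration_s

    def condition_onsets(self, condition: str) -> np.ndarray:
        return np.array([o for o, c in self.blocks if c == condition])

    def shifted(self, delta_s: float) -> "StimulusSchedule":
        return replace(self, blocks=[(o + delta_s, c) for o, c in self.blocks])

    def save_tsv(self, path) -> None:
        """BIDS-events-like TSV: onset_s, duration_s, condition."""
        with open(path, "w") as fh:
            fh.write("onset_s\tduration_s\tcondition\n")
            for onset, cond in self.blocks:
                fh.write(f"{onset:.3f}\t{self.block_duration_s:.3f}\t{cond}\n")


def load_schedule_tsv(path) -> StimulusSchedule:
    blocks = []
    dur = 11.0
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("onset_s")
        for line in fh:
            onset, d, cond = line.rstrip("\n").split("\t")
            blocks.append((float(onset), cond))
            dur = float(d)
    return StimulusSchedule(blocks, block_duration_s=dur)


@dataclass
class HabituationProfile:
    """Per-phrase amplitude decay within a block.

    The default (1, 0.6, 0.3, 0.2) encodes strong habituation after the
    first phrase of the train; amplitudes must be non-increasing and the
    phrases must fit inside the block.
    """

    amplitudes: tuple[float, ...] = (1.0, 0.6, 0.3, 0.2)
    phrase_duration_s: float = 2.2
    phrase_gap_s: float = 0.7

    def __post_init__(self):
        amps = tuple(float(a) for a in self.amplitudes)
        if any(b > a for a, b in zip(amps, amps[1:])):
            raise ConfigError("habituation amplitudes must be non-increasing")
        self.amplitudes = amps

    def span_s(self) -> float:
        n = len(self.amplitudes)
        return n * self.phrase_duration_s + (n - 1) * self.phrase_gap_s

    @classmethod
    def none(cls, n_phrases: int = 4, **kw) -> "HabituationProfile":
        """No-habituation variant: every phrase at amplitude 1."""
        return cls(amplitudes=(1.0,) * n_phrases, **kw)


@dataclass
class CanonicalHRF:
    """Adult canonical double-gamma hemodynamic response function.

    Standard defaults: response peak at 6 s, undershoot at 16 s, unit
    dispersions, response:undershoot ratio 6.  The base kernel is normalized
    to unit peak so stimulus amplitudes carry the physical scale.
    """

    response_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    response_undershoot_ratio: float = 6.0
    hbo2_shift_s: float = -1.0
    hbr_scale: float = -1.0 / 6.0
    duration_s: float = 32.0

    def kernel(self, dt: float, shift_s: float = 0.0) -> np.ndarray:
        """Sampled base kernel h(t - shift) on [0, duration), unit peak.

        A negative ``shift_s`` moves the response earlier; mass that would
        fall before t = 0 is truncated (the canonical kernel is ~0 there).
        """
        t = np.arange(0.0, self.duration_s, dt) - shift_s

        def gampdf(x, a, scale):
            x = np.maximum(x, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = (a - 1) * np.log(x / scale) - x / scale - gammaln(a) - np.log(scale)
            out = np.where(x > 0, np.exp(logp), 0.0)
            return out

        a1 = self.response_delay_s / self.response_dispersion
        a2 = self.undershoot_delay_s / self.undershoot_dispersion
        h = gampdf(t, a1, self.response_dispersion) - gampdf(
            t, a2, self.undershoot_dispersion
        ) / self.response_undershoot_ratio
        # normalize by the unshifted kernel's peak so shifts do not rescale
        t0 = np.arange(0.0, self.duration_s, dt)
        h0 = gampdf(t0, a1, self.response_dispersion) - gampdf(
            t0, a2, self.undershoot_dispersion
        ) / self.response_undershoot_ratio
        return h / h0.max()


def make_schedule(
    n_blocks_per_condition: int,
    seed: int | None = 0,
    rest_bounds_s: tuple[float, float] = (20.0, 30.0),
    block_duration_s: float = 11.0,
    initial_rest_s: float = 20.0,
    conditions=CONDITIONS,
) -> StimulusSchedule:
    """Randomized balanced block schedule, reproducible for a fixed seed.

    Every condition appears ``n_blocks_per_condition`` times in shuffled
    order; successive blocks are separated by rests drawn uniformly from
    ``rest_bounds_s``.
    """
    if n_blocks_per_condition < 1:
        raise ConfigError("need at least one block per condition")
    lo, hi = rest_bounds_s
    if lo > hi or lo < 0:
        raise ConfigError("invalid rest bounds")
    rng = np.random.default_rng(seed)
    order = list(conditions) * n_blocks_per_condition
    rng.shuffle(order)
    blocks = []
    t = float(initial_rest_s)
    for cond in order:
        blocks.append((t, cond))
        t += block_duration_s + float(rng.uniform(lo, hi))
    return StimulusSchedule(
        blocks,
        block_duration_s=block_duration_s,
        rest_bounds_s=rest_bounds_s,
        seed=seed,
    )


def neuronal_train(
    schedule: StimulusSchedule,
    habituation: HabituationProfile | None = None,
    dt: float = 0.1,
    duration_s: float | None = None,
    condition: str | None = None,
    mode: str = "phrases",
) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar neuronal drive for a schedule.

    In the default ``phrases`` mode each block contributes four boxcars of
    ``phrase_duration_s`` scaled by the habituation amplitudes; ``block``
    mode uses a single 11 s boxcar of amplitude 1 per block.  Restrict to
    one condition with ``condition``.
    """
    if dt > 0.5:
        raise ConfigError("sampling interval must be <= 0.5 s for convolution accuracy")
    hab = habituation or HabituationProfile()
    if mode == "phrases" and hab.span_s() > schedule.block_duration_s + 1e-9:
        raise ConfigError(
            f"phrases span {hab.span_s():.2f} s exceeds the "
            f"{schedule.block_duration_s:.2f} s block"
        )
    if duration_s is None:
        duration_s = schedule.end_s + 40.0
    t = np.arange(0.0, duration_s, dt)
    x = np.zeros_like(t)
    for onset, cond in schedule.blocks:
        if condition is not None and cond != condition:
            continue
        if mode == "block":
            x[(t >= onset) & (t < onset + schedule.block_duration_s)] += 1.0
        else:
            for k, amp in enumerate(hab.amplitudes):
                start = onset + k * (hab.phrase_duration_s + hab.phrase_gap_s)
                x[(t >= start) & (t < start + hab.phrase_duration_s)] += amp
    return t, x


def simulate_response(
    schedule: StimulusSchedule,
    habituation: HabituationProfile | None = None,
    hrf: CanonicalHRF | None = None,
    dt: float = 0.1,
    amplitude: float = 1.0,
    condition: str | None = None,
    mode: str = "phrases",
) -> dict[str, np.ndarray]:
    """Convolve the neuronal train with the canonical HRF.

    Returns ``{"t", "hbo2", "hbr", "hbt"}``; HbO2 uses the kernel shifted by
    ``hbo2_shift_s``, HbR the base kernel scaled by ``hbr_scale``, and
    HbT = HbO2 + HbR pointwise.  ``amplitude`` scales all outputs.
    """
    hrf = hrf or CanonicalHRF()
    t, x = neuronal_train(schedule, habituation, dt=dt, condition=condition, mode=mode)
    k_base = hrf.kernel(dt)
    k_shift = hrf.kernel(dt, shift_s=hrf.hbo2_shift_s)
    hbo2 = amplitude * np.convolve(x, k_shift)[: t.size] * dt
    hbr = amplitude * hrf.hbr_scale * np.convolve(x, k_base)[: t.size] * dt
    return {"t": t, "hbo2": hbo2, "hbr": hbr, "hbt": hbo2 + hbr}
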