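"""Synthetic multichannel EEG with injectable ERP ground truth.

A simulated recording is the sum of

* spatially independent 1/f^alpha background noise on every channel,
* parametric event-related kernels (Gaussian bumps with a fronto-central
  scalp gain map) added at stimulus latencies — an obligatory N50/P130
  complex on every sound, a statistical mismatch negativity (sMMN) on
  low-transition-probability endings, and a location MMN on endings from
  the deviant loudspeaker (double deviants receive both, additively),
* blink artifacts (400 ms raised cosine on the vertical EOG, propagated
  with decaying gain into the frontal rows).

The recording emulates a left-mastoid-referenced acquisition: the stored
signal of every channel is its scalp potential minus the left-mastoid
trace, so downstream re-referencing to the mastoid mean is meaningful.

Kernel injection is linear in the ground-truth amplitudes, and all random
draws are consumed in a parameter-independent order, so recordings that
share a seed differ only by the injected components.  This makes the
generator suitable for parameter-recovery validation of the full
preprocessing and statistics chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from tripletmmn import paradigm

__all__ = [
    "MontageSpec",
    "ErpGroundTruth",
    "ErpComponent",
    "NoiseSpec",
    "RawRecording",
    "SubjectData",
    "default_montage",
    "simulate_subject",
    "simulate_cohort",
    "iter_cohort",
]

_ROI_MAP = {
    "frontal_left": ["F7", "F5", "F3", "FT7", "FC5", "FC3"],
    "frontal_middle": ["F1", "FZ", "F2", "FC1", "FCZ", "FC2"],
    "frontal_right": ["F8", "F6", "F4", "FT8", "FC6", "FC4"],
    "central_left": ["T7", "C5", "C3", "TP7", "CP5", "CP3"],
    "central_middle": ["C1", "CZ", "C2", "CPZ"],
    "central_right": ["T8", "C6", "C4", "TP8", "CP6", "CP4"],
    "parietal_left": ["P7", "P5", "P3", "PO7", "PO3", "O1"],
    "parietal_middle": ["P1", "PZ", "P2", "POZ", "OZ"],
    "parietal_right": ["P8", "P6", "P4", "PO8", "PO4", "O2"],
}

# 59 scalp electrodes (10-10): the 51 ROI electrodes plus a prefrontal row
# that is not analysed but carries blink artifacts.
_EXTRA_SCALP = ["FP1", "FPZ", "FP2", "AF7", "AF3", "AFZ", "AF4", "AF8"]
_SCALP = [ch for roi in _ROI_MAP.values() for ch in roi] + _EXTRA_SCALP

_EOG = ["HEOG_L", "HEOG_R", "VEOG_LO", "VEOG_UP"]


@dataclass(frozen=True)
class MontageSpec:
    """Channel layout: 59 scalp electrodes (10-10), mastoids (left one the
    recording reference), four EOG channels, and the nine analysis ROIs."""

    scalp_channels: tuple[str, ...] = tuple(_SCALP)
    reference: str = "M1"
    mastoid: str = "M2"
    eog: tuple[str, ...] = tuple(_EOG)
    sampling_rate: float = 500.0
    roi_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _ROI_MAP.items()}
    )

    def __post_init__(self) -> None:
        if len(self.scalp_channels) != 59:
            raise ValueError("montage must define 59 scalp channels")
        seen: set[str] = set()
        for roi, chans in self.roi_map.items():
            for ch in chans:
                if ch not in self.scalp_channels:
                    raise ValueError(f"ROI {roi} electrode {ch} not in montage")
                if ch in seen:
                    raise ValueError(f"electrode {ch} appears in two ROIs")
                seen.add(ch)

    @property
    def channels(self) -> list[str]:
        """Recorded channel order: scalp, mastoid M2, EOG."""
        return list(self.scalp_channels) + [self.mastoid] + list(self.eog)

    def index(self, name: str) -> int:
        return self.channels.index(name)


def default_montage() -> MontageSpec:
    return MontageSpec()


# per-channel gain profiles (fronto-central maximum)
def _frontocentral_gain(left_bias: float = 0.0) -> dict[str, float]:
    base = {
        "frontal_middle": 1.0,
        "frontal_left": 0.8,
        "frontal_right": 0.8,
        "central_middle": 0.9,
        "central_left": 0.65,
        "central_right": 0.65,
        "parietal_middle": 0.45,
        "parietal_left": 0.3,
        "parietal_right": 0.3,
    }
    gains: dict[str, float] = {}
    for roi, chans in _ROI_MAP.items():
        g = base[roi]
        if left_bias:
            if roi.endswith("left"):
                g *= 1.0 + left_bias
            elif roi.endswith("right"):
                g *= 1.0 - left_bias
        for ch in chans:
            gains[ch] = g
    for ch in _EXTRA_SCALP:
        gains[ch] = 0.5
    return gains


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian ERP kernel: ``amp * exp(-(t-latency)^2 / (2 sigma^2))``
    scaled per channel by a scalp gain map."""

    amp: float  # µV at the peak of a unit-gain channel
    latency_ms: float
    sigma_ms: float
    gain: dict[str, float]

    def kernel(self, t_ms: np.ndarray) -> np.ndarray:
        return self.amp * np.exp(-0.5 * ((t_ms - self.latency_ms) / self.sigma_ms) ** 2)

    def window_mean(self, lo_ms: float, hi_ms: float, step_ms: float = 2.0) -> float:
        """Mean kernel value over a latency window on the sample grid."""
        t = np.arange(lo_ms, hi_ms, step_ms)
        return float(self.kernel(t).mean())


@dataclass(frozen=True)
class ErpGroundTruth:
    """Injectable ERP parameters.

    Amplitudes are peak values in µV; MMN components are negative.
    ``smmn_scale``/``locmmn_scale`` multiply the MMN amplitudes per
    presentation mode, encoding the empirical decline of both mismatch
    responses under temporally unpredictable stimulation.
    """

    n50_amp: float = -1.5
    p130_amp: float = 2.0
    smmn_amp: float = -2.0
    locmmn_amp: float = -2.5
    smmn_latency_ms: float = 220.0
    smmn_sigma_ms: float = 25.0
    locmmn_latency_ms: float = 170.0
    locmmn_sigma_ms: float = 20.0
    locmmn_left_bias: float = 0.15
    smmn_scale: dict[str, float] = field(
        default_factory=lambda: {"isochronous": 1.0, "random": 0.15}
    )
    locmmn_scale: dict[str, float] = field(
        default_factory=lambda: {"isochronous": 1.0, "random": 0.6}
    )

    def components_for(self, category: str, mode: str) -> list[ErpComponent]:
        """Kernels elicited by one stimulus of the given ending category
        (``'root'`` and ``'target'`` receive only the obligatory complex)."""
        fc = _frontocentral_gain()
        comps = [
            ErpComponent(self.n50_amp, 50.0, 15.0, fc),
            ErpComponent(self.p130_amp, 130.0, 20.0, fc),
        ]
        if category in ("stat_deviant", "double_deviant"):
            comps.append(self.smmn_component(mode))
        if category in ("phys_deviant", "double_deviant"):
            comps.append(self.locmmn_component(mode))
        return comps

    def smmn_component(self, mode: str) -> ErpComponent:
        return ErpComponent(
            self.smmn_amp * self.smmn_scale[mode],
            self.smmn_latency_ms,
            self.smmn_sigma_ms,
            _frontocentral_gain(),
        )

    def locmmn_component(self, mode: str) -> ErpComponent:
        return ErpComponent(
            self.locmmn_amp * self.locmmn_scale[mode],
            self.locmmn_latency_ms,
            self.locmmn_sigma_ms,
            _frontocentral_gain(self.locmmn_left_bias),
        )

    def predicted_roi_window_effect(
        self,
        component: ErpComponent,
        window_ms: tuple[float, float],
        montage: MontageSpec,
    ) -> dict[str, float]:
        """Ground-truth deviant-minus-standard window mean per ROI (µV)."""
        wm = component.window_mean(*window_ms)
        out = {}
        for roi, chans in montage.roi_map.items():
            out[roi] = wm * float(np.mean([component.gain[c] for c in chans]))
        return out

    def scaled(self, factor: float) -> "ErpGroundTruth":
        return replace(
            self,
            n50_amp=self.n50_amp * factor,
            p130_amp=self.p130_amp * factor,
            smmn_amp=self.smmn_amp * factor,
            locmmn_amp=self.locmmn_amp * factor,
        )

    @classmethod
    def zero(cls) -> "ErpGroundTruth":
        return cls(n50_amp=0.0, p130_amp=0.0, smmn_amp=0.0, locmmn_amp=0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Background and artifact model.

    ``background_sd`` is the per-channel standard deviation (µV) of the
    1/f^``spectral_exponent`` noise; blinks occur at ``blink_rate`` per
    minute with peak ``blink_amp`` µV on the vertical EOG.
    """

    background_sd: float = 8.0
    spectral_exponent: float = 1.0
    blink_rate: float = 4.0
    blink_amp: float = 150.0

    def __post_init__(self) -> None:
        if min(self.background_sd, self.blink_rate, self.blink_amp) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.spectral_exponent < 0:
            raise ValueError("spectral exponent must be non-negative")


@dataclass
class RawRecording:
    """Continuous recording: channels × samples in µV, plus stimulus and
    button-press annotations with sample indices."""

    data: np.ndarray
    montage: MontageSpec
    annotations: pd.DataFrame  # stimulus events, incl. 'sample' column
    presses: pd.DataFrame  # button presses, 'sample' column
    reference_state: str = "as_recorded"  # or 'mastoid_mean'

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.montage.channels):
            raise ValueError("data rows must match montage channels")
        n = self.data.shape[1]
        if len(self.annotations) and (
            self.annotations["sample"].min() < 0 or self.annotations["sample"].max() >= n
        ):
            raise ValueError("annotation sample index outside record")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(),
            self.montage,
            self.annotations.copy(),
            self.presses.copy(),
            self.reference_state,
        )


@dataclass
class SubjectData:
    """One simulated participant."""

    subject: int
    mode: str
    events: pd.DataFrame
    presses: pd.DataFrame
    recording: RawRecording
    permutation: paradigm.SoundPermutation


_BLINK_PROPAGATION = {"FP": 0.4, "AF": 0.25, "F": 0.15, "FC": 0.08}


def _blink_gain(ch: str) -> float:
    for prefix in ("FP", "AF", "FC", "FT"):
        if ch.startswith(prefix):
            return _BLINK_PROPAGATION.get(prefix, 0.0)
    if ch.startswith("F"):
        return _BLINK_PROPAGATION["F"]
    return 0.0


def _pink_noise(
    rng: np.random.Generator, n_ch: int, n_samp: int, sd: float, alpha: float, fs: float
) -> np.ndarray:
    """Spatially independent 1/f^alpha noise, unit-scaled to ``sd`` µV.

    Computed in single precision (spectral shaping of white noise);
    adequate for µV-scale signals and considerably faster.
    """
    from scipy import fft as sfft

    white = rng.standard_normal((n_ch, n_samp), dtype=np.float32)
    if alpha == 0.0:
        return white * np.float32(sd)
    spec = sfft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    f[0] = f[1]  # keep DC finite
    scale = (f ** (-alpha / 2.0)).astype(np.float32)
    colored = sfft.irfft(spec * scale, n=n_samp, axis=1)
    colored /= colored.std(axis=1, keepdims=True) + np.float32(1e-30)
    return colored * np.float32(sd)


def simulate_subject(
    events: pd.DataFrame,
    truth: ErpGroundTruth,
    noise: NoiseSpec,
    montage: MontageSpec,
    rng: np.random.Generator,
    mode: str = "random",
    presses: pd.DataFrame | None = None,
    pad_ms: float = 2000.0,
) -> RawRecording:
    """Render an event stream into a continuous left-mastoid-referenced
    recording with injected ERP ground truth.

    Random draws (background noise, blink times) are consumed in an order
    independent of the ground-truth amplitudes, so two calls with the same
    seed differ only by the injected kernels.
    """
    if not events["onset_ms"].is_monotonic_increasing:
        raise ValueError("events must be sorted by onset")
    fs = montage.sampling_rate
    step_ms = 1000.0 / fs
    chans = montage.channels
    n_ch = len(chans)
    t_end = float(events["onset_ms"].iloc[-1]) + pad_ms
    n_samp = int(np.ceil((t_end + pad_ms) / step_ms))

    # background noise for the recorded channels plus the (unstored) M1
    # reference; referencing subtracts the M1 trace from every channel
    full = _pink_noise(
        rng, n_ch + 1, n_samp, noise.background_sd, noise.spectral_exponent, fs
    )
    data = full[:n_ch] - full[n_ch]

    # blink artifacts
    dur = int(round(0.4 * fs))  # 400 ms raised cosine
    blink_wave = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(dur) / dur))
    n_blinks = rng.poisson(noise.blink_rate * (n_samp / fs) / 60.0)
    blink_starts = np.sort(rng.integers(0, max(1, n_samp - dur), size=n_blinks))
    gains = np.zeros(n_ch, dtype=np.float32)
    for i, ch in enumerate(chans):
        gains[i] = _blink_gain(ch)
    gains[montage.index("VEOG_UP")] = 1.0
    gains[montage.index("VEOG_LO")] = -0.5
    for s in blink_starts:
        data[:, s : s + dur] += (
            noise.blink_amp * gains[:, None] * blink_wave[None, : n_samp - s]
        ).astype(np.float32)

    # ERP kernels (scalp channels only; scalp rows come first)
    n_scalp = len(montage.scalp_channels)
    samples = np.round((events["onset_ms"].to_numpy() + pad_ms) / step_ms).astype(int)
    kern_t = np.arange(0.0, 400.0, step_ms)  # kernel support, 0–400 ms post-onset
    cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for cat in events["category"].unique():
        comps = truth.components_for(cat, mode)
        waves = []
        for c in comps:
            if c.amp == 0.0:
                continue
            g = np.array([c.gain[ch] for ch in montage.scalp_channels], dtype=np.float32)
            waves.append((g, c.kernel(kern_t).astype(np.float32)))
        cache[cat] = waves
    for s, cat in zip(samples, events["category"]):
        for g, w in cache[cat]:
            end = min(n_samp, s + len(w))
            data[:n_scalp, s:end] += g[:, None] * w[None, : end - s]

    ann = events.copy()
    ann["sample"] = samples
    if presses is None:
        presses = pd.DataFrame(columns=["press_time_ms", "target_onset_ms"])
    pr = presses.copy()
    pr["sample"] = np.round((pr["press_time_ms"].to_numpy(dtype=float) + pad_ms) / step_ms).astype(int)
    return RawRecording(data, montage, ann, pr, "as_recorded")


def _subject_seed(master: int, mode: str, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=(0 if mode == "isochronous" else 1, subject))


def iter_cohort(
    n_subjects: int,
    mode: str,
    cfg: paradigm.StreamConfig,
    tt: paradigm.TransitionTable,
    truth: ErpGroundTruth,
    noise: NoiseSpec,
    montage: MontageSpec,
    master_seed: int,
    target_hit_rate: float = 0.979,
) -> Iterator[SubjectData]:
    """Lazily simulate a cohort, one subject at a time.

    Each subject gets an independent seed derived from the master seed, a
    fresh sound-label permutation, and an alternating standard side
    (counterbalanced across participants).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if mode not in ("isochronous", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    for i in range(n_subjects):
        rng = np.random.default_rng(_subject_seed(master_seed, mode, i))
        perm = paradigm.SoundPermutation.random(rng)
        side = "left" if i % 2 == 0 else "right"
        sub_cfg = replace(cfg, standard_side_first_block=side)
        events = paradigm.generate_stream(sub_cfg, tt, rng)
        if sub_cfg.target_rate_per_min > 0:
            events, presses = paradigm.insert_targets_and_presses(
                events, sub_cfg, rng, hit_rate=target_hit_rate
            )
        else:
            presses = pd.DataFrame(columns=["press_time_ms", "target_onset_ms"])
        rec = simulate_subject(events, truth, noise, montage, rng, mode=mode, presses=presses)
        yield SubjectData(i, mode, events, presses, rec, perm)


def simulate_cohort(*args, **kwargs) -> list[SubjectData]:
    """Eager version of :func:`iter_cohort` (suitable for small cohorts)."""
    return list(iter_cohort(*args, **kwargs))
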