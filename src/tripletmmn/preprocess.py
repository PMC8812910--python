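"""Preprocessing chain: raw recording → condition-labelled epochs → ROI
waveforms.

The chain mirrors standard mismatch-negativity practice:

1. re-reference to the algebraic mean of the two mastoids,
2. zero-phase 30 Hz low-pass FIR (2750 taps, Blackman window),
3. sample rejection wherever the within-channel standard deviation in a
   200 ms *or* 800 ms gliding window exceeds 25 µV on any channel
   (EOG included),
4. epoching of triplet-ending events from −100 to +400 ms with a 100 ms
   pre-stimulus baseline, excluding epochs (precedence in this order)
   within 3 s after a target sound or button press, closer than 200 ms to
   an adjacent stimulus onset, or overlapping rejected samples,
5. averaging per condition and electrode cluster (nine ROIs).

Gliding windows advance sample by sample; both window lengths are applied
independently and OR-combined.  Standard deviations use the unbiased
(n−1) estimator per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from tripletmmn.erp_stats import group_blocks
from tripletmmn.synth_eeg import MontageSpec, RawRecording

__all__ = [
    "lowpass_fir",
    "design_lowpass",
    "rereference_mastoid_mean",
    "gliding_window_reject",
    "screen_bad_channels",
    "EpochSet",
    "extract_epochs",
    "roi_waveforms",
]

ENDING_CATEGORIES = ("standard", "stat_deviant", "phys_deviant", "double_deviant")


def design_lowpass(
    cutoff_hz: float = 30.0,
    taps: int = 2750,
    fs: float = 500.0,
    window: str = "blackman",
) -> np.ndarray:
    """FIR low-pass coefficients (linear phase)."""
    return signal.firwin(taps, cutoff_hz, fs=fs, window=window, pass_zero=True)


def lowpass_fir(
    rec: RawRecording,
    cutoff_hz: float = 30.0,
    taps: int = 2750,
    window: str = "blackman",
) -> RawRecording:
    """Zero-phase low-pass filter of every channel.

    The linear-phase design is applied forward and backward (via its
    autocorrelation kernel), which cancels the group delay exactly for any
    tap parity; the effective magnitude response is the square of the
    single-pass design.
    """
    if rec.n_samples < taps:
        raise ValueError(
            f"record of {rec.n_samples} samples is shorter than the {taps}-tap filter"
        )
    h = design_lowpass(cutoff_hz, taps, rec.montage.sampling_rate, window)
    h2 = np.convolve(h, h[::-1])  # symmetric, zero phase, odd length
    out = rec.copy()
    out.data = _fft_filter_same(rec.data, h2).astype(rec.data.dtype)
    return out


def _fft_filter_same(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-mode convolution of (channels × samples) with an odd
    symmetric kernel, via a single real FFT in working precision matched
    to the data (float32 in, float32 maths)."""
    from scipy import fft as sfft

    n = data.shape[1]
    m = len(kernel)
    nfft = sfft.next_fast_len(n + m - 1, real=True)
    dtype = np.float32 if data.dtype == np.float32 else np.float64
    kf = sfft.rfft(kernel.astype(dtype), n=nfft)
    df = sfft.rfft(data.astype(dtype, copy=False), n=nfft, axis=1)
    full = sfft.irfft(df * kf[None, :], n=nfft, axis=1)
    start = (m - 1) // 2
    return full[:, start : start + n]


def rereference_mastoid_mean(rec: RawRecording) -> RawRecording:
    """Re-reference from the recorded left mastoid to the mastoid mean.

    With M1 as recording reference, every stored channel is ``v − v_M1``;
    subtracting half of the stored M2 trace converts all channels to the
    (M1+M2)/2 reference.  Re-running on an already re-referenced record is
    an error.
    """
    if rec.reference_state != "as_recorded":
        raise ValueError(
            f"record is already re-referenced (state={rec.reference_state!r})"
        )
    out = rec.copy()
    m2 = rec.data[rec.montage.index(rec.montage.mastoid)].copy()
    out.data = rec.data - 0.5 * m2[None, :]
    out.reference_state = "mastoid_mean"
    return out


try:  # single-pass running-sum kernel; falls back to numpy if numba absent
    import numba

    @numba.njit(cache=False)
    def _rolling_viol_kernel(x, win, thr2_scaled, viol):  # pragma: no cover
        n_ch, n = x.shape
        for c in range(n_ch):
            s = 0.0
            s2 = 0.0
            for i in range(win):
                v = np.float64(x[c, i])
                s += v
                s2 += v * v
            if s2 - s * s / win > thr2_scaled:
                viol[0] = True
            for start in range(1, n - win + 1):
                v_old = np.float64(x[c, start - 1])
                v_new = np.float64(x[c, start + win - 1])
                s += v_new - v_old
                s2 += v_new * v_new - v_old * v_old
                if s2 - s * s / win > thr2_scaled:
                    viol[start] = True

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _rolling_sd_exceeds(data: np.ndarray, win: int, threshold: float) -> np.ndarray:
    """Boolean per window start: does any channel's SD (ddof=1) exceed
    ``threshold`` within the ``win``-sample window starting there?"""
    n = data.shape[1]
    if win > n:
        return np.zeros(0, dtype=bool)
    thr2_scaled = threshold * threshold * (win - 1)
    if _HAVE_NUMBA:
        viol = np.zeros(n - win + 1, dtype=np.bool_)
        _rolling_viol_kernel(np.ascontiguousarray(data), win, thr2_scaled, viol)
        return viol
    x = data.astype(np.float64)
    zeros = np.zeros((x.shape[0], 1))
    c1 = np.concatenate([zeros, np.cumsum(x, axis=1)], axis=1)
    c2 = np.concatenate([zeros, np.cumsum(x * x, axis=1)], axis=1)
    s1 = c1[:, win:] - c1[:, :-win]
    s2 = c2[:, win:] - c2[:, :-win]
    return ((s2 - s1 * s1 / win) > thr2_scaled).any(axis=0)


def gliding_window_reject(
    rec: RawRecording,
    threshold_uv: float = 25.0,
    windows_ms: tuple[float, ...] = (200.0, 800.0),
) -> np.ndarray:
    """Per-sample rejection mask (True = rejected).

    A sample is rejected iff it lies inside at least one gliding-window
    position — of either length, on any channel including EOG — whose
    within-window SD exceeds the threshold.
    """
    fs = rec.montage.sampling_rate
    n = rec.n_samples
    mask = np.zeros(n, dtype=bool)
    if not np.isfinite(threshold_uv):
        return mask
    for wms in windows_ms:
        win = int(round(wms * fs / 1000.0))
        viol = _rolling_sd_exceeds(rec.data, win, threshold_uv)
        starts = np.flatnonzero(viol)
        if len(starts):
            cov = np.zeros(n + 1, dtype=np.int64)
            np.add.at(cov, starts, 1)
            np.add.at(cov, np.minimum(starts + win, n), -1)
            mask |= np.cumsum(cov[:-1]) > 0
    return mask


def screen_bad_channels(
    rec: RawRecording, flat_tol_uv: float = 1e-6, outlier_factor: float = 5.0
) -> list[str]:
    """Automated stand-in for visual channel inspection: flag channels that
    are flat or whose overall SD exceeds ``outlier_factor`` × the median
    channel SD."""
    sds = rec.data.std(axis=1)
    med = np.median(sds[sds > flat_tol_uv]) if np.any(sds > flat_tol_uv) else 0.0
    bad = []
    for ch, sd in zip(rec.montage.channels, sds):
        if sd <= flat_tol_uv or (med > 0 and sd > outlier_factor * med):
            bad.append(ch)
    return bad


@dataclass
class EpochSet:
    """Baseline-corrected event-locked epochs.

    ``data`` is (epochs × channels × samples) over the half-open window
    [−100, 400) ms on the sample grid; ``info`` has one row per epoch
    (category, block, block_group, onset_ms); ``exclusions`` tallies why
    ending events were dropped.
    """

    data: np.ndarray
    info: pd.DataFrame
    montage: MontageSpec
    tmin_ms: float = -100.0
    tmax_ms: float = 400.0
    exclusions: dict = field(default_factory=dict)
    subject: int | None = None

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.montage.sampling_rate
        return np.arange(self.tmin_ms, self.tmax_ms, step)

    def __len__(self) -> int:
        return self.data.shape[0]


def extract_epochs(
    rec: RawRecording,
    mask: np.ndarray,
    tmin_ms: float = -100.0,
    tmax_ms: float = 400.0,
    baseline_ms: float = 100.0,
    post_event_exclusion_ms: float = 3000.0,
    min_adjacent_ms: float = 200.0,
    exclude_after_categories: tuple[str, ...] = ("target",),
    subject: int | None = None,
) -> EpochSet:
    """Epoch all triplet-ending events with the exclusion rules.

    Precedence of exclusions (each event counted once): (1) onset within
    ``post_event_exclusion_ms`` after a button press or an event of
    ``exclude_after_categories`` (default: the cover-task target sounds;
    widen to e.g. ``("target", "phys_deviant", "double_deviant")`` to also
    treat location deviants as exclusion triggers), (2) adjacent stimulus
    onset closer than ``min_adjacent_ms``, (3) any rejected sample inside
    the epoch window.  Surviving epochs are baseline-corrected per channel
    with the mean over [−``baseline_ms``, 0).
    """
    fs = rec.montage.sampling_rate
    step = 1000.0 / fs
    ev = rec.annotations
    onsets = ev["onset_ms"].to_numpy(dtype=float)
    samples = ev["sample"].to_numpy(dtype=int)
    is_ending = ev["category"].isin(ENDING_CATEGORIES).to_numpy()

    disturbers = np.sort(
        np.concatenate(
            [
                ev.loc[
                    ev["category"].isin(exclude_after_categories), "onset_ms"
                ].to_numpy(dtype=float),
                rec.presses["press_time_ms"].to_numpy(dtype=float)
                if len(rec.presses)
                else np.empty(0),
            ]
        )
    )

    n_pre = int(round(-tmin_ms / step))
    n_tot = int(round((tmax_ms - tmin_ms) / step))
    n_base = int(round(baseline_ms / step))

    kept, rows = [], []
    tallies = {"included": 0, "after_target_or_press": 0, "adjacent": 0, "artifact": 0}
    for i in np.flatnonzero(is_ending):
        t = onsets[i]
        # (1) within 3 s after a disturbing event or button press
        # (an event never excludes itself: strictly positive lag)
        j = np.searchsorted(disturbers, t, side="right")
        lagged = (t - disturbers[max(0, j - 2) : j])
        if np.any((lagged > 0.0) & (lagged < post_event_exclusion_ms)):
            tallies["after_target_or_press"] += 1
            continue
        # (2) adjacent stimulus onset closer than 200 ms
        gaps = []
        if i > 0:
            gaps.append(t - onsets[i - 1])
        if i + 1 < len(onsets):
            gaps.append(onsets[i + 1] - t)
        if gaps and min(gaps) < min_adjacent_ms:
            tallies["adjacent"] += 1
            continue
        # (3) artifact overlap
        s0 = samples[i] - n_pre
        s1 = s0 + n_tot
        if s0 < 0 or s1 > rec.n_samples:
            tallies["adjacent"] += 1  # cannot be epoched; record edge
            continue
        if mask[s0:s1].any():
            tallies["artifact"] += 1
            continue
        tallies["included"] += 1
        kept.append((s0, s1))
        rows.append(
            dict(
                category=ev["category"].iloc[i],
                block=int(ev["block"].iloc[i]),
                block_group=group_blocks(int(ev["block"].iloc[i])),
                onset_ms=t,
            )
        )

    if kept:
        data = np.stack([rec.data[:, s0:s1] for s0, s1 in kept]).astype(np.float64)
        base = data[:, :, n_pre - n_base : n_pre].mean(axis=2, keepdims=True)
        data -= base
    else:
        data = np.empty((0, rec.data.shape[0], n_tot))
    info = pd.DataFrame(rows, columns=["category", "block", "block_group", "onset_ms"])

    present = set(info["category"]) if len(info) else set()
    offered = set(ev.loc[is_ending, "category"])
    missing = [c for c in ENDING_CATEGORIES if c in offered and c not in present]
    if missing:
        warnings.warn(
            f"no surviving epochs for condition(s) {missing}; tallies={tallies}",
            stacklevel=2,
        )
    return EpochSet(
        data, info, rec.montage, tmin_ms, tmax_ms, exclusions=tallies, subject=subject
    )


def roi_waveforms(
    ep: EpochSet,
    montage: MontageSpec | None = None,
    by: tuple[str, ...] = ("category", "block_group"),
) -> pd.DataFrame:
    """Condition-averaged ROI waveforms.

    Epochs are averaged within each combination of ``by`` labels, then over
    the electrodes of each ROI.  Returns a DataFrame indexed by
    (*by*, roi) with one column per sample time (ms).
    """
    montage = montage or ep.montage
    ch_index = {ch: i for i, ch in enumerate(ep.montage.channels)}
    for roi, chans in montage.roi_map.items():
        for ch in chans:
            if ch not in ch_index:
                raise KeyError(f"ROI {roi} electrode {ch!r} missing from recording")
    times = ep.times_ms
    rows, index = [], []
    groups = ep.info.groupby(list(by), sort=True, observed=True).indices
    for key, idx in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        mean_ep = ep.data[idx].mean(axis=0)  # channels × samples
        for roi, chans in montage.roi_map.items():
            sel = [ch_index[c] for c in chans]
            rows.append(mean_ep[sel].mean(axis=0))
            index.append(key + (roi,))
    out = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=list(by) + ["roi"]),
        columns=np.round(times, 6),
    )
    return out
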