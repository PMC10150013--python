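"""Trial preprocessing: EMG resampling, zero-phase band-pass filtering,
epoch segmentation into 0.5 s sub-action windows, and trial-level
train/test splitting.

The processing order mirrors a typical synchronized-acquisition pipeline:
EMG is decimated to the EEG rate (500 Hz) so the modalities share a time
base, EEG is band-passed 2-40 Hz and EMG 2-100 Hz with zero-phase FIR
filters, then each 3 s epoch is cut into six contiguous 0.5 s windows whose
position index (0..5) becomes part of the sub-action label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .synthetic_data import TrialRecording, MOVEMENTS

__all__ = [
    "SegmentWindow",
    "EEG_BAND",
    "EMG_BAND",
    "resample_emg",
    "bandpass",
    "epoch_and_segment",
    "split_train_test",
    "preprocess_trial",
]

EEG_BAND = (2.0, 40.0)
EMG_BAND = (2.0, 100.0)
TARGET_RATE = 500.0
SEGMENT_SECONDS = 0.5


@dataclass
class SegmentWindow:
    """One 0.5 s multichannel window: 32 EEG rows then 8 EMG rows at 500 Hz."""

    data: np.ndarray            # (40, 250)
    movement: str
    position: int               # 0..5
    subject_id: str
    group: str
    rate: float = TARGET_RATE
    n_eeg: int = 32

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if self.position < 0:
            raise ValueError("position must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def resample_emg(trial: TrialRecording, target_rate: float = TARGET_RATE
                 ) -> TrialRecording:
    """Decimate EMG to the EEG rate with a polyphase anti-alias filter."""
    factor = trial.emg_rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"EMG rate {trial.emg_rate} is not an integer multiple of "
            f"{target_rate}"
        )
    factor = int(round(factor))
    if factor == 1:
        emg = trial.emg.copy()
    else:
        # 'line' boundary extension avoids edge ringing from zero padding
        emg = signal.resample_poly(trial.emg, up=1, down=factor, axis=1,
                                   padtype="line")
    return dc_replace(trial, emg=emg, emg_rate=target_rate)


def _fir_bandpass(data: np.ndarray, rate: float, band: tuple[float, float]
                  ) -> np.ndarray:
    low, high = band
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz >= Nyquist {nyq} Hz")
    n_samples = data.shape[-1]
    # linear-phase FIR applied forward-backward (zero phase); length capped
    # so filtfilt's edge padding fits in the signal
    numtaps = min(401, max(33, (n_samples - 4) // 3))
    if numtaps % 2 == 0:
        numtaps += 1
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=rate)
    return signal.filtfilt(taps, [1.0], data, axis=-1)


def bandpass(
    trial: TrialRecording,
    eeg_band: tuple[float, float] = EEG_BAND,
    emg_band: tuple[float, float] = EMG_BAND,
) -> TrialRecording:
    """Zero-phase FIR band-pass: EEG 2-40 Hz, EMG 2-100 Hz by default."""
    eeg = _fir_bandpass(trial.eeg, trial.eeg_rate, eeg_band)
    emg = _fir_bandpass(trial.emg, trial.emg_rate, emg_band)
    return dc_replace(trial, eeg=eeg, emg=emg)


def epoch_and_segment(
    trial: TrialRecording,
    n_segments: int = 6,
    segment_seconds: float = SEGMENT_SECONDS,
) -> list[SegmentWindow]:
    """Cut a preprocessed trial into contiguous sub-action windows.

    Requires EEG and EMG at a common rate; channels are stacked EEG-first
    (rows 0..31 EEG, 32..39 EMG).  The windows partition the epoch exactly:
    concatenating them recovers the full 40 x 1500 matrix.
    """
    if trial.emg_rate != trial.eeg_rate:
        raise ValueError("resample EMG to the EEG rate before segmenting")
    seg_len = int(round(segment_seconds * trial.eeg_rate))
    needed = n_segments * seg_len
    if trial.eeg.shape[1] < needed:
        raise ValueError(
            f"trial too short: {trial.eeg.shape[1]} samples < {needed} "
            f"({n_segments} x {segment_seconds} s)"
        )
    stacked = np.vstack([trial.eeg[:, :needed], trial.emg[:, :needed]])
    return [
        SegmentWindow(
            data=stacked[:, s * seg_len:(s + 1) * seg_len],
            movement=trial.movement, position=s,
            subject_id=trial.subject_id, group=trial.group,
            rate=trial.eeg_rate, n_eeg=trial.eeg.shape[0],
        )
        for s in range(n_segments)
    ]


def split_train_test(
    trials: Sequence,
    ratio: tuple[int, int] = (4, 1),
    seed: int = 0,
    movement_of: Callable = lambda t: t.movement,
) -> tuple[list, list]:
    """Stratified trial-level split (default 4:1 train:test).

    Splitting happens at the whole-trial level so that no trial's segments
    straddle the boundary, and independently per movement class so the
    class balance of train and test differs by at most one trial.
    """
    train_part, test_part = ratio
    if train_part <= 0 or test_part <= 0:
        raise ValueError("both ratio parts must be positive")
    test_share = test_part / (train_part + test_part)
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for t in trials:
        by_class.setdefault(movement_of(t), []).append(t)
    train, test = [], []
    for movement in sorted(by_class):
        cls_trials = by_class[movement]
        n = len(cls_trials)
        n_test = int(round(n * test_share))
        if n_test < 1 or n - n_test < 1:
            raise ValueError(
                f"class {movement!r}: {n} trials cannot fill both sides of a "
                f"{train_part}:{test_part} split"
            )
        perm = rng.permutation(n)
        test.extend(cls_trials[i] for i in perm[:n_test])
        train.extend(cls_trials[i] for i in perm[n_test:])
    return train, test


def preprocess_trial(
    trial: TrialRecording,
    n_segments: int = 6,
    segment_seconds: float = SEGMENT_SECONDS,
    ica_hook: Callable[[TrialRecording], TrialRecording] | None = None,
) -> list[SegmentWindow]:
    """Full per-trial chain: resample EMG -> band-pass -> (optional ICA
    artifact-removal hook) -> segment.  The ICA hook is a pass-through
    delegation point, disabled by default."""
    t = bandpass(resample_emg(trial))
    if ica_hook is not None:
        t = ica_hook(t)
    return epoch_and_segment(t, n_segments=n_segments,
                             segment_seconds=segment_seconds)
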