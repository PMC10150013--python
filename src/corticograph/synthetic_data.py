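"""Synthetic synchronized EEG-EMG trials with planted, recoverable structure.

Emulates a grasp-task recording session: 3 s isometric push / pull trials
with 32 EEG channels at 500 Hz (10-10 montage) and 8 forearm/upper-arm EMG
channels at 1000 Hz.  The generator plants exactly the two kinds of
structure the decoding pipeline consumes:

* **Band-power signatures** — each channel is a sum of band-limited Gaussian
  noise carriers (one per frequency band) whose amplitudes depend on the
  movement class and on the 0.5 s segment within the trial, plus white
  noise.  Movement identity is marked by the theta-band level; segment
  position by opposed alpha/beta amplitude ramps (alpha rises through a push
  while beta falls, and vice versa for a pull) — a cartoon of event-related
  desynchronization dynamics.
* **Corticomuscular coupling** — a shared beta-band latent drive is injected
  into sensorimotor EEG channels and flexor/extensor EMG channels with a
  configurable gain, so ordinal-pattern mutual information between those
  pairs rises with coupling strength.

What this deliberately does not model: volume conduction, realistic EEG
topographies, eye-blink or line-noise artifacts, or EMG rectification
nonlinearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "TrialRecording",
    "GeneratorProfile",
    "DatasetParseError",
    "EEG_CHANNEL_NAMES",
    "EMG_CHANNEL_NAMES",
    "MOVEMENTS",
    "generate_trial",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "read_edf",
]

MOVEMENTS = ("push", "pull")
GROUPS = ("healthy", "patient")

# 10-10 scalp positions of a standard 32-channel montage
EEG_CHANNEL_NAMES = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]
# forearm flexors/extensors, biceps, triceps, deltoid
EMG_CHANNEL_NAMES = ["FDS", "FCU", "FCR", "ECU", "ECRL", "BBS", "TBL", "LD"]

N_EEG, N_EMG = 32, 8
EEG_RATE, EMG_RATE = 500.0, 1000.0
TRIAL_SECONDS = 3.0
N_SEGMENTS = 6

BAND_EDGES = ((2.0, 4.0), (4.0, 8.0), (8.0, 15.0), (15.0, 30.0), (30.0, 40.0))

# sensorimotor strip (C3, Cz, C4, CP1) and task-relevant muscles
COUPLED_EEG = (12, 13, 14, 18)
COUPLED_EMG = (0, 1, 3, 4)  # FDS, FCU, ECU, ECRL
COUPLING_BAND = (15.0, 30.0)


class DatasetParseError(ValueError):
    """Raised when an on-disk trial container is malformed."""


@dataclass
class TrialRecording:
    """One synchronized 3 s EEG+EMG trial."""

    eeg: np.ndarray          # (32, 1500) at 500 Hz, microvolt scale
    emg: np.ndarray          # (8, samples) at emg_rate
    movement: str            # "push" | "pull"
    subject_id: str
    group: str               # "healthy" | "patient"
    eeg_rate: float = EEG_RATE
    emg_rate: float = EMG_RATE

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement!r}")
        if not (np.isfinite(self.eeg).all() and np.isfinite(self.emg).all()):
            raise ValueError("trial contains non-finite samples")
        if not math.isclose(self.eeg.shape[1] / self.eeg_rate,
                            self.emg.shape[1] / self.emg_rate):
            raise ValueError(
                "EEG and EMG durations differ: "
                f"{self.eeg.shape[1] / self.eeg_rate:.3f}s vs "
                f"{self.emg.shape[1] / self.emg_rate:.3f}s"
            )

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialRecording):
            return NotImplemented
        return (
            np.array_equal(self.eeg, other.eeg)
            and np.array_equal(self.emg, other.emg)
            and (self.movement, self.subject_id, self.group,
                 self.eeg_rate, self.emg_rate)
            == (other.movement, other.subject_id, other.group,
                other.eeg_rate, other.emg_rate)
        )


def _default_weights() -> np.ndarray:
    """(class, segment, band) carrier amplitudes for the default profile.

    Theta level separates push (2.0) from pull (0.6); alpha and beta ramp in
    opposite directions across the six segments with a 0.8 step, giving each
    of the 12 (movement, segment) sub-actions a distinct spectral signature.
    """
    w = np.ones((2, N_SEGMENTS, 5))
    seg = np.arange(N_SEGMENTS)
    w[0, :, 1] = 2.0                 # push: theta marker
    w[0, :, 2] = 0.4 + 0.8 * seg     # push: alpha rises
    w[0, :, 3] = 4.4 - 0.8 * seg     # push: beta falls
    w[1, :, 1] = 0.6                 # pull: theta marker
    w[1, :, 2] = 4.4 - 0.8 * seg     # pull: alpha falls
    w[1, :, 3] = 0.4 + 0.8 * seg     # pull: beta rises
    return w


@dataclass
class GeneratorProfile:
    """Everything the trial generator needs besides the movement label.

    ``band_weights`` has shape (2 classes, 6 segments, 5 bands) and gives
    the standard deviation of each band-limited carrier (in the common
    amplitude unit; trials are scaled to microvolts on output).
    ``coupling`` is the gain of the shared beta-band drive injected into the
    sensorimotor EEG channels and the task muscles.  ``noise_sd`` is the
    white-noise floor common to every channel.
    """

    band_weights: np.ndarray = field(default_factory=_default_weights)
    coupling: float = 1.5
    noise_sd: float = 1.0
    amplitude_uv: float = 5.0

    def __post_init__(self) -> None:
        self.band_weights = np.asarray(self.band_weights, dtype=float)
        if self.band_weights.shape != (2, N_SEGMENTS, 5):
            raise ValueError(
                f"band_weights must be (2, {N_SEGMENTS}, 5), "
                f"got {self.band_weights.shape}"
            )
        if np.any(self.band_weights < 0):
            raise ValueError("band weights must be nonnegative")
        if self.coupling < 0:
            raise ValueError("coupling must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if np.all(self.band_weights[0] == self.band_weights[1]):
            raise ValueError(
                "classes share identical band weights; planted structure "
                "would be unrecoverable"
            )

    @classmethod
    def default(cls) -> "GeneratorProfile":
        """The 'easy' healthy profile: strong planted structure, low noise."""
        return cls()

    @classmethod
    def degraded(cls, noise_sd: float = 10.0,
                 coupling_scale: float = 0.25) -> "GeneratorProfile":
        """Patient-like profile: same planted signatures buried under a much
        higher noise floor, with attenuated corticomuscular coupling."""
        base = cls()
        return replace(base, noise_sd=noise_sd,
                       coupling=base.coupling * coupling_scale)


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                rate: float, low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high) Hz,
    synthesized in the frequency domain."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    mask = (freqs >= low) & (freqs < high)
    spec = np.zeros((n_channels, freqs.size), dtype=complex)
    k = int(mask.sum())
    if k == 0:
        return np.zeros((n_channels, n_samples))
    spec[:, mask] = rng.standard_normal((n_channels, k)) + 1j * rng.standard_normal(
        (n_channels, k)
    )
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_trial(
    movement: str,
    profile: GeneratorProfile,
    seed: int | np.random.Generator,
    subject_id: str = "S00",
    group: str = "healthy",
) -> TrialRecording:
    """Generate one 3 s trial. Deterministic given the seed."""
    if movement not in MOVEMENTS:
        raise ValueError(f"movement must be one of {MOVEMENTS}, got {movement!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cls = MOVEMENTS.index(movement)
    seg_eeg = int(EEG_RATE * TRIAL_SECONDS / N_SEGMENTS)   # 250
    seg_emg = int(EMG_RATE * TRIAL_SECONDS / N_SEGMENTS)   # 500

    eeg_parts, emg_parts = [], []
    for s in range(N_SEGMENTS):
        eeg_s = np.zeros((N_EEG, seg_eeg))
        emg_s = np.zeros((N_EMG, seg_emg))
        for b, (low, high) in enumerate(BAND_EDGES):
            w = profile.band_weights[cls, s, b]
            eeg_s += w * _band_noise(rng, N_EEG, seg_eeg, EEG_RATE, low, high)
            emg_s += w * _band_noise(rng, N_EMG, seg_emg, EMG_RATE, low, high)
        eeg_parts.append(eeg_s)
        emg_parts.append(emg_s)
    eeg = np.concatenate(eeg_parts, axis=1)
    emg = np.concatenate(emg_parts, axis=1)

    # shared beta-band latent drive -> corticomuscular coupling
    n_emg_samples = emg.shape[1]
    latent = _band_noise(rng, 1, n_emg_samples, EMG_RATE, *COUPLING_BAND)[0]
    for ch in COUPLED_EEG:
        eeg[ch] += profile.coupling * latent[::2]
    for ch in COUPLED_EMG:
        emg[ch] += profile.coupling * latent

    eeg += profile.noise_sd * rng.standard_normal(eeg.shape)
    emg += 1.5 * profile.noise_sd * rng.standard_normal(emg.shape)
    scale = profile.amplitude_uv
    return TrialRecording(
        eeg=scale * eeg, emg=scale * emg, movement=movement,
        subject_id=subject_id, group=group,
    )


def generate_dataset(
    n_per_class: int,
    subjects: list[str],
    group_mix: dict[str, str] | None = None,
    profile: GeneratorProfile | dict[str, GeneratorProfile] | None = None,
    seed: int = 0,
) -> list[TrialRecording]:
    """Balanced trial set: ``n_per_class`` trials of each movement per subject.

    ``group_mix`` maps subject id -> group (default: all healthy).
    ``profile`` is one GeneratorProfile for everyone, or a mapping from group
    name to profile (e.g. a degraded profile for the patient group).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not subjects:
        raise ValueError("subject list is empty")
    group_mix = group_mix or {s: "healthy" for s in subjects}
    if profile is None:
        profile = GeneratorProfile.default()

    def profile_for(group: str) -> GeneratorProfile:
        return profile[group] if isinstance(profile, dict) else profile

    trials: list[TrialRecording] = []
    seeds = np.random.SeedSequence(seed).spawn(len(subjects))
    for subj, subj_seed in zip(subjects, seeds):
        group = group_mix.get(subj, "healthy")
        rng = np.random.default_rng(subj_seed)
        for movement in MOVEMENTS:
            for _ in range(n_per_class):
                trials.append(
                    generate_trial(movement, profile_for(group), rng,
                                   subject_id=subj, group=group)
                )
    return trials


# ---------------------------------------------------------------------------
# on-disk layout: one HDF5 container per subject + a sidecar metadata table

def write_dataset(trials: list[TrialRecording], path) -> None:
    """Write trials as one HDF5 file per subject plus metadata.tsv."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[TrialRecording]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    meta_rows = []
    for subj, subj_trials in by_subject.items():
        fname = root / f"{subj}.h5"
        with h5py.File(fname, "w") as f:
            f.attrs["subject_id"] = subj
            f.attrs["group"] = subj_trials[0].group
            for i, t in enumerate(subj_trials):
                g = f.create_group(f"trial_{i:04d}")
                g.create_dataset("eeg", data=t.eeg)
                g.create_dataset("emg", data=t.emg)
                g.attrs["movement"] = t.movement
                g.attrs["eeg_rate"] = t.eeg_rate
                g.attrs["emg_rate"] = t.emg_rate
                meta_rows.append((subj, t.group, i, t.movement, fname.name))
    with open(root / "metadata.tsv", "w") as fh:
        fh.write("subject\tgroup\ttrial\tmovement\tfile\n")
        for row in meta_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_dataset(path) -> list[TrialRecording]:
    """Read a dataset written by :func:`write_dataset`; lossless round trip."""
    root = Path(path)
    files = sorted(root.glob("*.h5"))
    if not files:
        raise DatasetParseError(f"no subject containers (*.h5) found in {root}")
    trials: list[TrialRecording] = []
    for fname in files:
        with h5py.File(fname, "r") as f:
            if "subject_id" not in f.attrs or "group" not in f.attrs:
                raise DatasetParseError(
                    f"{fname.name}: missing subject_id/group file attributes"
                )
            subj = str(f.attrs["subject_id"])
            group = str(f.attrs["group"])
            for key in sorted(f.keys()):
                g = f[key]
                for req in ("movement", "eeg_rate", "emg_rate"):
                    if req not in g.attrs:
                        raise DatasetParseError(
                            f"{fname.name}/{key}: missing attribute {req!r}"
                        )
                if "eeg" not in g or "emg" not in g:
                    raise DatasetParseError(
                        f"{fname.name}/{key}: missing eeg/emg datasets"
                    )
                trials.append(TrialRecording(
                    eeg=g["eeg"][()], emg=g["emg"][()],
                    movement=str(g.attrs["movement"]),
                    subject_id=subj, group=group,
                    eeg_rate=float(g.attrs["eeg_rate"]),
                    emg_rate=float(g.attrs["emg_rate"]),
                ))
    return trials


def read_edf(path, n_eeg: int = N_EEG, movement: str = "push",
             subject_id: str = "edf", group: str = "healthy") -> TrialRecording:
    """Import one trial from an EDF file (optional; requires mne).

    The first ``n_eeg`` channels are taken as EEG and the remainder as EMG;
    the sampling rate is read from the EDF header.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()
    if data.shape[0] <= n_eeg:
        raise DatasetParseError(
            f"EDF file has {data.shape[0]} channels; need more than {n_eeg}"
        )
    rate = float(raw.info["sfreq"])
    return TrialRecording(
        eeg=data[:n_eeg], emg=data[n_eeg:], movement=movement,
        subject_id=subject_id, group=group, eeg_rate=rate, emg_rate=rate,
    )
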