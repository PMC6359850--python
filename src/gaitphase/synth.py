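"""Seeded generator of stylized, labelled gait signals.

Emulates treadmill walking recorded by thigh/knee sensors: knee
flexion-extension angle (degrees), thigh-segment angular velocity
(rad/s, 3 axes) and thigh-segment acceleration (m/s^2, 3 axes), sampled
at 200 Hz, across five surface conditions — level ground (LG), 7 deg
down-slope (DS), 7 deg up-slope (US), 5 deg right cross-slope (RS), 5 deg
left cross-slope (LS) — and four belt speeds (self-paced ~1.33 m/s, 0.8,
0.6, 0.4 m/s).

Each stride is built from smooth templates with stylized gait structure:

* knee angle carries a stance flexion wave whose amplitude shrinks
  monotonically as walking slows, and a swing flexion peak near 60 deg
  whose maximum defines the maximum-knee-flexion event;
* the x-axis angular velocity is the knee-angle time derivative (so it
  crosses zero at knee-angle extrema);
* the z-axis acceleration carries a gravity-scale offset during stance;
* inter-stride template jitter and additive channel noise both grow as
  speed drops, mirroring the higher variability of slow walking.

Surfaces act as mild covariates (small template offsets/gains), not as
separate regimes.  Ground-truth labels are derived from the generated
event indices via :func:`gaitphase.preprocess.label_phases`.

Determinism: an identical :class:`SimConfig` (including ``seed``)
produces bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ConfigurationError, InputError, label_phases

__all__ = [
    "SURFACES",
    "SimConfig",
    "GaitSignal",
    "StrideAnnotation",
    "Recording",
    "simulate_cohort",
    "training_cohort",
    "validation_cohort",
    "write_signal_csv",
    "read_signal_csv",
    "write_annotations_json",
    "read_annotations_json",
]

SURFACES = ("LG", "DS", "US", "RS", "LS")

#: Self-paced reference speed (m/s) used to normalise speed effects.
REFERENCE_SPEED = 1.33

#: Stride time at the reference speed (s).
REFERENCE_STRIDE_TIME = 1.1

#: Per-channel additive-noise scale (native units) at noise_sd = 1.
_NOISE_SCALE = {"ka": 0.8, "angvel": 0.06, "acc": 0.25}

# Mild per-surface template modifiers: (stance-amp offset deg,
# baseline offset deg, lateral angvel offset rad/s, lateral acc offset m/s^2)
_SURFACE_FX = {
    "LG": (0.0, 0.0, 0.0, 0.0),
    "DS": (-2.0, -1.0, 0.0, 0.0),
    "US": (3.0, 2.0, 0.0, 0.0),
    "RS": (0.5, 0.0, 0.15, 0.6),
    "LS": (0.5, 0.0, -0.15, -0.6),
}

GRAVITY = 9.81


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated recording (one subject x condition)."""

    surface: str = "LG"
    speed_mps: float = REFERENCE_SPEED
    n_strides: int = 10
    sample_rate_hz: float = 200.0
    noise_sd: float = 1.0
    variability_scale: float = 1.0
    seed: int = 0
    #: stride fractions of (mid-stance, foot-off, max knee flexion)
    event_fracs: tuple[float, float, float] = (0.30, 0.60, 0.73)
    #: multiplicative subject offsets (amplitude, stride-time, baseline deg)
    subject_fx: tuple[float, float, float] = (1.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ConfigurationError(f"unknown surface {self.surface!r}")
        if self.speed_mps <= 0:
            raise ConfigurationError("speed_mps must be positive")
        if self.n_strides < 1:
            raise ConfigurationError("n_strides must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if self.noise_sd < 0 or self.variability_scale < 0:
            raise ConfigurationError("noise_sd and variability_scale must be >= 0")
        f = self.event_fracs
        if not (0.0 < f[0] < f[1] < f[2] < 1.0):
            raise ConfigurationError("event_fracs must be increasing in (0, 1)")


@dataclasses.dataclass(frozen=True)
class StrideAnnotation:
    """Sample indices of the four gait events bounding one stride."""

    initial_contact: int
    mid_stance: int
    foot_off: int
    max_knee_flexion: int
    next_initial_contact: int

    def __post_init__(self) -> None:
        idx = dataclasses.astuple(self)
        if not all(a < b for a, b in zip(idx, idx[1:])):
            raise InputError(f"gait events must be strictly increasing, got {idx}")

    def shifted(self, offset: int) -> "StrideAnnotation":
        return StrideAnnotation(*(i + offset for i in dataclasses.astuple(self)))


@dataclasses.dataclass
class GaitSignal:
    """Uniformly sampled multichannel gait record.

    ``angvel`` and ``acc`` are ``(n, 3)`` arrays ordered x, y, z.
    ``labels`` is an object array of phase names ('' = unlabelled) or
    ``None`` when the record is unlabelled.
    """

    t: np.ndarray
    ka: np.ndarray
    angvel: np.ndarray
    acc: np.ndarray
    sample_rate_hz: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.t.shape[0]
        if self.ka.shape != (n,) or self.angvel.shape != (n, 3) or self.acc.shape != (n, 3):
            raise InputError("channel lengths disagree")
        for arr in (self.t, self.ka, self.angvel, self.acc):
            if not np.all(np.isfinite(arr)):
                raise InputError("non-finite sample in gait signal")
        if self.labels is not None and self.labels.shape != (n,):
            raise InputError("labels length disagrees with channels")

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclasses.dataclass
class Recording:
    """One simulated subject-condition recording with its ground truth."""

    recording_id: str
    config: SimConfig
    signal: GaitSignal
    annotations: list[StrideAnnotation]


def _stride_samples(config: SimConfig, time_jitter: float) -> int:
    """Stride duration in samples; slower walking -> longer strides."""
    ratio = REFERENCE_SPEED / config.speed_mps
    stride_t = REFERENCE_STRIDE_TIME * ratio**0.55 * config.subject_fx[1]
    stride_t *= 1.0 + time_jitter
    return max(int(round(stride_t * config.sample_rate_hz)), 40)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _stride_template(
    config: SimConfig, n: int, amp_jitter: float, frac_jitter: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, StrideAnnotation]:
    """Noiseless per-stride channel templates plus event annotation.

    Returns (ka, angvel(n,3), acc(n,3), annotation with indices local to
    the stride).
    """
    amp_fx, base_fx, lat_av_fx, lat_acc_fx = _SURFACE_FX[config.surface]
    tau = np.arange(n) / n  # stride phase in [0, 1)

    fracs = np.clip(np.asarray(config.event_fracs) + frac_jitter, 0.02, 0.98)
    fracs = np.maximum.accumulate(fracs + np.array([0.0, 1e-3, 2e-3]))
    i_ms = int(round(fracs[0] * n))
    i_fo = int(round(fracs[1] * n))

    speed_gain = (config.speed_mps / REFERENCE_SPEED) ** 0.7
    amp = 1.0 + amp_jitter
    stance_amp = max((16.0 * speed_gain + amp_fx) * config.subject_fx[0] * amp, 0.5)
    swing_amp = 57.0 * config.subject_fx[0] * amp
    base = 3.0 + base_fx + config.subject_fx[2]

    tau_mkf = fracs[2]
    ka = (
        base
        + stance_amp * np.exp(-0.5 * ((tau - 0.15) / 0.08) ** 2)
        + swing_amp * np.exp(-0.5 * ((tau - tau_mkf) / 0.06) ** 2)
    )

    # maximum-knee-flexion event = argmax of the template in swing
    lo = min(i_fo + 1, n - 2)
    i_mkf = lo + int(np.argmax(ka[lo : n - 1]))
    i_ms = min(max(i_ms, 1), i_fo - 1)
    i_fo = min(max(i_fo, i_ms + 1), i_mkf - 1)

    dt = 1.0 / config.sample_rate_hz
    dka = np.gradient(ka, dt)
    angvel = np.empty((n, 3))
    angvel[:, 0] = np.deg2rad(dka) * 0.25
    angvel[:, 1] = (
        0.9 * speed_gain * amp * np.sin(2 * np.pi * tau + 0.4)
        + 0.3 * np.sin(4 * np.pi * tau)
        + lat_av_fx
    )
    angvel[:, 2] = 0.4 * speed_gain * amp * np.sin(2 * np.pi * tau + 1.9) + lat_av_fx / 2

    # smooth stance indicator: 1 during stance, low during swing
    stance = 1.0 - 0.8 * (_smoothstep((tau - fracs[1]) / 0.06) - _smoothstep((tau - 0.97) / 0.03))
    acc = np.empty((n, 3))
    acc[:, 0] = 0.8 * speed_gain * np.sin(4 * np.pi * tau + 0.7) + lat_acc_fx
    acc[:, 1] = (
        2.2 * speed_gain * amp * np.sin(2 * np.pi * tau)
        + 1.1 * speed_gain * np.sin(6 * np.pi * tau + 0.3)
    )
    acc[:, 2] = GRAVITY * stance + 1.3 * speed_gain * np.sin(4 * np.pi * tau + 2.1)

    ann = StrideAnnotation(0, i_ms, i_fo, i_mkf, n)
    return ka, angvel, acc, ann


def simulate_cohort(
    config: SimConfig,
) -> tuple[GaitSignal, list[StrideAnnotation]]:
    """Simulate ``config.n_strides`` concatenated strides for one condition.

    Inter-stride jitter and additive noise scale with
    ``variability_scale * (reference_speed / speed_mps)`` and
    ``noise_sd * (reference_speed / speed_mps)`` respectively, so slow
    walking is noisier and more variable, as observed in treadmill data.
    """
    rng = np.random.default_rng(config.seed)
    slow_factor = REFERENCE_SPEED / config.speed_mps
    jit = 0.03 * config.variability_scale * slow_factor

    kas, avs, accs, anns = [], [], [], []
    offset = 0
    for _ in range(config.n_strides):
        amp_jitter = rng.normal(0.0, jit)
        time_jitter = float(np.clip(rng.normal(0.0, jit), -0.3, 0.3))
        frac_jitter = rng.normal(0.0, jit / 3.0, size=3)
        n = _stride_samples(config, time_jitter)
        ka, av, ac, ann = _stride_template(config, n, amp_jitter, frac_jitter)
        kas.append(ka)
        avs.append(av)
        accs.append(ac)
        anns.append(ann.shifted(offset))
        offset += n

    ka = np.concatenate(kas)
    angvel = np.concatenate(avs)
    acc = np.concatenate(accs)
    n_total = ka.shape[0]

    if config.noise_sd > 0:
        s = config.noise_sd * slow_factor
        ka = ka + rng.normal(0.0, s * _NOISE_SCALE["ka"], n_total)
        angvel = angvel + rng.normal(0.0, s * _NOISE_SCALE["angvel"], (n_total, 3))
        acc = acc + rng.normal(0.0, s * _NOISE_SCALE["acc"], (n_total, 3))

    t = np.arange(n_total) / config.sample_rate_hz
    labels = label_phases(anns, n_total)
    signal = GaitSignal(
        t=t, ka=ka, angvel=angvel, acc=acc,
        sample_rate_hz=config.sample_rate_hz, labels=labels,
    )
    return signal, anns


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

TRAINING_SPEEDS = (REFERENCE_SPEED, 0.8, 0.6, 0.4)


def _subject_fx(rng: np.random.Generator) -> tuple[float, float, float]:
    return (
        float(rng.normal(1.0, 0.06)),
        float(rng.normal(1.0, 0.05)),
        float(rng.normal(0.0, 1.0)),
    )


def training_cohort(
    seed: int,
    n_subjects: int = 30,
    speeds: Sequence[float] = TRAINING_SPEEDS,
    surfaces: Sequence[str] = SURFACES,
    n_strides: int = 10,
    sp_speed_sd: float = 0.04,
    noise_sd: float = 1.0,
    variability_scale: float = 1.0,
) -> list[Recording]:
    """Training-style cohort: every subject walks every surface x speed.

    Defaults mirror the study design (30 subjects, 4 speeds, 5 surfaces,
    10 strides per condition, self-paced speed ~N(1.33, 0.04)).  Smaller
    values may be passed for desk-scale experiments.
    """
    rng = np.random.default_rng(seed)
    out: list[Recording] = []
    for s in range(n_subjects):
        fx = _subject_fx(rng)
        sp = float(np.clip(rng.normal(REFERENCE_SPEED, sp_speed_sd), 0.3, None))
        for speed in speeds:
            actual = sp if speed == REFERENCE_SPEED else speed
            for surf in surfaces:
                cfg = SimConfig(
                    surface=surf,
                    speed_mps=actual,
                    n_strides=n_strides,
                    noise_sd=noise_sd,
                    variability_scale=variability_scale,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject_fx=fx,
                )
                signal, anns = simulate_cohort(cfg)
                rid = f"train_s{s:02d}_{surf}_{actual:.2f}"
                out.append(Recording(rid, cfg, signal, anns))
    return out


def validation_cohort(
    seed: int,
    n_subjects: int = 12,
    surfaces: Sequence[str] = SURFACES,
    n_strides: int = 6,
    sp_speed_mean: float = 1.41,
    sp_speed_sd: float = 0.34,
    noise_sd: float = 1.0,
    variability_scale: float = 1.0,
) -> list[Recording]:
    """Validation-style cohort: self-paced only, wider speed spread.

    Defaults mirror the held-out study design (12 unseen subjects,
    self-paced ~N(1.41, 0.34), 6 strides per surface).
    """
    rng = np.random.default_rng(seed)
    out: list[Recording] = []
    for s in range(n_subjects):
        fx = _subject_fx(rng)
        sp = float(np.clip(rng.normal(sp_speed_mean, sp_speed_sd), 0.3, None))
        for surf in surfaces:
            cfg = SimConfig(
                surface=surf,
                speed_mps=sp,
                n_strides=n_strides,
                noise_sd=noise_sd,
                variability_scale=variability_scale,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_fx=fx,
            )
            signal, anns = simulate_cohort(cfg)
            rid = f"val_s{s:02d}_{surf}_{sp:.2f}"
            out.append(Recording(rid, cfg, signal, anns))
    return out


# ---------------------------------------------------------------------------
# CSV / JSON round-trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "time", "ka", "angvel_x", "angvel_y", "angvel_z",
    "acc_x", "acc_y", "acc_z", "label",
]


def write_signal_csv(signal: GaitSignal, path: str | Path) -> None:
    """Write a signal to the package CSV dialect (header required)."""
    labels = signal.labels if signal.labels is not None else [""] * len(signal)
    df = pd.DataFrame(
        {
            "time": signal.t,
            "ka": signal.ka,
            "angvel_x": signal.angvel[:, 0],
            "angvel_y": signal.angvel[:, 1],
            "angvel_z": signal.angvel[:, 2],
            "acc_x": signal.acc[:, 0],
            "acc_y": signal.acc[:, 1],
            "acc_z": signal.acc[:, 2],
            "label": labels,
        }
    )
    df.to_csv(path, index=False)


def read_signal_csv(path: str | Path, sample_rate_hz: float | None = None) -> GaitSignal:
    """Read a signal CSV written by :func:`write_signal_csv`."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"signal CSV missing column(s): {', '.join(missing)}")
    t = df["time"].to_numpy(dtype=float)
    if sample_rate_hz is None:
        if t.size < 2:
            raise InputError("cannot infer sample rate from fewer than 2 samples")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    labels = df["label"].astype(str).to_numpy(dtype=object)
    if not any(lab for lab in labels):
        labels = None
    return GaitSignal(
        t=t,
        ka=df["ka"].to_numpy(dtype=float),
        angvel=df[["angvel_x", "angvel_y", "angvel_z"]].to_numpy(dtype=float),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        sample_rate_hz=float(sample_rate_hz),
        labels=labels,
    )


def write_annotations_json(
    annotations: Sequence[StrideAnnotation],
    config: SimConfig,
    path: str | Path,
) -> None:
    """JSON sidecar: stride annotations plus the SimConfig that made them."""
    doc = {
        "config": dataclasses.asdict(config),
        "annotations": [dataclasses.asdict(a) for a in annotations],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotations_json(path: str | Path) -> tuple[list[StrideAnnotation], SimConfig]:
    doc = json.loads(Path(path).read_text())
    cfg_d = doc["config"]
    for key in ("event_fracs", "subject_fx"):
        cfg_d[key] = tuple(cfg_d[key])
    config = SimConfig(**cfg_d)
    anns = [StrideAnnotation(**a) for a in doc["annotations"]]
    return anns, config
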