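"""Sliding-window feature extraction.

Each 0.1-s window (20 samples at 200 Hz, advanced by 0.01 s for 90%
overlap) yields a fixed-order vector of 20 features computed from the
knee angle (KA), the three thigh angular-velocity axes (AngVel), the
three thigh acceleration axes (Acc), and the resultant Acc magnitude.
The window is labelled by the phase of its *last* sample, so a trained
classifier predicts the phase "now", at the trailing edge of the buffer.

Feature conventions
-------------------
* "max difference" is the within-window range, ``max - min``;
* variance is the population form (divide by n);
* sign-sum scores each sample -1 (negative), +1 (positive), 0 (exact
  zero) and sums;
* a peak is an interior sample strictly greater than both neighbours;
* principal frequency is the non-DC FFT bin of greatest magnitude, ties
  broken toward the lowest frequency; a window with no non-DC energy
  reports 0 Hz;
* the Acc z/y correlation is the Pearson coefficient, defined as 0 when
  either channel has zero variance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import InputError, ConfigurationError, UNLABELLED, resultant
from .synth import GaitSignal, Recording

__all__ = [
    "FEATURE_NAMES",
    "WindowSpec",
    "FeatureWindow",
    "WindowView",
    "sliding_windows",
    "sign_sum",
    "count_peaks",
    "principal_frequency",
    "window_correlation",
    "extract_features",
    "feature_matrix",
    "feature_matrix_from_recordings",
    "write_feature_csv",
    "read_feature_csv",
    "write_arff_header",
]

#: Fixed order of the 20 window features.
FEATURE_NAMES: tuple[str, ...] = (
    "ka_mean",
    "angvel_x_mean",
    "angvel_y_mean",
    "acc_y_mean",
    "acc_z_mean",
    "ka_var",
    "ka_max_diff",
    "angvel_x_max_diff",
    "ka_min",
    "angvel_y_min",
    "acc_y_max",
    "angvel_x_sign_sum",
    "angvel_y_sign_sum",
    "angvel_z_sign_sum",
    "acc_x_sign_sum",
    "acc_y_sign_sum",
    "acc_z_sign_sum",
    "res_acc_peak_count",
    "angvel_y_principal_freq",
    "acc_zy_corr",
)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (defaults: 0.1 s window, 0.01 s step)."""

    window_s: float = 0.1
    step_s: float = 0.01
    sample_rate_hz: float = 200.0

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.sample_rate_hz))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_s * self.sample_rate_hz))

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.step_samples / self.window_samples

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ConfigurationError("window must span at least 2 samples")
        if self.step_samples < 1:
            raise ConfigurationError("step must span at least 1 sample")
        if self.step_samples > self.window_samples:
            raise ConfigurationError("step must not exceed the window")


@dataclasses.dataclass
class WindowView:
    """Views of all channels for one window."""

    ka: np.ndarray
    angvel: np.ndarray  # (w, 3)
    acc: np.ndarray  # (w, 3)
    sample_rate_hz: float
    end_index: int
    label: str | None = None


@dataclasses.dataclass
class FeatureWindow:
    """One 20-element feature vector with the last-sample label."""

    features: np.ndarray
    end_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.features.shape != (len(FEATURE_NAMES),):
            raise InputError("feature vector must have exactly 20 entries")
        if not np.all(np.isfinite(self.features)):
            raise InputError("non-finite feature value")


def n_windows(n_samples: int, spec: WindowSpec) -> int:
    """Number of complete windows: ``floor((N - w) / step) + 1``."""
    w, s = spec.window_samples, spec.step_samples
    if n_samples < w:
        raise InputError(f"signal of {n_samples} samples shorter than one window ({w})")
    return (n_samples - w) // s + 1


def sliding_windows(signal: GaitSignal, spec: WindowSpec) -> Iterator[WindowView]:
    """Iterate complete windows starting at 0, step, 2*step, ..."""
    w, s = spec.window_samples, spec.step_samples
    count = n_windows(len(signal), spec)
    for k in range(count):
        a, b = k * s, k * s + w
        end = b - 1
        label = None
        if signal.labels is not None:
            lab = signal.labels[end]
            label = None if lab == UNLABELLED else str(lab)
        yield WindowView(
            ka=signal.ka[a:b],
            angvel=signal.angvel[a:b],
            acc=signal.acc[a:b],
            sample_rate_hz=signal.sample_rate_hz,
            end_index=end,
            label=label,
        )


# ---------------------------------------------------------------------------
# Per-window operators (each accepts a 1-D window or a 2-D stack of windows)
# ---------------------------------------------------------------------------


def sign_sum(x: np.ndarray) -> np.ndarray | int:
    """Sum of per-sample scores: -1 negative, +1 positive, 0 for zero."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InputError("sign_sum of empty window")
    out = np.sign(x).sum(axis=-1)
    return int(out) if x.ndim == 1 else out.astype(int)


def count_peaks(x: np.ndarray) -> np.ndarray | int:
    """Number of interior samples strictly greater than both neighbours."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        return 0 if x.ndim == 1 else np.zeros(x.shape[0], dtype=int)
    mid = x[..., 1:-1]
    peaks = (mid > x[..., :-2]) & (mid > x[..., 2:])
    out = peaks.sum(axis=-1)
    return int(out) if x.ndim == 1 else out.astype(int)


def principal_frequency(x: np.ndarray, sample_rate_hz: float) -> np.ndarray | float:
    """Frequency (Hz) of the largest-magnitude non-DC spectral component.

    Ties resolve to the lowest frequency; a window with no non-DC energy
    (e.g. constant) reports 0 Hz by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise InputError("principal_frequency needs at least 2 samples")
    spec = np.abs(np.fft.rfft(x, axis=-1))
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / sample_rate_hz)
    nondc = spec[..., 1:]
    # argmax takes the first maximum -> lowest-frequency tie-break
    best = np.argmax(nondc, axis=-1)
    out = freqs[1:][best]
    # no non-DC energy (relative to DC magnitude) -> 0 Hz
    tol = 1e-9 * (spec[..., 0] + 1.0)
    out = np.where(np.max(nondc, axis=-1) <= tol, 0.0, out)
    return float(out) if x.ndim == 1 else out


def window_correlation(y: np.ndarray, z: np.ndarray) -> np.ndarray | float:
    """Pearson correlation; 0 if either input has zero variance."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape or y.shape[-1] < 2:
        raise InputError("window_correlation needs equal-length windows (>= 2)")
    yc = y - y.mean(axis=-1, keepdims=True)
    zc = z - z.mean(axis=-1, keepdims=True)
    num = (yc * zc).sum(axis=-1)
    den = np.sqrt((yc * yc).sum(axis=-1) * (zc * zc).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return float(r) if y.ndim == 1 else r


def _feature_block(
    ka: np.ndarray,
    angvel: np.ndarray,
    acc: np.ndarray,
    sample_rate_hz: float,
) -> np.ndarray:
    """Compute the 20 features for a stack of windows.

    ``ka`` is (m, w); ``angvel`` and ``acc`` are (m, w, 3).
    """
    av_x, av_y, av_z = angvel[..., 0], angvel[..., 1], angvel[..., 2]
    ac_x, ac_y, ac_z = acc[..., 0], acc[..., 1], acc[..., 2]
    res_acc = resultant(ac_x, ac_y, ac_z)

    cols = [
        ka.mean(axis=-1),
        av_x.mean(axis=-1),
        av_y.mean(axis=-1),
        ac_y.mean(axis=-1),
        ac_z.mean(axis=-1),
        ka.var(axis=-1),  # population variance
        ka.max(axis=-1) - ka.min(axis=-1),
        av_x.max(axis=-1) - av_x.min(axis=-1),
        ka.min(axis=-1),
        av_y.min(axis=-1),
        ac_y.max(axis=-1),
        sign_sum(av_x),
        sign_sum(av_y),
        sign_sum(av_z),
        sign_sum(ac_x),
        sign_sum(ac_y),
        sign_sum(ac_z),
        count_peaks(res_acc),
        principal_frequency(av_y, sample_rate_hz),
        window_correlation(ac_z, ac_y),
    ]
    return np.stack([np.asarray(c, dtype=float) for c in cols], axis=-1)


def extract_features(window: WindowView) -> FeatureWindow:
    """The 20-feature vector of one window, labelled by its last sample."""
    for name, arr in (("ka", window.ka), ("angvel", window.angvel), ("acc", window.acc)):
        if arr is None or arr.shape[0] != window.ka.shape[0]:
            raise InputError(f"missing or misaligned channel: {name}")
    feats = _feature_block(
        window.ka[None, :],
        window.angvel[None, :, :],
        window.acc[None, :, :],
        window.sample_rate_hz,
    )[0]
    return FeatureWindow(features=feats, end_index=window.end_index, label=window.label)


def feature_matrix(
    signal: GaitSignal,
    spec: WindowSpec | None = None,
    recording_id: str = "",
    labelled_only: bool = True,
) -> pd.DataFrame:
    """All window features of a signal as a DataFrame.

    Columns: the 20 features (see :data:`FEATURE_NAMES`), ``label``,
    ``end_index`` and ``recording_id``.  Windows ending on unlabelled
    samples are dropped when ``labelled_only`` is set.
    """
    spec = spec or WindowSpec(sample_rate_hz=signal.sample_rate_hz)
    w, s = spec.window_samples, spec.step_samples
    m = n_windows(len(signal), spec)
    ka_w = sliding_window_view(signal.ka, w)[::s][:m]
    av_w = sliding_window_view(signal.angvel, (w, 3)).squeeze(1)[::s][:m]
    ac_w = sliding_window_view(signal.acc, (w, 3)).squeeze(1)[::s][:m]
    feats = _feature_block(ka_w, av_w, ac_w, spec.sample_rate_hz)

    ends = np.arange(m) * s + w - 1
    if signal.labels is not None:
        labels = signal.labels[ends]
    else:
        labels = np.full(m, UNLABELLED, dtype=object)

    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df["label"] = labels
    df["end_index"] = ends
    df["recording_id"] = recording_id
    if labelled_only:
        df = df[df["label"] != UNLABELLED].reset_index(drop=True)
    return df


def feature_matrix_from_recordings(
    recordings: Sequence[Recording], spec: WindowSpec | None = None
) -> pd.DataFrame:
    """Concatenated feature matrices of a cohort, keyed by recording_id."""
    parts = [
        feature_matrix(rec.signal, spec, recording_id=rec.recording_id)
        for rec in recordings
    ]
    return pd.concat(parts, ignore_index=True)


def write_feature_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in (*FEATURE_NAMES, "label", "end_index") if c not in df.columns]
    if missing:
        raise InputError(f"feature CSV missing column(s): {', '.join(missing)}")
    if "recording_id" not in df.columns:
        df["recording_id"] = ""
    df["recording_id"] = df["recording_id"].astype(str)
    return df


def write_arff_header(path: str | Path, relation: str = "gait_windows") -> None:
    """ARFF-compatible attribute listing for cross-checks with WEKA tools."""
    lines = [f"@relation {relation}", ""]
    lines += [f"@attribute {name} numeric" for name in FEATURE_NAMES]
    lines.append("@attribute label {LR,PO,Swing,TSw}")
    lines += ["", "@data"]
    Path(path).write_text("\n".join(lines) + "\n")
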