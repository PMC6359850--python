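"""Signal conditioning and gait-phase labelling.

A stride is partitioned into four phases by four gait events:

=================  ==========================  =========================
phase              starts at                   ends at
=================  ==========================  =========================
Loading Response   initial contact             mid-stance
Push-Off           mid-stance                  foot-off
Swing              foot-off                    maximum knee flexion
Terminal Swing     maximum knee flexion        next initial contact
=================  ==========================  =========================

Intervals are half-open ``[start, end)`` so every in-stride sample carries
exactly one label.  The phase cycle is fixed:
``LR -> PO -> Swing -> TSw -> LR``.

Filtering uses a zero-phase (forward-backward) Butterworth low-pass, the
standard conditioning step for optical-marker kinematics before event
labelling; zero-phase application avoids shifting events in time.
"""

from __future__ import annotations

import enum
from typing import Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "PhaseLabel",
    "PHASE_ORDER",
    "SUCCESSOR",
    "UNLABELLED",
    "InputError",
    "ConfigurationError",
    "butterworth_lowpass",
    "resample_linear",
    "resultant",
    "label_phases",
]

#: Fixed cyclic order of the four gait phases.
PHASE_ORDER: tuple[str, str, str, str] = ("LR", "PO", "Swing", "TSw")

#: Cyclic successor map LR -> PO -> Swing -> TSw -> LR.
SUCCESSOR: dict[str, str] = {
    "LR": "PO",
    "PO": "Swing",
    "Swing": "TSw",
    "TSw": "LR",
}

#: Sentinel for samples outside any annotated stride.
UNLABELLED: str = ""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid parameter or configuration value."""


class PhaseLabel(str, enum.Enum):
    """One of the four gait phases of a stride."""

    LR = "LR"
    PO = "PO"
    SWING = "Swing"
    TSW = "TSw"

    @property
    def successor(self) -> "PhaseLabel":
        """Next phase in the fixed gait cycle."""
        return PhaseLabel(SUCCESSOR[self.value])


def butterworth_lowpass(
    signal: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``), doubling
    the effective order of attenuation and cancelling phase delay.

    Parameters
    ----------
    signal
        1-D input signal.
    sample_rate_hz
        Sampling rate in Hz.
    cutoff_hz
        -3 dB cut-off frequency (per pass), default 10 Hz.
    order
        Filter order per pass, default 4.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InputError("butterworth_lowpass expects a 1-D signal")
    if sample_rate_hz <= 0:
        raise ConfigurationError("sample_rate_hz must be positive")
    if not cutoff_hz < sample_rate_hz / 2.0:
        raise ConfigurationError(
            f"cutoff ({cutoff_hz} Hz) must be below Nyquist "
            f"({sample_rate_hz / 2.0} Hz)"
        )
    if x.size <= 3 * order:
        raise InputError(
            f"signal too short ({x.size} samples) for order-{order} filtering"
        )
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    return _sig.sosfiltfilt(sos, x)


def resample_linear(
    signal: np.ndarray, from_hz: float, to_hz: float = 200.0
) -> np.ndarray:
    """Resample a uniformly sampled signal by linear interpolation.

    The first sample is preserved exactly; the output grid runs at
    ``to_hz`` over the same duration as the input.
    """
    x = np.asarray(signal, dtype=float)
    if from_hz <= 0 or to_hz <= 0:
        raise ConfigurationError("sampling rates must be positive")
    if x.ndim != 1 or x.size < 2:
        raise InputError("resample_linear needs at least 2 samples")
    if from_hz == to_hz:
        return x.copy()
    t_old = np.arange(x.size) / from_hz
    duration = t_old[-1]
    n_new = int(np.floor(duration * to_hz)) + 1
    t_new = np.arange(n_new) / to_hz
    return np.interp(t_new, t_old, x)


def resultant(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Elementwise vector magnitude ``sqrt(ax^2 + ay^2 + az^2)``.

    Used to collapse the three axes of angular velocity or acceleration
    into one orientation-free magnitude channel.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (ax.shape == ay.shape == az.shape):
        raise InputError("resultant requires equal-length channels")
    return np.sqrt(ax * ax + ay * ay + az * az)


def label_phases(annotations: Sequence, n_samples: int) -> np.ndarray:
    """Per-sample phase labels from ordered stride annotations.

    Returns an object array of length ``n_samples`` holding ``"LR"``,
    ``"PO"``, ``"Swing"``, ``"TSw"`` or :data:`UNLABELLED` for samples
    outside every stride.

    Raises
    ------
    InputError
        If annotations overlap, are unordered, or index outside the
        signal.
    """
    labels = np.full(n_samples, UNLABELLED, dtype=object)
    prev_end = -1
    for ann in annotations:
        idx = (
            ann.initial_contact,
            ann.mid_stance,
            ann.foot_off,
            ann.max_knee_flexion,
            ann.next_initial_contact,
        )
        if any(i < 0 or i > n_samples for i in idx) or idx[-1] > n_samples:
            raise InputError(f"annotation indices {idx} outside [0, {n_samples}]")
        if not all(a < b for a, b in zip(idx, idx[1:])):
            raise InputError(f"annotation events not strictly increasing: {idx}")
        if ann.initial_contact < prev_end:
            raise InputError("annotations overlap or are unordered")
        prev_end = ann.next_initial_contact
        bounds = idx
        for phase, (a, b) in zip(PHASE_ORDER, zip(bounds, bounds[1:])):
            labels[a:b] = phase
    return labels
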