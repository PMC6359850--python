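"""Transition Sequence Verification and Correction (TSVC).

A streaming post-classifier that enforces the cyclic gait-phase order
``LR -> PO -> Swing -> TSw -> LR`` on a stream of per-window phase
predictions and removes isolated misclassifications.

Two rules operate on a history of the last three accepted labels:

* **Rule A** — if the three history labels are identical and the
  incoming label is neither that label nor its successor in the cycle,
  the incoming label is an impossible jump and is relabelled to the
  history label (e.g. ``LR, LR, LR, Swing`` becomes ``LR, LR, LR, LR``).
* **Rule B** — if the incoming label *is* the successor, it may still be
  an isolated outlier rather than a real transition, so it is held for
  one instance of lookahead.  If the next label returns to the history
  label the held instance was an outlier and is relabelled (e.g.
  ``LR, LR, LR, PO, LR`` becomes ``LR, LR, LR, LR, LR``); otherwise it
  is released unchanged, confirming the transition.

Labels are emitted in arrival order; after :meth:`TsvcState.flush` the
number of emitted labels equals the number consumed.  The only latency
is Rule B's single-instance lookahead (10 ms at the default 0.01-s
step).  With fewer than three accepted labels, or a non-uniform
three-label history, instances pass through uncorrected.

Phase transitions in a corrected stream double as gait-event detections:
``TSw -> LR`` marks initial contact, ``LR -> PO`` mid-stance,
``PO -> Swing`` foot-off and ``Swing -> TSw`` maximum knee flexion.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Iterable, Sequence

from .preprocess import PHASE_ORDER, SUCCESSOR

__all__ = [
    "TransitionModel",
    "TsvcState",
    "tsvc_step",
    "tsvc_correct",
    "detect_events",
    "EVENT_OF_TRANSITION",
]

#: Canonical transition -> gait event map.
EVENT_OF_TRANSITION: dict[tuple[str, str], str] = {
    ("TSw", "LR"): "initial_contact",
    ("LR", "PO"): "mid_stance",
    ("PO", "Swing"): "foot_off",
    ("Swing", "TSw"): "max_knee_flexion",
}


@dataclasses.dataclass(frozen=True)
class TransitionModel:
    """The fixed cyclic phase sequence and its allowed transitions."""

    cycle: tuple[str, ...] = PHASE_ORDER

    def successor(self, phase: str) -> str:
        return SUCCESSOR[str(phase)]

    def allowed(self, prev: str, cur: str) -> bool:
        """A phase may persist or advance one step in the cycle."""
        return cur == prev or cur == self.successor(prev)


@dataclasses.dataclass
class TsvcState:
    """Streaming state: 3-label history plus Rule B's 1-instance buffer."""

    model: TransitionModel = dataclasses.field(default_factory=TransitionModel)
    history: deque = dataclasses.field(default_factory=lambda: deque(maxlen=3))
    pending: str | None = None
    emitted_count: int = 0

    def _emit(self, label: str, out: list[str]) -> None:
        out.append(label)
        self.history.append(label)
        self.emitted_count += 1

    def step(self, incoming) -> list[str]:
        """Consume one label; return the labels emitted by this step."""
        incoming = str(incoming)
        out: list[str] = []

        if self.pending is not None:
            held, self.pending = self.pending, None
            href = self.history[-1] if self.history else None
            if incoming == href:
                # isolated outlier between identical neighbours
                self._emit(href, out)
            else:
                self._emit(held, out)
            # fall through: incoming is processed against the updated history

        if len(self.history) == 3 and len(set(self.history)) == 1:
            ref = self.history[-1]
            if incoming == ref:
                self._emit(incoming, out)
            elif incoming == self.model.successor(ref):
                self.pending = incoming  # Rule B lookahead
            else:
                self._emit(ref, out)  # Rule A relabel
        else:
            # insufficient or unstable history: pass through unchanged
            self._emit(incoming, out)
        return out

    def flush(self) -> list[str]:
        """Release any pending instance unchanged at end of stream."""
        out: list[str] = []
        if self.pending is not None:
            held, self.pending = self.pending, None
            self._emit(held, out)
        return out


def tsvc_step(state: TsvcState, incoming) -> tuple[TsvcState, list[str]]:
    """Functional wrapper over :meth:`TsvcState.step` (mutates state)."""
    return state, state.step(incoming)


def tsvc_correct(labels: Iterable) -> list[str]:
    """Batch correction: fold the stream through TSVC and flush."""
    state = TsvcState()
    out: list[str] = []
    n = 0
    for lab in labels:
        n += 1
        out.extend(state.step(lab))
    out.extend(state.flush())
    assert len(out) == n, "TSVC must preserve stream length"
    return out


def detect_events(labels: Sequence) -> list[tuple[int, str]]:
    """Gait events at every phase change of a (corrected) label stream.

    Returns ``(sample_index, event_name)`` pairs where the index is the
    first sample of the new phase.  Transitions outside the canonical
    cycle are reported as ``"unexpected_transition"``.
    """
    events: list[tuple[int, str]] = []
    labels = [str(x) for x in labels]
    for i in range(1, len(labels)):
        prev, cur = labels[i - 1], labels[i]
        if cur != prev:
            name = EVENT_OF_TRANSITION.get((prev, cur), "unexpected_transition")
            events.append((i, name))
    return events
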