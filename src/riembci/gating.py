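"""Command gating: turn the per-epoch label/probability stream into discrete
game commands.

A command is emitted only when the classifier outputs the same label for
``n_consecutive`` epochs in a row, each with pseudo-probability above
``prob_floor`` (defaults N_e = 8, P_c = 0.3).  Two post-emission behaviors
are provided: ``reset`` (the streak restarts after each command, so a
sustained mental task emits at most one command per N_e epochs) and
``sliding`` (a plain sliding window over the last N_e epochs, allowing
overlapping emissions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

__all__ = ["GateConfig", "GateState", "gate_step", "gate_run"]


@dataclass
class GateConfig:
    n_consecutive: int = 8  # N_e
    prob_floor: float = 0.3  # P_c
    mode: str = "reset"  # "reset" | "sliding"

    def __post_init__(self) -> None:
        if self.n_consecutive < 1:
            raise ValueError("n_consecutive must be >= 1")
        if not 0 <= self.prob_floor < 1:
            raise ValueError("prob_floor must lie in [0, 1)")
        if self.mode not in ("reset", "sliding"):
            raise ValueError("mode must be 'reset' or 'sliding'")


@dataclass
class GateState:
    streak_label: Optional[str] = None
    streak_length: int = 0
    epoch_index: int = 0
    emitted_log: List[Tuple[int, str]] = field(default_factory=list)


def gate_step(state: GateState, cfg: GateConfig, label, probability: float) -> Optional[str]:
    """Advance the gate by one epoch; returns the emitted command, if any.

    An epoch extends the streak iff its label matches the current candidate
    and its probability strictly exceeds the floor; otherwise the streak
    restarts at this epoch (length 1 if the epoch itself qualifies, else 0 —
    a sub-floor probability breaks the streak entirely).
    """
    if not 0 <= probability <= 1:
        raise ValueError("probability must lie in [0, 1]")
    qualifies = probability > cfg.prob_floor
    if qualifies and label == state.streak_label:
        state.streak_length += 1
    elif qualifies:
        state.streak_label = label
        state.streak_length = 1
    else:
        state.streak_label = None
        state.streak_length = 0

    command = None
    if state.streak_length >= cfg.n_consecutive:
        command = state.streak_label
        state.emitted_log.append((state.epoch_index, command))
        if cfg.mode == "reset":
            state.streak_label = None
            state.streak_length = 0
        # sliding: keep the streak — the window re-fires while it lasts
    state.epoch_index += 1
    return command


def gate_run(stream: Iterable[Tuple[object, float]], cfg: GateConfig) -> List[Tuple[int, object]]:
    """Fold :func:`gate_step` over an ordered (label, probability) stream."""
    state = GateState()
    for label, prob in stream:
        gate_step(state, cfg, label, prob)
    return state.emitted_log
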