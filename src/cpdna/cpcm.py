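"""Competitive prediction context model (CPCM).

A binary-alphabet order-``k_c`` context model over the history of *which model
class* — 0 for the weighted context models, 1 for the weighted repeat models —
assigned the higher probability to each past base.  Before coding a base, the
class with the higher estimated probability given the last ``k_c`` winner bits
is selected and only that class's mixed distribution reaches the arithmetic
coder.  After the base is known, the actual winner (the class whose mixture
gave the true symbol more mass; ties go to class 0) is recorded and shifted
into the context.

Counts use the same 8-bit halve-on-saturation policy as the base-level
context models.  At the start of the sequence the context is zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fcm import COUNTER_MAX

CLASS_CM = 0
CLASS_RM = 1


@dataclass
class CPCMState:
    k_c: int
    alpha_c: float = 1.0
    counter_max: int = COUNTER_MAX

    def __post_init__(self):
        if not 1 <= self.k_c <= 24:
            raise ValueError("k_c must be in 1..24")
        if self.alpha_c <= 0:
            raise ValueError("alpha_c must be positive")
        self.counts = bytearray(2 ** (self.k_c + 1))
        self.context = 0
        self.mask = (1 << self.k_c) - 1


def cpcm_select(state: CPCMState) -> int:
    """Class whose estimated probability given the winner-bit context is
    higher; ties select the context-model class."""
    base = state.context * 2
    c0 = state.counts[base]
    c1 = state.counts[base + 1]
    den = c0 + c1 + 2.0 * state.alpha_c
    p0 = (c0 + state.alpha_c) / den
    p1 = (c1 + state.alpha_c) / den
    return CLASS_RM if p1 > p0 else CLASS_CM


def cpcm_record(state: CPCMState, winner: int) -> None:
    """Count the winner under the current context, then shift it in."""
    base = state.context * 2
    if state.counts[base + winner] >= state.counter_max:
        state.counts[base] //= 2
        state.counts[base + 1] //= 2
    state.counts[base + winner] += 1
    state.context = ((state.context << 1) | winner) & state.mask


def determine_winner(p_cm_true: float, p_rm_true: float) -> int:
    """Class that gave the true symbol more probability mass this step."""
    return CLASS_RM if p_rm_true > p_cm_true else CLASS_CM
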