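"""Soft blending of expert distributions with per-expert forgetting factors.

Both model classes (context models and repeat models) combine their members
the same way.  With per-expert weights :math:`w_m` summing to one, the blended
probability of symbol :math:`x` is

    P(x) = sum_m w_m * P_m(x)

and after the true symbol is revealed each weight is refreshed as

    w_m  <-  (w_m)^{gamma_m} * P_m(x_true),   then renormalised,

where ``gamma_m`` in [0, 1) is the forgetting factor: at 0 the weights track
only the last step's performance, near 1 they integrate performance over a
long horizon.  Weights are floored at 1e-12 before normalisation so that no
expert is ever permanently silenced by underflow.

The update order is: raise the old weight to gamma, multiply by the expert's
probability of the true symbol, floor, normalise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

WEIGHT_FLOOR = 1e-12


@dataclass
class MixState:
    """Per-expert mixing weights and forgetting factors."""

    weights: list[float]
    gammas: list[float]

    def __post_init__(self):
        if len(self.weights) != len(self.gammas):
            raise ValueError("weights and gammas must have equal length")
        for g in self.gammas:
            if not 0.0 <= g < 1.0:
                raise ValueError(f"gamma {g} outside [0, 1)")

    @classmethod
    def uniform(cls, gammas: list[float]) -> "MixState":
        n = len(gammas)
        return cls(weights=[1.0 / n] * n, gammas=list(gammas))


def mix(dists: list[list[float]], state: MixState) -> list[float]:
    """Blend expert distributions with the current weights."""
    if len(dists) != len(state.weights):
        raise ValueError("number of distributions does not match weights")
    out = [0.0, 0.0, 0.0, 0.0]
    for w, d in zip(state.weights, dists):
        for s in range(4):
            out[s] += w * d[s]
    return out


def update_weights(state: MixState, p_true: list[float]) -> None:
    """Refresh weights in place given each expert's probability of the true
    symbol; guarded reset to uniform if everything underflows to zero."""
    if len(p_true) != len(state.weights):
        raise ValueError("p_true length does not match weights")
    w = state.weights
    total = 0.0
    for m in range(len(w)):
        u = (w[m] ** state.gammas[m]) * p_true[m]
        if u < WEIGHT_FLOOR:
            u = WEIGHT_FLOOR
        w[m] = u
        total += u
    if total <= 0.0:  # unreachable with the floor, kept as a guard
        for m in range(len(w)):
            w[m] = 1.0 / len(w)
        return
    for m in range(len(w)):
        w[m] /= total
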