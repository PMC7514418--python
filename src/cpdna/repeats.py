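"""Weighted stochastic repeat models (copy experts).

A repeat model is a pointer into the already-coded sequence that predicts the
next base as the base at the pointer (or its complement, for an inverted
repeat walked backwards).  Pointers are spawned when the current ``k_r``-mer
has been seen before: a hash table maps each past ``k_r``-mer to the positions
*following* its occurrences (bounded per k-mer, FIFO replacement), and one of
the stored positions is chosen uniformly at random with the shared, seeded
codec RNG — "stochastic" because no index has to be transmitted: the
decompressor replays the identical draw.  At most ``rpn`` instances per model
group are active at once.

Each instance scores itself with a beta-like hit estimator

    q = (hits + a_hit) / (hits + fails + a_hit + a_miss)

and predicts ``q`` for the base at its pointer and ``(1-q)/3`` for the other
three.  An instance is switched off when ``q`` drops below
``deactivate_below`` or its pointer leaves the coded region; the slot becomes
reusable on the next step.  Active instances are blended with the same
weighted mechanism as the context models, with a deliberately small shared
forgetting factor so the class adapts within a few bases.

The spawn attempt for a position runs *before* that position is added to the
index, so a pointer always addresses strictly-past sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .mixer import MixState, mix, update_weights
from .rng import PortableRNG
from .sequence_io import COMPLEMENT_CODE


@dataclass(frozen=True)
class RepeatConfig:
    """One group of stochastic repeat models sharing a k-mer index."""

    k_r: int = 8
    rpn: int = 16
    a_hit: int = 1
    a_miss: int = 3
    deactivate_below: float = 0.4
    gamma_r: float = 0.1
    ir_enabled: bool = True
    max_positions_per_kmer: int = 16

    def __post_init__(self):
        if self.rpn < 1:
            raise ValueError("rpn must be >= 1")
        if self.k_r < 4:
            raise ValueError("k_r must be >= 4")
        if not 0.0 < self.deactivate_below < 1.0:
            raise ValueError("deactivate_below must be in (0, 1)")
        if not 0.0 <= self.gamma_r < 1.0:
            raise ValueError("gamma_r must be in [0, 1)")
        if self.a_hit <= 0 or self.a_miss <= 0:
            raise ValueError("pseudo-counts must be positive")
        if self.max_positions_per_kmer < 1:
            raise ValueError("max_positions_per_kmer must be >= 1")


class KmerIndex:
    """k-mer -> bounded FIFO list of positions following past occurrences."""

    def __init__(self, bound: int):
        self.bound = bound
        self._map: dict[int, list[int]] = {}

    def add(self, kmer: int, pos: int) -> None:
        lst = self._map.setdefault(kmer, [])
        if len(lst) >= self.bound:
            lst.pop(0)
        lst.append(pos)

    def positions(self, kmer: int) -> list[int]:
        return self._map.get(kmer, [])


FORWARD = 0
INVERTED = 1


class RepeatInstance:
    """One active copy pointer."""

    __slots__ = ("pointer", "hits", "fails", "orientation", "weight", "active",
                 "predicted")

    def __init__(self, pointer: int, orientation: int, weight: float = 0.0):
        self.pointer = pointer
        self.hits = 0
        self.fails = 0
        self.orientation = orientation
        self.weight = weight
        self.active = True
        self.predicted = -1

    def q(self, cfg: RepeatConfig) -> float:
        return float(self.hits + cfg.a_hit) / float(
            self.hits + self.fails + cfg.a_hit + cfg.a_miss
        )


def repeat_predict(inst: RepeatInstance, codes, cfg: RepeatConfig) -> list[float]:
    """Distribution of one instance; deactivates on an out-of-range pointer."""
    n_coded = len(codes)
    if inst.pointer < 0 or inst.pointer >= n_coded:
        inst.active = False
        inst.predicted = -1
        return [0.25, 0.25, 0.25, 0.25]
    g = int(codes[inst.pointer])
    if inst.orientation == INVERTED:
        g = COMPLEMENT_CODE[g]
    inst.predicted = g
    q = inst.q(cfg)
    rest = (1.0 - q) / 3.0
    d = [rest, rest, rest, rest]
    d[g] = q
    return d


def repeat_update(inst: RepeatInstance, actual_sym: int, cfg: RepeatConfig) -> None:
    """Tally the outcome, advance the pointer, apply the switch-off rule."""
    if not inst.active:
        return
    if inst.predicted == actual_sym:
        inst.hits += 1
    else:
        inst.fails += 1
    inst.pointer += 1 if inst.orientation == FORWARD else -1
    if inst.q(cfg) < cfg.deactivate_below or inst.pointer < 0:
        inst.active = False


class RepeatModelGroup:
    """Index + instance pool + spawn logic for one repeat configuration."""

    def __init__(self, cfg: RepeatConfig):
        self.cfg = cfg
        self.index = KmerIndex(cfg.max_positions_per_kmer)
        self.instances: list[RepeatInstance] = []
        self.kmer = 0
        self.rc_kmer = 0
        self.mask = (1 << (2 * cfg.k_r)) - 1

    def active_instances(self) -> list[RepeatInstance]:
        return [r for r in self.instances if r.active]

    def reap(self) -> None:
        self.instances = [r for r in self.instances if r.active]

    def try_spawn(self, kmer: int, rng: PortableRNG,
                  orientation: int = FORWARD) -> Optional[RepeatInstance]:
        """Spawn one instance from a uniformly drawn stored position, if the
        k-mer is known and a slot is free.  Consumes one RNG draw iff the
        position list is non-empty and a slot is free."""
        if len(self.instances) >= self.cfg.rpn:
            return None
        positions = self.index.positions(kmer)
        if not positions:
            return None
        p = positions[rng.below(len(positions))]
        if orientation == FORWARD:
            inst = RepeatInstance(p, FORWARD)
        else:
            ptr = p - self.cfg.k_r - 1
            if ptr < 0:
                return None
            inst = RepeatInstance(ptr, INVERTED)
        inst.weight = 1.0 / (len(self.instances) + 1)
        self.instances.append(inst)
        return inst

    def step_spawn_and_index(self, pos: int, sym: int, rng: PortableRNG) -> None:
        """Per-base bookkeeping after base ``sym`` was coded at ``pos``:
        roll the k-mers, attempt forward (then inverted) spawns, then record
        position ``pos + 1`` for the k-mer ending at ``pos``."""
        cfg = self.cfg
        self.kmer = ((self.kmer << 2) | sym) & self.mask
        self.rc_kmer = (COMPLEMENT_CODE[sym] << (2 * (cfg.k_r - 1))) | (self.rc_kmer >> 2)
        if pos + 1 < cfg.k_r:
            return
        self.try_spawn(self.kmer, rng, FORWARD)
        if cfg.ir_enabled:
            self.try_spawn(self.rc_kmer, rng, INVERTED)
        self.index.add(self.kmer, pos + 1)


def repeats_mixture(dists: list[list[float]], state: MixState) -> list[float]:
    """Blend active instance distributions; uniform when none are active."""
    if not dists:
        return [0.25, 0.25, 0.25, 0.25]
    return mix(dists, state)
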