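"""Deterministic synthetic DNA generator.

Produces sequences with the statistical structures each model class targets,
so the whole test suite runs without any external data:

* ``random``    — i.i.d. uniform ACGT background (the incompressible floor);
* ``tandem``    — a unit repeated back to back (exact tandem repeats);
* ``dispersed`` — random background with a unit copied over random windows
  (dispersed repeats);
* ``inverted``  — ``S || reverse_complement(S)`` (inverted repeats);
* ``mutated``   — a tandem array with i.i.d. point substitutions.

Any kind may additionally be mutated by setting ``sub_rate`` > 0.  All output
is a function of ``seed`` alone, via the same portable xorshift64* generator
the codec uses, so results reproduce across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rng import PortableRNG
from .sequence_io import BASES, pack, reverse_complement_codes, unpack, PackedSequence

KINDS = ("random", "tandem", "dispersed", "inverted", "mutated")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int
    unit_len: int = 50
    copies: int = 0
    sub_rate: float = 0.0
    seed: int = 0
    unit: str = ""  # explicit repeat unit (tandem/mutated) or S (inverted)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must be in [0, 1]")


def _random_codes(n: int, rng: PortableRNG) -> np.ndarray:
    return np.array([rng.below(4) for _ in range(n)], dtype=np.uint8)


def gen_codes(spec: FixtureSpec) -> np.ndarray:
    """Generate the fixture as an array of base codes of length exactly n."""
    rng = PortableRNG(spec.seed)
    n = spec.n
    kind = spec.kind
    explicit = pack(spec.unit).codes() if spec.unit else None
    if kind == "random":
        codes = _random_codes(n, rng)
    elif kind in ("tandem", "mutated"):
        unit = explicit if explicit is not None else _random_codes(spec.unit_len, rng)
        if spec.copies and unit.size * spec.copies > n:
            raise ValueError("unit_len * copies exceeds n")
        reps = -(-n // unit.size)
        codes = np.tile(unit, reps)[:n]
    elif kind == "dispersed":
        codes = _random_codes(n, rng)
        unit = explicit if explicit is not None else _random_codes(spec.unit_len, rng)
        copies = spec.copies or max(1, n // (4 * spec.unit_len))
        for _ in range(copies):
            if n <= spec.unit_len:
                start = 0
            else:
                start = rng.below(n - spec.unit_len)
            codes[start : start + spec.unit_len] = unit[: min(spec.unit_len, n - start)]
    elif kind == "inverted":
        s = explicit if explicit is not None else _random_codes(n // 2, rng)
        codes = np.concatenate([s, reverse_complement_codes(s)])[:n]
        if codes.size < n:
            codes = np.concatenate([codes, _random_codes(n - codes.size, rng)])
    else:  # pragma: no cover
        raise AssertionError(kind)
    rate = spec.sub_rate
    if kind == "mutated" and rate == 0.0:
        rate = 0.05  # the study condition for the mutated-repeat fixture
    if rate > 0.0:
        codes = mutate_codes(codes, rate, rng)
    return codes


def gen(spec: FixtureSpec) -> str:
    return unpack(PackedSequence(gen_codes(spec)))


def mutate_codes(codes: np.ndarray, sub_rate: float, rng: PortableRNG) -> np.ndarray:
    """Replace each base independently, with probability ``sub_rate``, by a
    uniformly chosen *different* base."""
    out = codes.copy()
    for i in range(out.size):
        if rng.unit() < sub_rate:
            out[i] = (int(out[i]) + 1 + rng.below(3)) % 4
    return out


def mutate(s: str, sub_rate: float, seed: int) -> str:
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be in [0, 1]")
    rng = PortableRNG(seed)
    codes = mutate_codes(pack(s).codes(), sub_rate, rng)
    return unpack(PackedSequence(codes))
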