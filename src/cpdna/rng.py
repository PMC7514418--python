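"""Portable deterministic 64-bit RNG shared by the codec and the fixture generator.

The compressor and decompressor must draw identical random numbers on any
platform, so the stochastic repeat spawning cannot rely on a library RNG whose
stream is not part of its stability contract.  We use the xorshift64* generator
(Vigna, 2016): state transition

    s ^= s >> 12;  s ^= (s << 25) & 2^64-1;  s ^= s >> 27;
    output = (s * 0x2545F4914F6CDD1D) mod 2^64

seeded through one round of the splitmix64 finaliser so that small integer
seeds (including 0) give well-mixed starting states.  The same transition is
re-implemented inside the numba kernel; `test_codec` asserts the streams agree.
"""

from __future__ import annotations

MASK64 = 0xFFFFFFFFFFFFFFFF

_SPLITMIX_GAMMA = 0x9E3779B97F4A7C15
_XS_MULT = 0x2545F4914F6CDD1D


def splitmix64(x: int) -> int:
    """One splitmix64 step; used for seeding and for hashing integer keys."""
    x = (x + _SPLITMIX_GAMMA) & MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & MASK64
    return x ^ (x >> 31)


def seed_state(seed: int) -> int:
    """Map an arbitrary 64-bit seed to a nonzero xorshift64* state."""
    s = splitmix64(seed & MASK64)
    return s if s != 0 else _SPLITMIX_GAMMA


def next_u64(state: int) -> tuple[int, int]:
    """Advance the generator; returns (new_state, output)."""
    s = state & MASK64
    s ^= s >> 12
    s ^= (s << 25) & MASK64
    s ^= s >> 27
    return s, (s * _XS_MULT) & MASK64


class PortableRNG:
    """Stateful wrapper around the xorshift64* transition."""

    def __init__(self, seed: int):
        self.state = seed_state(seed)

    def next_u64(self) -> int:
        self.state, out = next_u64(self.state)
        return out

    def below(self, n: int) -> int:
        """Uniform-ish integer in [0, n) via modulo reduction.

        The modulo bias for the tiny n used here (position-list lengths,
        alphabet size) is < 2^-59 and, more importantly, the draw is identical
        on both codec sides, which is the property that matters.
        """
        if n <= 0:
            raise ValueError("n must be positive")
        return self.next_u64() % n

    def unit(self) -> float:
        """Float in [0, 1) with 53 random bits."""
        return (self.next_u64() >> 11) * (1.0 / (1 << 53))
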