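"""Integer range coder over 4-symbol distributions.

The modelling side produces IEEE-double distributions; before coding they are
quantised to integer frequencies summing to exactly ``2^16`` (largest-
remainder rounding, every frequency at least 1, ties broken by symbol code
order).  The coder itself is integer-only — a carry-counting byte-oriented
range coder in the LZMA tradition with 32-bit range, 64-bit low and byte-wise
renormalisation at ``2^24`` — so the emitted bitstream is a pure function of
the frequency-table sequence and is identical on any platform.

Coding cost is within a fraction of a bit per symbol of the ideal
``-log2(f_sym / 2^16)`` plus a constant flush overhead (≤ 6 bytes/stream).
"""

from __future__ import annotations

TOTAL_BITS = 16
TOTAL = 1 << TOTAL_BITS          # frequency tables always sum to 2^16
TOP = 1 << 24                    # renormalisation threshold
MASK32 = 0xFFFFFFFF


def quantize(d) -> tuple[int, int, int, int]:
    """Largest-remainder quantisation of a 4-symbol distribution to integer
    frequencies with ``sum == 2^16`` and ``min >= 1``.

    Ties are broken deterministically by symbol code order: additions go to
    the lowest-index symbol among equal remainders, removals to the
    lowest-index eligible symbol among equal remainders.
    """
    f = [0, 0, 0, 0]
    r = [0.0, 0.0, 0.0, 0.0]
    total = 0
    for s in range(4):
        x = d[s] * TOTAL
        fs = int(x)
        rs = x - fs
        if fs < 1:
            fs = 1
            rs = -1.0          # a clamped-up symbol never also gains the +1
        f[s] = fs
        r[s] = rs
        total += fs
    while total < TOTAL:
        best = -1
        for s in range(4):
            if r[s] > -0.5 and (best < 0 or r[s] > r[best]):
                best = s
        f[best] += 1
        r[best] = -1.0
        total += 1
    while total > TOTAL:
        best = -1
        for s in range(4):
            if f[s] > 1 and (best < 0 or r[s] < r[best]):
                best = s
        f[best] -= 1
        r[best] = 2.0          # do not take twice from the same symbol first
        total -= 1
    return (f[0], f[1], f[2], f[3])


class RangeEncoder:
    def __init__(self):
        self.low = 0            # 33+ bit accumulator (python int)
        self.range = MASK32
        self.cache = 0
        self.cache_size = 1     # the first shifted byte is a leading zero
        self.out = bytearray()

    def _shift_low(self):
        if self.low < 0xFF000000 or self.low > MASK32:
            carry = self.low >> 32
            self.out.append((self.cache + carry) & 0xFF)
            while self.cache_size > 1:
                self.out.append((0xFF + carry) & 0xFF)
                self.cache_size -= 1
            self.cache = (self.low >> 24) & 0xFF
            self.cache_size = 0
        self.cache_size += 1
        self.low = (self.low << 8) & MASK32

    def encode(self, sym: int, freqs) -> None:
        cum = 0
        for s in range(sym):
            cum += freqs[s]
        r = self.range >> TOTAL_BITS
        self.low += cum * r
        self.range = freqs[sym] * r
        while self.range < TOP:
            self._shift_low()
            self.range = (self.range << 8) & MASK32

    def flush(self) -> bytes:
        for _ in range(5):
            self._shift_low()
        return bytes(self.out)


class RangeDecoder:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0
        self.range = MASK32
        self.code = 0
        self._next_byte()  # leading zero byte from the encoder cache
        for _ in range(4):
            self.code = ((self.code << 8) | self._next_byte()) & MASK32

    def _next_byte(self) -> int:
        if self.pos < len(self.data):
            b = self.data[self.pos]
            self.pos += 1
            return b
        return 0  # tolerate the flush tail; framing is checked by length

    def decode(self, freqs) -> int:
        r = self.range >> TOTAL_BITS
        dv = self.code // r
        if dv >= TOTAL:
            dv = TOTAL - 1
        cum = 0
        sym = 0
        while sym < 3 and cum + freqs[sym] <= dv:
            cum += freqs[sym]
            sym += 1
        self.code -= cum * r
        self.range = freqs[sym] * r
        while self.range < TOP:
            self.code = ((self.code << 8) | self._next_byte()) & MASK32
            self.range = (self.range << 8) & MASK32
        return sym
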