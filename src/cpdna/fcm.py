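"""Finite context models over the 4-letter DNA alphabet.

An order-``k`` context model keeps 8-bit counts ``c(s | ctx)`` of each base
``s`` following each ``k``-mer context and predicts with the Laplace-style
estimator

    P(s | ctx) = (c(s|ctx) + alpha) / (sum_s' c(s'|ctx) + 4*alpha),

where ``alpha`` interpolates between the uniform distribution (large alpha)
and the raw frequency distribution (alpha -> 0).  Counts saturate at 255: when
an increment would overflow, all four counters of that context are halved
(integer division) first, which preserves their ordering and keeps old
statistics decaying rather than frozen.

Storage is either a dense table of ``4^(k+1)`` counters or, for deep contexts
where that is impossibly sparse, a bounded cache-hash: a power-of-two number
of buckets, each holding at most ``max_collisions`` exact k-mer keys with FIFO
replacement, so only the most recent contexts per bucket are remembered.

Inverted repeats are handled by a sub-program expressed in two pieces:

* the *IR event*: after coding ``x_i`` with window ``x_{i-k..i}``, the counter
  at context ``revcomp(x_{i-k+1..i})`` for symbol ``complement(x_{i-k})`` is
  updated.  This is exactly what a forward pass over the reverse-complement
  strand would record, so a model that stores both events sees both strands.
* the *IR query* (``ir_mode="ir_only"``): candidate ``s`` is scored by the
  count at context ``revcomp(x_{i-k+1..i-1} . s)`` for symbol
  ``complement(x_{i-k})``, then the four scores go through the same estimator.

``ir_mode="both"`` stores both events and predicts from the forward context;
``ir_only`` stores both events and predicts through the IR query; ``forward``
stores and predicts forward only.

A substitutional-tolerant context model (STCM) shares the counter store of a
same-order host model (single writer: the host updates, the STCM never does)
but maintains its own *edited* context: on a misprediction it may substitute
its own most probable symbol for the true one, up to ``max_subs`` times,
which keeps a deep context on track across point mutations.  A ring buffer of
the last ``l`` hit/fail outcomes gates the model: it is switched off (emits
the uniform distribution) while the window holds more than ``t`` fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .rng import splitmix64
from .sequence_io import COMPLEMENT_CODE

COUNTER_MAX = 255

IR_FORWARD = 0
IR_ONLY = 1
IR_BOTH = 2
_IR_NAMES = {"forward": IR_FORWARD, "ir_only": IR_ONLY, "both": IR_BOTH}


@dataclass(frozen=True)
class STCMConfig:
    """Substitutional-tolerant sub-model attached to a context model."""

    max_subs: int = 4
    t: int = 8
    l: int = 32

    def __post_init__(self):
        if self.max_subs < 1:
            raise ValueError("max_subs must be >= 1")
        if not 0 < self.t <= self.l:
            raise ValueError("need 0 < t <= l")
        if self.l > 63:
            raise ValueError("history window l is limited to 63")


@dataclass(frozen=True)
class CMConfig:
    """Configuration of one finite context model."""

    k: int
    alpha_num: int = 1
    alpha_den: int = 1
    gamma: float = 0.9
    ir_mode: str = "forward"
    storage: str = "auto"  # auto | table | cache_hash
    max_collisions: int = 4
    counter_max: int = COUNTER_MAX
    stcm: Optional[STCMConfig] = None

    def __post_init__(self):
        if not 1 <= self.k <= 24:
            raise ValueError("context order k must be in 1..24")
        if self.alpha_num <= 0 or self.alpha_den <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if self.ir_mode not in _IR_NAMES:
            raise ValueError(f"unknown ir_mode {self.ir_mode!r}")
        if self.storage not in ("auto", "table", "cache_hash"):
            raise ValueError(f"unknown storage {self.storage!r}")
        if self.max_collisions < 1:
            raise ValueError("max_collisions must be >= 1")

    @property
    def alpha(self) -> float:
        return self.alpha_num / self.alpha_den


class CounterStore:
    """Counter storage: dense table or bounded cache-hash.

    Both variants expose ``counts(ctx) -> (c0, c1, c2, c3)`` (a miss reads as
    all zeros) and ``increment(ctx, sym)`` with the halve-on-saturation
    policy.  The cache-hash buckets a 64-bit mix of the exact k-mer integer;
    inserting into a full bucket evicts its oldest entry (FIFO).
    """

    def __init__(self, k: int, storage: str, max_collisions: int = 4,
                 n_buckets: int = 1 << 16, counter_max: int = COUNTER_MAX):
        if storage not in ("table", "cache_hash"):
            raise ValueError(storage)
        if storage == "cache_hash" and n_buckets & (n_buckets - 1):
            raise ValueError("n_buckets must be a power of two")
        self.k = k
        self.storage = storage
        self.counter_max = counter_max
        self.max_collisions = max_collisions
        if storage == "table":
            self._table = bytearray(4 ** (k + 1))
        else:
            self.n_buckets = n_buckets
            # bucket -> list of [key, [c0..c3]] in insertion order
            self._buckets: dict[int, list[list]] = {}

    def _bucket_of(self, ctx: int) -> int:
        return splitmix64(ctx) & (self.n_buckets - 1)

    def counts(self, ctx: int) -> tuple[int, int, int, int]:
        if self.storage == "table":
            base = ctx * 4
            t = self._table
            return (t[base], t[base + 1], t[base + 2], t[base + 3])
        for key, c in self._buckets.get(self._bucket_of(ctx), ()):
            if key == ctx:
                return tuple(c)
        return (0, 0, 0, 0)

    def increment(self, ctx: int, sym: int) -> None:
        if self.storage == "table":
            base = ctx * 4
            t = self._table
            if t[base + sym] >= self.counter_max:
                for s in range(4):
                    t[base + s] //= 2
            t[base + sym] += 1
            return
        bucket = self._buckets.setdefault(self._bucket_of(ctx), [])
        for key, c in bucket:
            if key == ctx:
                if c[sym] >= self.counter_max:
                    for s in range(4):
                        c[s] //= 2
                c[sym] += 1
                return
        if len(bucket) >= self.max_collisions:
            bucket.pop(0)
        bucket.append([ctx, [0, 0, 0, 0]])
        bucket[-1][1][sym] = 1


def estimate(counts, alpha: float) -> list[float]:
    """The (c + alpha) / (C + 4 alpha) estimator; always strictly positive."""
    tot = counts[0] + counts[1] + counts[2] + counts[3]
    den = tot + 4.0 * alpha
    return [(counts[s] + alpha) / den for s in range(4)]


def cm_predict(store: CounterStore, ctx: int, alpha: float) -> list[float]:
    return estimate(store.counts(ctx), alpha)


def cm_update(store: CounterStore, ctx: int, sym: int) -> None:
    store.increment(ctx, sym)


def ir_event(window: list[int], k: int) -> tuple[int, int]:
    """Map a coded window ``x_{i-k..i}`` (k+1 base codes) to the equivalent
    reverse-complement-strand event ``(ir_context, ir_symbol)``."""
    if len(window) != k + 1:
        raise ValueError("window must hold k+1 symbols")
    tail = window[1:]
    ir_ctx = 0
    for s in reversed(tail):
        ir_ctx = (ir_ctx << 2) | COMPLEMENT_CODE[s]
    return ir_ctx, COMPLEMENT_CODE[window[0]]


class ContextModel:
    """Stateful order-k context model with incremental forward and
    reverse-complement contexts."""

    def __init__(self, cfg: CMConfig, store: Optional[CounterStore] = None,
                 n_buckets: int = 1 << 16):
        self.cfg = cfg
        self.k = cfg.k
        self.alpha = cfg.alpha
        self.ir = _IR_NAMES[cfg.ir_mode]
        self.mask = (1 << (2 * cfg.k)) - 1
        if store is None:
            storage = cfg.storage
            if storage == "auto":
                storage = "table" if cfg.k <= 8 else "cache_hash"
            store = CounterStore(cfg.k, storage, cfg.max_collisions,
                                 n_buckets=n_buckets, counter_max=cfg.counter_max)
        self.store = store
        self.ctx = 0        # last k symbols, zero (A) padded at start
        self.rc = 0         # reverse complement of the last k symbols
        self.seen = 0       # symbols consumed so far

    def predict(self) -> list[float]:
        if self.ir == IR_ONLY:
            scores = [0, 0, 0, 0]
            qsym = self.rc & 3
            head = self.rc >> 2
            for s in range(4):
                ctx_s = (COMPLEMENT_CODE[s] << (2 * (self.k - 1))) | head
                scores[s] = self.store.counts(ctx_s)[qsym]
            return estimate(scores, self.alpha)
        return cm_predict(self.store, self.ctx, self.alpha)

    def update(self, sym: int) -> None:
        rc_new = (COMPLEMENT_CODE[sym] << (2 * (self.k - 1))) | (self.rc >> 2)
        self.store.increment(self.ctx, sym)
        if self.ir != IR_FORWARD and self.seen >= self.k:
            self.store.increment(rc_new, self.rc & 3)
        self.ctx = ((self.ctx << 2) | sym) & self.mask
        self.rc = rc_new
        self.seen += 1

    def true_context(self) -> int:
        return self.ctx


class STCM:
    """Substitutional-tolerant view over a host context model's store."""

    def __init__(self, cfg: STCMConfig, host: ContextModel):
        self.cfg = cfg
        self.host = host
        self.k = host.k
        self.mask = host.mask
        self.ctx = 0                 # edited context
        self.subs_left = cfg.max_subs
        self.hist = 0                # bitmask, 1 = fail
        self.hist_len = 0
        self.fails = 0

    @property
    def active(self) -> bool:
        return self.fails <= self.cfg.t

    def belief(self) -> list[float]:
        """Ungated estimate from the shared memory at the edited context."""
        return cm_predict(self.host.store, self.ctx, self.host.alpha)

    def predict(self) -> list[float]:
        if not self.active:
            return [0.25, 0.25, 0.25, 0.25]
        return self.belief()

    def top_symbol(self) -> int:
        """Most probable symbol of the *ungated* belief (ties: lowest code).

        The hit/fail cache and the context-edit machinery track the belief
        even while the model is switched off; otherwise an inactive model
        would score its uniform fallback, never register hits, and could
        never switch back on.
        """
        d = self.belief()
        best = 0
        for s in range(1, 4):
            if d[s] > d[best]:
                best = s
        return best

    def update(self, true_sym: int, top_sym: int, host_ctx_old: int) -> None:
        """Record the outcome; ``host_ctx_old`` is the host's forward context
        *before* consuming ``true_sym`` (used to rebuild the true history)."""
        fail = 1 if top_sym != true_sym else 0
        if self.hist_len == self.cfg.l:
            oldest = (self.hist >> (self.cfg.l - 1)) & 1
            self.fails -= oldest
            self.hist = ((self.hist << 1) & ((1 << self.cfg.l) - 1)) | fail
        else:
            self.hist = (self.hist << 1) | fail
            self.hist_len += 1
        self.fails += fail

        if fail:
            if self.subs_left > 0:
                self.ctx = ((self.ctx << 2) | top_sym) & self.mask
                self.subs_left -= 1
            else:
                self.ctx = ((host_ctx_old << 2) | true_sym) & self.mask
                self.subs_left = self.cfg.max_subs
        else:
            self.ctx = ((self.ctx << 2) | true_sym) & self.mask
            if self.hist_len == self.cfg.l and self.fails == 0:
                self.subs_left = self.cfg.max_subs
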