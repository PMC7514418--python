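# Methods

## Model

The compressor codes one base at a time.  Per base, in a fixed order that
both codec sides replay identically:

1. every context model (CM) and substitutional-tolerant context model (STCM)
   predicts; the class distribution is the weight-blended mixture;
2. every active repeat pointer predicts; the class distribution is the
   weight-blended mixture (uniform if no pointer is active);
3. the competitive prediction context model (CPCM) selects one class from
   the history of past winners; the selected distribution is normalised,
   quantised to integer frequencies and the base is range-coded;
4. with the true base known: both classes' weights refresh
   (`w ← w^γ · P(true)`, floored at 1e-12, renormalised), CM counters update
   (forward event, and the inverted-repeat event for IR-enabled models),
   STCM edit states update, repeat pointers tally hit/fail, advance and
   possibly switch off, the actual winner is recorded into the CPCM, and
   each repeat group attempts spawns and then indexes the current k-mer.

Decompression runs the same loop with the range decoder in step 3; every
model decision is a function of already-decoded bases plus the header, so
the two sides stay synchronised by construction.  An instrumented mode
digests the full model state (contexts, weights, pointers, RNG state) every
N bases; the test suite asserts compressor and decompressor digests agree.

### Context models

`P(s|ctx) = (c + α)/(C + 4α)` with 8-bit counters; on saturation all four
counters of the context are halved before incrementing, which preserves
their ordering and ages old evidence.  Orders up to ~10 use a dense table;
deeper orders use a cache-hash: 2^b buckets × `max_collisions` exact-key
slots with FIFO replacement, so only the latest contexts per bucket are
kept.  The bucket count scales with the sequence length (between 2^10 and
2^22 buckets, about 8 per coded base), a pure function of header fields, so
both sides size memory identically.

Inverted repeats: after coding `x_i`, IR-enabled models also update the
counter at context `revcomp(x_{i-k+1..i})` for symbol `comp(x_{i-k})` —
exactly what a forward pass over the opposite strand would record.  Mode
`both` predicts from the forward context (and thus benefits from IR events
recorded earlier); mode `ir_only` predicts by querying candidate `s` at
context `comp(s)·rc[: k-1]` for symbol `rc[k-1]`, where `rc` is the running
reverse-complement context.  At the start of the sequence both the forward
and the reverse-complement contexts are A-padded; the padding convention is
internal and symmetric.

### Substitutional-tolerant context models

An STCM shares its host CM's counter store (single writer: only the host
updates it) but keeps a private, *edited* context.  Its **belief** is the
plain estimator at the edited context.  A hit/fail ring buffer of length `l`
scores the belief's top symbol against the truth; the model is switched off
while more than `t` of the last `l` outcomes were fails, in which case it
*emits* the uniform distribution.  The hit/fail cache always scores the
ungated belief: gating the score on the gated output would self-lock (an
inactive model would score its uniform fallback, never register hits, and
never reactivate).  On a fail with substitution budget left, the model
appends its own top symbol to the edited context (treating the observed
base as a likely point mutation) and spends one unit of budget; with the
budget exhausted, it resets the edited context to the true history and
restores the budget; a full window of hits also restores the budget.
Ties in the top symbol go to the lowest base code (A<C<G<T).

### Stochastic repeat models

A per-group hash index maps each `k_r`-mer to up to 16 positions *following*
its past occurrences (FIFO replacement).  After coding base `i`, if a slot
is free (at most `rpn` concurrent pointers per group) and the current
`k_r`-mer is indexed, one stored position is drawn uniformly with the shared
seeded RNG and a forward pointer starts there; with IR enabled the
reverse-complement k-mer is also looked up and may start a backward pointer
that emits complements.  The spawn attempt runs *before* the current
position is indexed, so a pointer always addresses strictly-past sequence
(self-reference is impossible by construction).  A deactivated pointer's
slot becomes reusable on the following base.

A pointer predicts the base at its position with probability
`q = (hits + a_hit)/(hits + fails + a_hit + a_miss)` and `(1−q)/3` for the
rest, and is switched off when `q < deactivate_below` (default 0.4) or the
pointer leaves the coded region.  The prior is deliberately pessimistic,
`(a_hit, a_miss) = (1, 3)`: a fresh pointer starts at `q = 1/4`, i.e. the
uniform distribution, and must earn confidence through hits.  With an
optimistic prior, chance k-mer matches in non-repetitive sequence would
inject confident wrong predictions, polluting both the coded stream and the
CPCM's winner history; with the uniform prior a spurious pointer is
(almost) free and dies after its first miss.

### Class selection and winner bookkeeping

The CPCM is a binary order-`k_c` context model over winner bits (0 =
context-model class, 1 = repeat class) with the same counter policy as the
CMs.  Because both class probabilities share a denominator, selection
reduces to comparing counts; ties select class 0.  The *winner* each step
is the class whose mixture put more mass on the true base (ties to class
0) — this is decodable, since the decoder knows the true base before the
bookkeeping step.

### Quantisation and coding

The selected distribution is quantised by largest-remainder rounding to
integer frequencies summing to exactly 2^16, each at least 1, with
deterministic tie-breaks by symbol code; the expected quantisation loss is
below 0.001 bits/base whenever every probability exceeds 1e-4.  The coder
is a carry-counting byte-oriented range coder (32-bit range, byte-wise
renormalisation at 2^24).  Since it consumes only integer frequencies, the
bitstream is a pure function of the frequency-table sequence.  Its overhead
over the ideal codelength `Σ −log2(f/2^16)` is ≤ ~48 bits of framing (one
leading byte plus a 5-byte flush) plus a range-truncation term of about
0.0003–0.0005 bits/base; on streams up to ~10 kb the total slack stays
under 64 bits.

### Determinism

All model arithmetic is IEEE-754 double precision executed in a fixed
order.  The stochastic spawning uses xorshift64\* seeded through splitmix64;
the seed travels in the header.  All real-valued parameters are serialised
as integer rationals/permille, so parsing the header reconstructs the exact
configuration.  The same pipeline exists twice — a numba-compiled engine
and a pure-Python engine composed from the module-level operations — and
the test suite asserts they emit byte-identical containers, which pins the
operation order against refactoring drift.

## Presets

Levels 1–15 grow monotonically in model count, maximum context order,
repeat budget (total rpn 8 → 72) and CPCM order (4 → 16).  Forgetting
factors follow the empirical pattern for this mixture type: shallow models
below 0.9, deep models at ~0.95, and the order-6 model — tracking the short
periodicities of DNA — at 0.80 within [0.75, 0.85].  Deep models get small
α (down to 1/64) so a single prior occurrence of a deep context yields a
near-certain prediction.  The CPCM order is 5 at level 2 and reaches 16 at
level 12, matching the observation that longer sequences support deeper
winner histories.

## Synthetic data

The fixture generator produces the structures each model class targets:
i.i.d. uniform background (the incompressibility floor), exact tandem
arrays (`unit^m`), dispersed copies in random background, inverted
constructs `S‖revcomp(S)`, and mutated tandem arrays with i.i.d.
substitutions (default 5%).  Everything derives from the same portable RNG
as the codec, so fixtures are bit-reproducible across platforms.  What the
generator does **not** emulate: base-composition skew, isochores, varying
repeat families, indels, and long-range correlations of real genomes.
Passing tests therefore demonstrate the mechanics of the models (copy
tracking, IR mapping, substitution tolerance, selector behaviour) and exact
losslessness, not field compression ratios on real genomes.

## Problem sizes

The test and acceptance runs use 100 kb fixtures for rate measurements
(floors stabilise to ±0.01 BPS at that size), 20 kb for the half-copy
selector fixture, and 1–2000 bp sequences for the all-preset losslessness
sweep.  These sizes exercise every code path, including cache-hash storage
(which engages for orders ≥ 11 at 100 kb) and the bounded position lists.

## Known limitations

* Orders above 24 and non-ACGT alphabets are unsupported; non-ACGT input
  characters are deleted (reported via `FilterReport`), not preserved.
* Multi-record FASTA is concatenated; headers, case and line structure are
  not preserved.
* The container format is this package's own; it is not byte-compatible
  with other genomic compressors.
* On exact long repeats, deep context models already capture most of the
  structure, so the repeat class's measured advantage concentrates on
  copies longer than the deepest context and on configurations without
  deep low-α models.
* Single-threaded by design: the per-base state is a strict chain.
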