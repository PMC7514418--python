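import dataclasses
import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdna import (CMConfig, CodecConfig, FixtureSpec, RepeatConfig,
                   STCMConfig, codec, gen, pack, presets, unpack)

SMALL_CFG = CodecConfig(
    cms=(CMConfig(k=2, gamma=0.6),
         CMConfig(k=5, gamma=0.85, ir_mode="both",
                  stcm=STCMConfig(max_subs=2, t=4, l=16))),
    rms=(RepeatConfig(k_r=5, rpn=4),),
    k_c=5, seed=77)


def fixture_seq(kind, n, seed):
    return pack(gen(FixtureSpec(kind, n, unit_len=20, seed=seed)))


class TestHeader:
    def test_round_trip(self):
        blob = codec.serialize_header(SMALL_CFG, 1234)
        cfg, n, flags, off = codec.parse_header(blob + b"payload")
        assert cfg == SMALL_CFG and n == 1234 and flags == 0
        assert codec.serialize_header(cfg, n) == blob

    def test_bad_magic(self):
        with pytest.raises(ValueError, match="magic"):
            codec.parse_header(b"XXXX" + bytes(40))

    def test_checksum_detects_tamper(self):
        blob = bytearray(codec.serialize_header(SMALL_CFG, 1234))
        blob[10] ^= 0x40
        with pytest.raises(ValueError):
            codec.parse_header(bytes(blob))

    def test_level_presets_serialize_exactly(self):
        for level in presets.LEVELS:
            cfg = presets.level_preset(level, seed=3)
            blob = codec.serialize_header(cfg, 999)
            cfg2, _, _, _ = codec.parse_header(blob + b"")
            assert cfg2 == cfg


class TestRoundTrip:
    @pytest.mark.parametrize("s", ["A", "C", "G", "T", "ACGT", "AAAAAAAAAA"])
    def test_tiny_sequences(self, s):
        seq = pack(s)
        assert unpack(codec.decompress(codec.compress(seq, SMALL_CFG))) == s

    @given(st.text(alphabet="ACGT", min_size=1, max_size=300),
           st.integers(0, 2 ** 32))
    @settings(max_examples=40, deadline=None)
    def test_random_sequences(self, s, seed):
        cfg = dataclasses.replace(SMALL_CFG, seed=seed)
        seq = pack(s)
        assert codec.decompress(codec.compress(seq, cfg)) == seq

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            codec.compress(pack(""), SMALL_CFG)

    def test_homopolymer_all_presets(self):
        seq = pack("A" * 500)
        for level in presets.LEVELS:
            cfg = presets.level_preset(level, seed=1)
            assert codec.decompress(codec.compress(seq, cfg)) == seq


class TestEnginesAgree:
    """The pure-Python pipeline built from the module-level operations and
    the compiled engine must produce byte-identical containers."""

    @pytest.mark.parametrize("kind", ["random", "tandem", "inverted",
                                      "mutated"])
    def test_containers_identical(self, kind):
        seq = fixture_seq(kind, 700, seed=5)
        b_py = codec.compress(seq, SMALL_CFG, engine="python")
        b_nb = codec.compress(seq, SMALL_CFG, engine="numba")
        assert b_py == b_nb
        assert codec.decompress(b_nb, engine="python") == seq

    def test_checkpoint_checksums_identical(self):
        seq = fixture_seq("mutated", 1200, seed=6)
        cfg = presets.level_preset(5, seed=9)
        _, _, ck_py = codec.compress_report(seq, cfg, engine="python",
                                            ckpt_interval=250)
        _, _, ck_nb = codec.compress_report(seq, cfg, engine="numba",
                                            ckpt_interval=250)
        assert ck_py == ck_nb and len(ck_py) == 4


class TestDeterminismAndSync:
    def test_identical_runs_identical_bytes(self):
        seq = fixture_seq("dispersed", 2000, seed=8)
        cfg = presets.level_preset(6, seed=123)
        h1 = hashlib.sha256(codec.compress(seq, cfg)).hexdigest()
        h2 = hashlib.sha256(codec.compress(seq, cfg)).hexdigest()
        assert h1 == h2

    def test_seed_changes_repeat_trajectory_but_not_losslessness(self):
        seq = fixture_seq("tandem", 3000, seed=2)
        for seed in (0, 1, 2 ** 63):
            cfg = dataclasses.replace(presets.level_preset(4), seed=seed)
            assert codec.decompress(codec.compress(seq, cfg)) == seq

    def test_compressor_decompressor_state_checksums_agree(self):
        seq = fixture_seq("mutated", 20_000, seed=10)
        cfg = presets.level_preset(7, seed=5)
        blob, _, ck_enc = codec.compress_report(seq, cfg, ckpt_interval=2500)
        out, ck_dec = codec.decompress_with_checksums(blob,
                                                      ckpt_interval=2500)
        assert out == seq
        assert ck_enc == ck_dec and len(ck_enc) == 8


class TestTamper:
    def test_payload_crc_detects_header_seed_flip(self):
        # dispersed repeats: stored positions have genuinely different
        # continuations, so the spawn RNG trajectory is observable
        seq = pack(gen(FixtureSpec("dispersed", 1500, unit_len=40, copies=6,
                                   seed=3)))
        blob = bytearray(codec.compress(seq, SMALL_CFG, payload_crc=True))
        # flip the stored seed and fix up the header CRC
        cfg, n, flags, off = codec.parse_header(bytes(blob))
        tampered = dataclasses.replace(cfg, seed=cfg.seed ^ 1)
        new_header = codec.serialize_header(tampered, n, flags)
        forged = new_header + bytes(blob[off:])
        with pytest.raises(ValueError, match="checksum"):
            codec.decompress(forged)

    def test_truncation_detected(self):
        seq = fixture_seq("random", 400, seed=3)
        blob = codec.compress(seq, SMALL_CFG, payload_crc=True)
        with pytest.raises(ValueError):
            codec.decompress(blob[:20])


class TestPresets:
    def test_monotone_resources(self):
        counts, max_ks, rpns, kcs = [], [], [], []
        for level in presets.LEVELS:
            cfg = presets.level_preset(level)
            n_st = sum(1 for c in cfg.cms if c.stcm is not None)
            counts.append(len(cfg.cms) + n_st + len(cfg.rms))
            max_ks.append(max(c.k for c in cfg.cms))
            rpns.append(sum(r.rpn for r in cfg.rms))
            kcs.append(cfg.k_c)
        for seq in (counts, max_ks, rpns, kcs):
            assert all(a <= b for a, b in zip(seq, seq[1:]))

    def test_out_of_range_level(self):
        for bad in (0, 16, -1):
            with pytest.raises(ValueError):
                presets.level_preset(bad)

    def test_all_presets_have_both_classes(self):
        for level in presets.LEVELS:
            cfg = presets.level_preset(level)
            assert cfg.cms and cfg.rms


class TestReport:
    def test_metrics_sanity(self, half_copy_20kb):
        rep = codec.report(half_copy_20kb, presets.level_preset(5, seed=1))
        assert 0 < rep.bps <= 8
        assert rep.payload_bytes < rep.total_bytes
        assert 0 <= rep.select_rm_frac <= 1
        assert abs(sum(rep.final_cm_weights) - 1) < 1e-9
        # payload is within the coder slack of the logged ideal codelength
        assert abs(8 * rep.payload_bytes - rep.ideal_bits) <= 64

    def test_config_requires_a_model(self):
        with pytest.raises(ValueError):
            CodecConfig(cms=(), rms=())


def brute_force_cm_class(s_codes, cfgs, alpha, gammas):
    """Independent reimplementation of the context-model class: dict-based
    counters rebuilt with string keys plus the two-line weight recursion."""
    import math
    from collections import defaultdict

    counts = [defaultdict(lambda: [0, 0, 0, 0]) for _ in cfgs]
    w = [1.0 / len(cfgs)] * len(cfgs)
    hist = []
    out = []
    for i, sym in enumerate(s_codes):
        dists = []
        for m, k in enumerate(cfgs):
            ctx = tuple(([0] * k + hist)[-k:])
            c = counts[m][ctx]
            tot = sum(c) + 4.0 * alpha
            dists.append([(c[x] + alpha) / tot for x in range(4)])
        mixp = [sum(w[m] * dists[m][x] for m in range(len(cfgs)))
                for x in range(4)]
        out.append(mixp[sym])
        u = [max(w[m] ** gammas[m] * dists[m][sym], 1e-12)
             for m in range(len(cfgs))]
        tu = sum(u)
        w = [x / tu for x in u]
        for m, k in enumerate(cfgs):
            ctx = tuple(([0] * k + hist)[-k:])
            counts[m][ctx][sym] += 1
        hist.append(sym)
    return out


def test_full_cm_mixture_matches_brute_force_oracle():
    """Engine-logged class-0 probabilities of the true base equal an
    independent dict-based recount with the weight recursion, k <= 3."""
    seq = fixture_seq("random", 64, seed=14)
    ks = [1, 3]
    gammas = [0.6, 0.8]
    cfg = CodecConfig(
        cms=tuple(CMConfig(k=k, gamma=g, storage="table")
                  for k, g in zip(ks, gammas)),
        rms=(), k_c=4, seed=0)
    res = codec.run_details(seq, cfg)
    expect = brute_force_cm_class(list(seq.codes()), ks, 1.0, gammas)
    assert np.allclose(res.p_cm, expect, atol=1e-12)


def test_every_single_base_round_trips_on_every_preset():
    for base in "ACGT":
        seq = pack(base)
        for level in presets.LEVELS:
            cfg = presets.level_preset(level, seed=2)
            assert unpack(codec.decompress(codec.compress(seq, cfg))) == base
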