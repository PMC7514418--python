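"""Compression/decompression orchestration and the container format.

The per-base pipeline is: both model classes predict, the competitive
prediction context model selects one class, the selected distribution is
quantised and the base range-coded; afterwards every model updates with the
true base.  Compressor and decompressor run the identical pipeline in the
identical order, so the decoder reconstructs every model decision from the
bases it has already decoded — the only side information is the header.

Container layout (all integers little-endian)::

    magic "CPD1" | version u8 | flags u8
    sequence length u64 | RNG seed u64
    n_cm u8, then per context model:
        k u8 | alpha_num u32 | alpha_den u32 | gamma_permille u16 | ir u8
        | max_collisions u8 | has_stcm u8 [| max_subs u8 | t u8 | l u8]
    n_rm u8, then per repeat group:
        k_r u8 | rpn u16 | a_hit u16 | a_miss u16 | deact_permille u16
        | gamma_permille u16 | ir u8 | max_positions u8
    k_c u8 | alpha_c_num u32 | alpha_c_den u32
    header crc32 u32
    payload bytes
    [crc32 of the decoded base stream, if flags bit 0]

Real-valued parameters travel as integer rationals/permille so the header is
platform-exact.  Model memory is sized from the sequence length (known to
both sides from the header): a context model keeps a dense table when
``4^(k+1)`` counters are no larger than roughly 64 counters per coded base,
otherwise a bounded cache-hash; hash-bucket and k-mer-index sizes scale with
the sequence length between fixed floor and ceiling powers of two.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .fcm import CMConfig, STCMConfig
from .repeats import RepeatConfig
from .sequence_io import PackedSequence

MAGIC = b"CPD1"
VERSION = 1
FLAG_PAYLOAD_CRC = 1

_IR_CODE = {"forward": 0, "ir_only": 1, "both": 2}
_IR_NAME = {v: k for k, v in _IR_CODE.items()}


@dataclass(frozen=True)
class CodecConfig:
    """Full model configuration; at least one model across both classes."""

    cms: tuple[CMConfig, ...] = ()
    rms: tuple[RepeatConfig, ...] = ()
    k_c: int = 8
    alpha_c_num: int = 1
    alpha_c_den: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.cms and not self.rms:
            raise ValueError("at least one model is required")
        if not 1 <= self.k_c <= 24:
            raise ValueError("k_c must be in 1..24")
        if self.alpha_c_num <= 0 or self.alpha_c_den <= 0:
            raise ValueError("alpha_c must be positive")

    @property
    def alpha_c(self) -> float:
        return self.alpha_c_num / self.alpha_c_den


@dataclass
class Report:
    """Metrics of a completed compression run."""

    n: int
    payload_bytes: int
    total_bytes: int
    bps: float                      # 8 * payload_bytes / n
    ideal_bits: float               # sum of -log2(quantised p(true))
    select_rm_frac: float           # fraction of bases coded by the repeat class
    win_rm_frac: float              # fraction of bases the repeat class won
    final_cm_weights: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "payload_bytes": self.payload_bytes,
            "total_bytes": self.total_bytes,
            "bps": self.bps,
            "ideal_bits": self.ideal_bits,
            "select_rm_frac": self.select_rm_frac,
            "win_rm_frac": self.win_rm_frac,
            "final_cm_weights": self.final_cm_weights,
        }


# ---------------------------------------------------------------------------
# permille / rational helpers

def _permille(x: float, what: str) -> int:
    p = round(x * 1000)
    if abs(x * 1000 - p) > 1e-9 or not 0 <= p <= 1000:
        raise ValueError(f"{what}={x} is not an exact permille value")
    return p


# ---------------------------------------------------------------------------
# header

def serialize_header(cfg: CodecConfig, n: int, flags: int = 0) -> bytes:
    out = bytearray()
    out += MAGIC
    out += struct.pack("<BB", VERSION, flags)
    out += struct.pack("<QQ", n, cfg.seed & 0xFFFFFFFFFFFFFFFF)
    out += struct.pack("<B", len(cfg.cms))
    for c in cfg.cms:
        out += struct.pack(
            "<BIIHBBB", c.k, c.alpha_num, c.alpha_den,
            _permille(c.gamma, "gamma"), _IR_CODE[c.ir_mode],
            c.max_collisions, 1 if c.stcm else 0)
        if c.stcm:
            out += struct.pack("<BBB", c.stcm.max_subs, c.stcm.t, c.stcm.l)
    out += struct.pack("<B", len(cfg.rms))
    for r in cfg.rms:
        out += struct.pack(
            "<BHHHHHBB", r.k_r, r.rpn, r.a_hit, r.a_miss,
            _permille(r.deactivate_below, "deactivate_below"),
            _permille(r.gamma_r, "gamma_r"),
            1 if r.ir_enabled else 0, r.max_positions_per_kmer)
    out += struct.pack("<BII", cfg.k_c, cfg.alpha_c_num, cfg.alpha_c_den)
    out += struct.pack("<I", zlib.crc32(bytes(out)))
    return bytes(out)


def parse_header(blob: bytes) -> tuple[CodecConfig, int, int, int]:
    """Returns (config, sequence length, flags, header byte count)."""
    try:
        return _parse_header(blob)
    except struct.error as exc:
        raise ValueError(f"truncated container header: {exc}") from exc


def _parse_header(blob: bytes) -> tuple[CodecConfig, int, int, int]:
    if len(blob) < 8 or blob[:4] != MAGIC:
        raise ValueError("not a CPD1 container (bad magic)")
    version, flags = struct.unpack_from("<BB", blob, 4)
    if version != VERSION:
        raise ValueError(f"unsupported container version {version}")
    off = 6
    n, seed = struct.unpack_from("<QQ", blob, off)
    off += 16
    (n_cm,) = struct.unpack_from("<B", blob, off)
    off += 1
    cms = []
    for _ in range(n_cm):
        k, anum, aden, gperm, ir, coll, has_st = struct.unpack_from(
            "<BIIHBBB", blob, off)
        off += 14
        stcm = None
        if has_st:
            subs, t, l = struct.unpack_from("<BBB", blob, off)
            off += 3
            stcm = STCMConfig(max_subs=subs, t=t, l=l)
        cms.append(CMConfig(k=k, alpha_num=anum, alpha_den=aden,
                            gamma=gperm / 1000.0, ir_mode=_IR_NAME[ir],
                            max_collisions=coll, stcm=stcm))
    (n_rm,) = struct.unpack_from("<B", blob, off)
    off += 1
    rms = []
    for _ in range(n_rm):
        k_r, rpn, ah, am, dperm, gperm, ir, maxpos = struct.unpack_from(
            "<BHHHHHBB", blob, off)
        off += 13
        rms.append(RepeatConfig(k_r=k_r, rpn=rpn, a_hit=ah, a_miss=am,
                                deactivate_below=dperm / 1000.0,
                                gamma_r=gperm / 1000.0,
                                ir_enabled=bool(ir),
                                max_positions_per_kmer=maxpos))
    k_c, acn, acd = struct.unpack_from("<BII", blob, off)
    off += 9
    (crc,) = struct.unpack_from("<I", blob, off)
    if crc != zlib.crc32(blob[:off]):
        raise ValueError("header checksum mismatch")
    off += 4
    cfg = CodecConfig(cms=tuple(cms), rms=tuple(rms), k_c=k_c,
                      alpha_c_num=acn, alpha_c_den=acd, seed=seed)
    return cfg, n, flags, off


# ---------------------------------------------------------------------------
# memory plan (a pure function of config and sequence length)

def _next_pow2(x: int) -> int:
    return 1 << max(0, (x - 1).bit_length())


def _clamp_pow2(x: int, lo: int, hi: int) -> int:
    return min(max(_next_pow2(x), lo), hi)


@dataclass
class MemoryPlan:
    cm_storage: list[str]
    cm_hash_bits: list[int]
    index_bits: list[int]


def build_plan(cfg: CodecConfig, n: int) -> MemoryPlan:
    table_cap = _clamp_pow2(64 * n, 1 << 16, 1 << 26)
    hash_buckets = _clamp_pow2(8 * n, 1 << 10, 1 << 22)
    storages = []
    bits = []
    for c in cfg.cms:
        if c.storage == "auto":
            storage = "table" if 4 ** (c.k + 1) <= table_cap else "cache_hash"
        else:
            storage = c.storage
            if storage == "table" and 4 ** (c.k + 1) > 1 << 28:
                raise ValueError(f"dense table for k={c.k} is too large")
        storages.append(storage)
        bits.append(hash_buckets.bit_length() - 1)
    index_slots = _clamp_pow2(8 * n, 1 << 10, 1 << 22)
    return MemoryPlan(
        cm_storage=storages,
        cm_hash_bits=bits,
        index_bits=[index_slots.bit_length() - 1] * len(cfg.rms),
    )


# ---------------------------------------------------------------------------
# numba engine wrapper

def _run_kernel(cfg: CodecConfig, plan: MemoryPlan, mode: str,
                codes: np.ndarray | None = None, payload: bytes = b"",
                n: int | None = None, ckpt_interval: int = 0):
    from . import _kernels
    from .reference import EngineResult

    if mode == "encode":
        codes = np.ascontiguousarray(codes, dtype=np.uint8)
        n = int(codes.size)
        seq = codes.copy()
    else:
        assert n is not None
        seq = np.zeros(n, dtype=np.uint8)
    if n < 1:
        raise ValueError("sequence must contain at least one base")

    ncm = len(cfg.cms)
    cm_k = np.array([c.k for c in cfg.cms], dtype=np.int64)
    cm_alpha = np.array([c.alpha for c in cfg.cms], dtype=np.float64)
    cm_ir = np.array([_IR_CODE[c.ir_mode] for c in cfg.cms], dtype=np.int8)
    cm_mask = np.array([(1 << (2 * c.k)) - 1 for c in cfg.cms], dtype=np.int64)
    cm_storage = np.array(
        [0 if s == "table" else 1 for s in plan.cm_storage], dtype=np.int8)
    cm_taboff = np.full(ncm, -1, dtype=np.int64)
    cm_hslotoff = np.full(ncm, -1, dtype=np.int64)
    cm_hbits = np.zeros(ncm, dtype=np.int64)
    cm_hcoll = np.ones(ncm, dtype=np.int64)
    cm_hbucketoff = np.zeros(ncm, dtype=np.int64)
    tab_total = 0
    hslot_total = 0
    hbucket_total = 0
    for m, c in enumerate(cfg.cms):
        if cm_storage[m] == 0:
            cm_taboff[m] = tab_total
            tab_total += 4 ** (c.k + 1)
        else:
            bits = plan.cm_hash_bits[m]
            cm_hbits[m] = bits
            cm_hcoll[m] = c.max_collisions
            cm_hslotoff[m] = hslot_total
            cm_hbucketoff[m] = hbucket_total
            hslot_total += (1 << bits) * c.max_collisions
            hbucket_total += 1 << bits
    tables = np.zeros(tab_total, dtype=np.uint8)
    hkeys = np.full(hslot_total, -1, dtype=np.int64)
    hcnt = np.zeros(4 * hslot_total, dtype=np.uint8)
    hfifo = np.zeros(hbucket_total, dtype=np.uint8)

    st_host = np.array(
        [m for m, c in enumerate(cfg.cms) if c.stcm is not None],
        dtype=np.int64)
    st_subs = np.array(
        [cfg.cms[m].stcm.max_subs for m in st_host], dtype=np.int64)
    st_t = np.array([cfg.cms[m].stcm.t for m in st_host], dtype=np.int64)
    st_l = np.array([cfg.cms[m].stcm.l for m in st_host], dtype=np.int64)
    nexp = ncm + len(st_host)
    wexp = (np.full(nexp, 1.0 / nexp, dtype=np.float64)
            if nexp else np.zeros(0, dtype=np.float64))
    exp_gamma = np.array(
        [c.gamma for c in cfg.cms] + [cfg.cms[m].gamma for m in st_host],
        dtype=np.float64)

    ng = len(cfg.rms)
    rg_k = np.array([r.k_r for r in cfg.rms], dtype=np.int64)
    rg_rpn = np.array([r.rpn for r in cfg.rms], dtype=np.int64)
    rg_ah = np.array([r.a_hit for r in cfg.rms], dtype=np.int64)
    rg_am = np.array([r.a_miss for r in cfg.rms], dtype=np.int64)
    rg_deact = np.array([r.deactivate_below for r in cfg.rms], dtype=np.float64)
    rg_gamma = np.array([r.gamma_r for r in cfg.rms], dtype=np.float64)
    rg_ir = np.array([1 if r.ir_enabled else 0 for r in cfg.rms], dtype=np.int8)
    rg_mask = np.array([(1 << (2 * r.k_r)) - 1 for r in cfg.rms], dtype=np.int64)
    rg_maxpos = np.array(
        [r.max_positions_per_kmer for r in cfg.rms], dtype=np.int64)
    rg_ioff = np.zeros(ng, dtype=np.int64)
    ig_bits = np.array(plan.index_bits, dtype=np.int64)
    ig_keyoff = np.zeros(ng, dtype=np.int64)
    ig_posoff = np.zeros(ng, dtype=np.int64)
    ioff = 0
    keyoff = 0
    posoff = 0
    for g, r in enumerate(cfg.rms):
        rg_ioff[g] = ioff
        ioff += r.rpn
        ig_keyoff[g] = keyoff
        ig_posoff[g] = posoff
        keyoff += 1 << plan.index_bits[g]
        posoff += (1 << plan.index_bits[g]) * r.max_positions_per_kmer
    ikeys = np.full(keyoff, -1, dtype=np.int64)
    icnt = np.zeros(keyoff, dtype=np.uint8)
    ififo = np.zeros(keyoff, dtype=np.uint8)
    ipos = np.zeros(posoff, dtype=np.uint32)
    ri_ptr = np.zeros(ioff, dtype=np.int64)
    ri_hits = np.zeros(ioff, dtype=np.int64)
    ri_fails = np.zeros(ioff, dtype=np.int64)
    ri_orient = np.zeros(ioff, dtype=np.int8)
    ri_w = np.zeros(ioff, dtype=np.float64)
    ri_act = np.zeros(ioff, dtype=np.uint8)
    ri_pred = np.full(ioff, -1, dtype=np.int8)
    ri_n = np.zeros(ng, dtype=np.int64)

    cp_counts = np.zeros(2 ** (cfg.k_c + 1), dtype=np.uint8)

    if mode == "encode":
        pay = np.zeros(2 * n + 4096, dtype=np.uint8)
    else:
        pay = np.frombuffer(payload, dtype=np.uint8).copy()
    plen = np.zeros(1, dtype=np.int64)
    sel = np.zeros(n, dtype=np.uint8)
    win = np.zeros(n, dtype=np.uint8)
    pcm_log = np.zeros(n, dtype=np.float64)
    prm_log = np.zeros(n, dtype=np.float64)
    fq_log = np.zeros(n, dtype=np.uint32)
    n_ck = (n // ckpt_interval + 2) if ckpt_interval else 1
    cks = np.zeros(n_ck, dtype=np.uint64)
    ncks = np.zeros(1, dtype=np.int64)

    _kernels._run(
        0 if mode == "encode" else 1, n, seq, pay, plen,
        np.uint64(cfg.seed & 0xFFFFFFFFFFFFFFFF),
        cm_k, cm_alpha, cm_ir, cm_mask, 255,
        cm_storage, cm_taboff, tables,
        cm_hslotoff, cm_hbits, cm_hcoll, cm_hbucketoff, hkeys, hcnt, hfifo,
        st_host, st_subs, st_t, st_l,
        wexp, exp_gamma,
        rg_k, rg_rpn, rg_ah, rg_am, rg_deact, rg_gamma, rg_ir, rg_mask,
        rg_maxpos, rg_ioff,
        ig_bits, ig_keyoff, ig_posoff, ikeys, icnt, ififo, ipos,
        ri_ptr, ri_hits, ri_fails, ri_orient, ri_w, ri_act, ri_pred, ri_n,
        cfg.k_c, cfg.alpha_c, cp_counts,
        sel, win, pcm_log, prm_log, fq_log,
        ckpt_interval, cks, ncks)

    payload_out = (bytes(pay[: plen[0]].tobytes()) if mode == "encode"
                   else payload)
    return EngineResult(
        codes=seq, payload=payload_out, sel=sel, win=win, p_cm=pcm_log,
        p_rm=prm_log, fq_true=fq_log, final_cm_weights=list(wexp),
        checksums=[int(x) for x in cks[: ncks[0]]],
    )


def _run_engine(cfg, plan, mode, engine, **kw):
    if engine == "python":
        from .reference import run_reference
        return run_reference(cfg, plan, mode, **kw)
    if engine == "numba":
        return _run_kernel(cfg, plan, mode, **kw)
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# public API

def compress(seq: PackedSequence, cfg: CodecConfig, engine: str = "numba",
             payload_crc: bool = False) -> bytes:
    blob, _, _ = compress_report(seq, cfg, engine=engine,
                                 payload_crc=payload_crc)
    return blob


def compress_report(seq: PackedSequence, cfg: CodecConfig,
                    engine: str = "numba", payload_crc: bool = False,
                    ckpt_interval: int = 0):
    """Compress; returns ``(container bytes, Report, checksum list)``.

    With ``ckpt_interval`` > 0, model-state checksums are recorded every that
    many bases; a decompression run with the same interval must reproduce
    them exactly (see :func:`decompress_with_checksums`).
    """
    if len(seq) < 1:
        raise ValueError("cannot compress an empty sequence")
    codes = seq.codes()
    n = len(seq)
    plan = build_plan(cfg, n)
    res = _run_engine(cfg, plan, "encode", engine, codes=codes,
                      ckpt_interval=ckpt_interval)
    flags = FLAG_PAYLOAD_CRC if payload_crc else 0
    header = serialize_header(cfg, n, flags)
    blob = header + res.payload
    if payload_crc:
        blob += struct.pack("<I", zlib.crc32(codes.tobytes()))
    return blob, _make_report(n, len(res.payload), len(blob), res), res.checksums


def _make_report(n: int, payload_bytes: int, total_bytes: int, res) -> Report:
    ideal = float(np.sum(-np.log2(res.fq_true.astype(np.float64) / 65536.0)))
    return Report(
        n=n,
        payload_bytes=payload_bytes,
        total_bytes=total_bytes,
        bps=8.0 * payload_bytes / n,
        ideal_bits=ideal,
        select_rm_frac=float(np.mean(res.sel)),
        win_rm_frac=float(np.mean(res.win)),
        final_cm_weights=res.final_cm_weights,
    )


def decompress(blob: bytes, engine: str = "numba") -> PackedSequence:
    seq, _ = decompress_with_checksums(blob, engine=engine, ckpt_interval=0)
    return seq


def decompress_with_checksums(blob: bytes, engine: str = "numba",
                              ckpt_interval: int = 0):
    """Decompress; returns ``(PackedSequence, checksum list)``."""
    cfg, n, flags, off = parse_header(blob)
    end = len(blob)
    if flags & FLAG_PAYLOAD_CRC:
        if end - off < 4:
            raise ValueError("truncated container (missing payload checksum)")
        end -= 4
    payload = blob[off:end]
    plan = build_plan(cfg, n)
    res = _run_engine(cfg, plan, "decode", engine, payload=payload, n=n,
                      ckpt_interval=ckpt_interval)
    if flags & FLAG_PAYLOAD_CRC:
        (want,) = struct.unpack_from("<I", blob, end)
        got = zlib.crc32(res.codes.tobytes())
        if want != got:
            raise ValueError("payload checksum mismatch: corrupt container")
    return PackedSequence(res.codes), res.checksums


def report(seq: PackedSequence, cfg: CodecConfig, engine: str = "numba") -> Report:
    """Compress and return the run metrics only."""
    _, rep, _ = compress_report(seq, cfg, engine=engine)
    return rep


def per_base_bits(seq: PackedSequence, cfg: CodecConfig,
                  engine: str = "numba") -> np.ndarray:
    """Per-base coded cost in bits, ``-log2`` of the quantised probability the
    coder actually used; sums to the payload size within the coder's slack."""
    codes = seq.codes()
    plan = build_plan(cfg, len(seq))
    res = _run_engine(cfg, plan, "encode", engine, codes=codes)
    return -np.log2(res.fq_true.astype(np.float64) / 65536.0)


def run_details(seq: PackedSequence, cfg: CodecConfig,
                engine: str = "numba"):
    """Full engine result (per-base class selections, winners, class
    probabilities of the true base, quantised frequencies) for analysis."""
    codes = seq.codes()
    plan = build_plan(cfg, len(seq))
    return _run_engine(cfg, plan, "encode", engine, codes=codes)
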