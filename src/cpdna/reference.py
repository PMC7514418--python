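"""Pure-Python codec engine, composed directly from the model modules.

This is the readable, slow path: the per-base pipeline is written in terms of
the public operations of :mod:`~cpdna.fcm`, :mod:`~cpdna.repeats`,
:mod:`~cpdna.mixer`, :mod:`~cpdna.cpcm` and :mod:`~cpdna.coder`.  The
numba engine (:mod:`~cpdna._kernels`) replays exactly the same arithmetic in
the same order; the test suite asserts that both produce byte-identical
containers, so this module doubles as the executable definition of the
pipeline.

Per-base order of operations (identical on both codec sides):

1. every context model / STCM predicts; the class mixture is blended;
2. every active repeat instance predicts; the class mixture is blended;
3. the CPCM selects a class; the selected distribution is normalised,
   quantised and the base is arithmetic-coded (or decoded);
4. with the true base known: class weights refresh, context-model counters
   update (forward and inverted-repeat events), STCM edit states update,
   repeat instances tally/advance/deactivate, the winner class is recorded
   into the CPCM, and spawn attempts plus the k-mer index update run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cpcm as cpcm_mod
from .coder import RangeDecoder, RangeEncoder, quantize
from .fcm import STCM, ContextModel, CounterStore
from .mixer import WEIGHT_FLOOR, MixState, mix, update_weights
from .repeats import RepeatModelGroup, repeat_predict, repeat_update
from .rng import MASK64, PortableRNG, splitmix64

_CKSUM_SEED = 0x9E3779B97F4A7C15


def _argmax_low(d) -> int:
    best = 0
    for s in range(1, 4):
        if d[s] > d[best]:
            best = s
    return best


@dataclass
class EngineResult:
    codes: np.ndarray
    payload: bytes
    sel: np.ndarray          # selected class per base
    win: np.ndarray          # actual winner per base
    p_cm: np.ndarray         # CM-class probability of the true base
    p_rm: np.ndarray         # repeat-class probability of the true base
    fq_true: np.ndarray      # quantised frequency of the true base
    final_cm_weights: list[float] = field(default_factory=list)
    checksums: list[int] = field(default_factory=list)


def run_reference(cfg, plan, mode: str, codes=None, payload: bytes = b"",
                  n: int | None = None, ckpt_interval: int = 0) -> EngineResult:
    """Run the pipeline in pure Python.  ``mode`` is 'encode' or 'decode'."""
    if mode == "encode":
        codes = np.asarray(codes, dtype=np.uint8)
        n = int(codes.size)
    else:
        assert n is not None
        codes = np.zeros(n, dtype=np.uint8)
    if n < 1:
        raise ValueError("sequence must contain at least one base")

    cms = []
    for ci, c in enumerate(cfg.cms):
        store = CounterStore(c.k, plan.cm_storage[ci], c.max_collisions,
                             n_buckets=1 << plan.cm_hash_bits[ci],
                             counter_max=c.counter_max)
        cms.append(ContextModel(c, store=store))
    stcms = []
    st_host = []
    for ci, c in enumerate(cfg.cms):
        if c.stcm is not None:
            stcms.append(STCM(c.stcm, cms[ci]))
            st_host.append(ci)
    gammas = [c.gamma for c in cfg.cms] + [cfg.cms[h].gamma for h in st_host]
    wcm = MixState.uniform(gammas) if gammas else MixState([], [])

    groups = [RepeatModelGroup(rc) for rc in cfg.rms]
    cp = cpcm_mod.CPCMState(cfg.k_c, cfg.alpha_c)
    rng = PortableRNG(cfg.seed)

    enc = RangeEncoder() if mode == "encode" else None
    dec = RangeDecoder(payload) if mode == "decode" else None

    sel = np.zeros(n, dtype=np.uint8)
    win = np.zeros(n, dtype=np.uint8)
    p_cm_log = np.zeros(n, dtype=np.float64)
    p_rm_log = np.zeros(n, dtype=np.float64)
    fq_log = np.zeros(n, dtype=np.uint32)
    checksums: list[int] = []

    for i in range(n):
        # --- class 0: context models + STCMs -----------------------------
        dists = [cm.predict() for cm in cms]
        tops = []
        for st in stcms:
            dists.append(st.predict())
            tops.append(st.top_symbol())
        cm_mix = mix(dists, wcm) if dists else [0.25, 0.25, 0.25, 0.25]

        # --- class 1: repeat instances -----------------------------------
        for g in groups:
            g.reap()
        insts = [(g, inst) for g in groups for inst in g.instances]
        rdists = [repeat_predict(inst, codes[:i], g.cfg) for g, inst in insts]
        if insts:
            wsum = 0.0
            for _, inst in insts:
                wsum += inst.weight
            rw = [inst.weight / wsum for _, inst in insts]
            rm_mix = [0.0, 0.0, 0.0, 0.0]
            for w, d in zip(rw, rdists):
                for s in range(4):
                    rm_mix[s] += w * d[s]
        else:
            rw = []
            rm_mix = [0.25, 0.25, 0.25, 0.25]

        # --- select, code ------------------------------------------------
        cls = cpcm_mod.cpcm_select(cp)
        chosen = cm_mix if cls == 0 else rm_mix
        ssum = chosen[0] + chosen[1] + chosen[2] + chosen[3]
        norm = [chosen[0] / ssum, chosen[1] / ssum, chosen[2] / ssum,
                chosen[3] / ssum]
        ft = quantize(norm)
        if mode == "encode":
            s = int(codes[i])
            enc.encode(s, ft)
        else:
            s = dec.decode(ft)
            codes[i] = s
        sel[i] = cls
        fq_log[i] = ft[s]
        p_cm_log[i] = cm_mix[s]
        p_rm_log[i] = rm_mix[s]

        # --- updates -----------------------------------------------------
        if dists:
            update_weights(wcm, [d[s] for d in dists])
        if insts:
            us = []
            tot = 0.0
            for w, (g, _), d in zip(rw, insts, rdists):
                u = (w ** g.cfg.gamma_r) * d[s]
                if u < WEIGHT_FLOOR:
                    u = WEIGHT_FLOOR
                us.append(u)
                tot += u
            for u, (_, inst) in zip(us, insts):
                inst.weight = u / tot

        host_old = [cm.ctx for cm in cms]
        for cm in cms:
            cm.update(s)
        for st, top, h in zip(stcms, tops, st_host):
            st.update(s, top, host_old[h])
        for g, inst in insts:
            repeat_update(inst, s, g.cfg)

        w_cls = cpcm_mod.determine_winner(cm_mix[s], rm_mix[s])
        win[i] = w_cls
        cpcm_mod.cpcm_record(cp, w_cls)

        for g in groups:
            g.step_spawn_and_index(i, s, rng)

        if ckpt_interval and (i + 1) % ckpt_interval == 0:
            checksums.append(
                _checksum(i, cp, rng, cms, wcm, groups))

    payload_out = enc.flush() if mode == "encode" else payload
    return EngineResult(
        codes=codes,
        payload=payload_out,
        sel=sel,
        win=win,
        p_cm=p_cm_log,
        p_rm=p_rm_log,
        fq_true=fq_log,
        final_cm_weights=list(wcm.weights),
        checksums=checksums,
    )


def _checksum(i, cp, rng, cms, wcm, groups) -> int:
    """Order-sensitive digest of the full model state; the numba engine
    computes the identical digest so compressor/decompressor synchronisation
    can be checked at checkpoints."""
    h = _CKSUM_SEED

    def mixin(x: int) -> None:
        nonlocal h
        h = splitmix64((h ^ (x & MASK64)) & MASK64)

    mixin(i + 1)
    mixin(cp.context)
    mixin(rng.state)
    for cm in cms:
        mixin(cm.ctx)
        mixin(cm.rc)
    for w in wcm.weights:
        mixin(int(w * 4294967296.0))
    for g in groups:
        mixin(len(g.instances))
        for inst in g.instances:
            mixin(inst.pointer & MASK64)
            mixin(inst.hits)
            mixin(inst.fails)
            mixin(inst.orientation)
            mixin(int(inst.weight * 4294967296.0))
    return h
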