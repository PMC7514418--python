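"""Numba-compiled codec engine.

This module replays, instruction for instruction, the arithmetic of the pure
Python engine in :mod:`~cpdna.reference`: the same expression shapes, the same
summation orders, the same integer hashing and RNG transitions.  Both engines
therefore produce byte-identical containers (asserted by the test suite); this
one exists because the per-base pipeline must run at millions of operations
per second.

All model state lives in flat numpy arrays prepared by
:func:`cpdna.codec._build_state`; see :mod:`~cpdna.reference` for the
documented semantics of each step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_M64 = U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _mix64(x):
    # splitmix64 finaliser (also the seeding step of the codec RNG)
    x = (x + U64(0x9E3779B97F4A7C15)) & _M64
    x = ((x ^ (x >> U64(30))) * U64(0xBF58476D1CE4E5B9)) & _M64
    x = ((x ^ (x >> U64(27))) * U64(0x94D049BB133111EB)) & _M64
    return x ^ (x >> U64(31))


@njit(cache=True)
def _rng_next(s):
    # xorshift64* transition; returns (new_state, output)
    s = s & _M64
    s ^= s >> U64(12)
    s = (s ^ (s << U64(25))) & _M64
    s ^= s >> U64(27)
    return s, (s * U64(0x2545F4914F6CDD1D)) & _M64


@njit(cache=True)
def _seed_state(seed):
    s = _mix64(seed)
    if s == U64(0):
        s = U64(0x9E3779B97F4A7C15)
    return s


@njit(cache=True)
def _quantize(d, f):
    """Largest-remainder quantisation to sum 2^16, min 1 (cf. coder.quantize)."""
    r = np.empty(4, dtype=np.float64)
    total = 0
    for s in range(4):
        x = d[s] * 65536.0
        fs = int(x)
        rs = x - fs
        if fs < 1:
            fs = 1
            rs = -1.0
        f[s] = fs
        r[s] = rs
        total += fs
    while total < 65536:
        best = -1
        for s in range(4):
            if r[s] > -0.5 and (best < 0 or r[s] > r[best]):
                best = s
        f[best] += 1
        r[best] = -1.0
        total += 1
    while total > 65536:
        best = -1
        for s in range(4):
            if f[s] > 1 and (best < 0 or r[s] < r[best]):
                best = s
        f[best] -= 1
        r[best] = 2.0
        total -= 1


@njit(cache=True)
def _enc_shift_low(cst, out, pos):
    # cst = [low, cache, cache_size]; LZMA-style carry-counting byte output
    low = cst[0]
    if low < U64(0xFF000000) or low > U64(0xFFFFFFFF):
        carry = low >> U64(32)
        out[pos] = np.uint8((cst[1] + carry) & U64(0xFF))
        pos += 1
        while cst[2] > U64(1):
            out[pos] = np.uint8((U64(0xFF) + carry) & U64(0xFF))
            pos += 1
            cst[2] -= U64(1)
        cst[1] = (low >> U64(24)) & U64(0xFF)
        cst[2] = U64(0)
    cst[2] += U64(1)
    cst[0] = (low << U64(8)) & U64(0xFFFFFFFF)
    return pos


@njit(cache=True)
def _cm_counts(m, ctx, cm_storage, cm_taboff, tables, cm_hslotoff, cm_hbits,
               cm_hcoll, hkeys, hcnt, out):
    if cm_storage[m] == 0:
        base = cm_taboff[m] + ctx * 4
        out[0] = tables[base]
        out[1] = tables[base + 1]
        out[2] = tables[base + 2]
        out[3] = tables[base + 3]
        return
    bmask = U64((np.int64(1) << cm_hbits[m]) - 1)
    bucket = np.int64(_mix64(U64(ctx)) & bmask)
    coll = cm_hcoll[m]
    sbase = cm_hslotoff[m] + bucket * coll
    for j in range(coll):
        if hkeys[sbase + j] == ctx:
            cbase = (sbase + j) * 4
            out[0] = hcnt[cbase]
            out[1] = hcnt[cbase + 1]
            out[2] = hcnt[cbase + 2]
            out[3] = hcnt[cbase + 3]
            return
    out[0] = 0
    out[1] = 0
    out[2] = 0
    out[3] = 0


@njit(cache=True)
def _cm_incr(m, ctx, sym, counter_max, cm_storage, cm_taboff, tables,
             cm_hslotoff, cm_hbits, cm_hcoll, cm_hbucketoff, hkeys, hcnt,
             hfifo):
    if cm_storage[m] == 0:
        base = cm_taboff[m] + ctx * 4
        if tables[base + sym] >= counter_max:
            tables[base] //= 2
            tables[base + 1] //= 2
            tables[base + 2] //= 2
            tables[base + 3] //= 2
        tables[base + sym] += 1
        return
    bmask = U64((np.int64(1) << cm_hbits[m]) - 1)
    bucket = np.int64(_mix64(U64(ctx)) & bmask)
    coll = cm_hcoll[m]
    sbase = cm_hslotoff[m] + bucket * coll
    for j in range(coll):
        if hkeys[sbase + j] == ctx:
            cbase = (sbase + j) * 4
            if hcnt[cbase + sym] >= counter_max:
                hcnt[cbase] //= 2
                hcnt[cbase + 1] //= 2
                hcnt[cbase + 2] //= 2
                hcnt[cbase + 3] //= 2
            hcnt[cbase + sym] += 1
            return
    # miss: insert at the FIFO slot (evicting its previous occupant)
    fidx = cm_hbucketoff[m] + bucket
    j = np.int64(hfifo[fidx])
    slot = sbase + j
    hkeys[slot] = ctx
    cbase = slot * 4
    hcnt[cbase] = 0
    hcnt[cbase + 1] = 0
    hcnt[cbase + 2] = 0
    hcnt[cbase + 3] = 0
    hcnt[cbase + sym] = 1
    hfifo[fidx] = np.uint8((j + 1) % coll)


@njit(cache=True)
def _index_lookup_pick(g, kmer, r, ig_bits, ig_keyoff, ig_posoff, rg_maxpos,
                       ikeys, icnt, ififo, ipos):
    """Return (count, picked position) for the r-th oldest stored position of
    ``kmer`` (r is only used when count > 0)."""
    smask = (np.int64(1) << ig_bits[g]) - 1
    h = np.int64(_mix64(U64(kmer)) & U64(smask))
    for t in range(64):
        slot = ig_keyoff[g] + ((h + t) & smask)
        key = ikeys[slot]
        if key == kmer:
            c = np.int64(icnt[slot])
            maxpos = rg_maxpos[g]
            if c < maxpos:
                idx = r % c if c > 0 else 0
            else:
                idx = (np.int64(ififo[slot]) + (r % c)) % maxpos
            return c, np.int64(ipos[(slot - ig_keyoff[g]) * maxpos
                                    + ig_posoff[g] + idx])
        if key == -1:
            return 0, np.int64(-1)
    return 0, np.int64(-1)


@njit(cache=True)
def _index_add(g, kmer, pos, ig_bits, ig_keyoff, ig_posoff, rg_maxpos, ikeys,
               icnt, ififo, ipos):
    smask = (np.int64(1) << ig_bits[g]) - 1
    h = np.int64(_mix64(U64(kmer)) & U64(smask))
    slot = np.int64(-1)
    for t in range(64):
        cand = ig_keyoff[g] + ((h + t) & smask)
        key = ikeys[cand]
        if key == kmer or key == -1:
            slot = cand
            break
    if slot == -1:
        # probe budget exhausted (load kept low by sizing; deterministic reuse)
        slot = ig_keyoff[g] + ((h + 63) & smask)
        ikeys[slot] = -1
    maxpos = rg_maxpos[g]
    pbase = (slot - ig_keyoff[g]) * maxpos + ig_posoff[g]
    if ikeys[slot] != kmer:
        ikeys[slot] = kmer
        icnt[slot] = 0
        ififo[slot] = 0
    c = np.int64(icnt[slot])
    if c < maxpos:
        ipos[pbase + c] = np.uint32(pos)
        icnt[slot] = np.uint8(c + 1)
    else:
        j = np.int64(ififo[slot])
        ipos[pbase + j] = np.uint32(pos)
        ififo[slot] = np.uint8((j + 1) % maxpos)


@njit(cache=True)
def _run(mode, n, seq, payload, plen, seed,
         # context models
         cm_k, cm_alpha, cm_ir, cm_mask, counter_max,
         cm_storage, cm_taboff, tables,
         cm_hslotoff, cm_hbits, cm_hcoll, cm_hbucketoff, hkeys, hcnt, hfifo,
         # STCMs
         st_host, st_subs, st_t, st_l,
         # expert mixing
         wexp, exp_gamma,
         # repeat groups
         rg_k, rg_rpn, rg_ah, rg_am, rg_deact, rg_gamma, rg_ir, rg_mask,
         rg_maxpos, rg_ioff,
         ig_bits, ig_keyoff, ig_posoff, ikeys, icnt, ififo, ipos,
         ri_ptr, ri_hits, ri_fails, ri_orient, ri_w, ri_act, ri_pred, ri_n,
         # CPCM
         cp_k, cp_alpha, cp_counts,
         # logs / instrumentation
         sel, win, pcm_log, prm_log, fq_log,
         ckpt_interval, cks, ncks):
    ncm = cm_k.shape[0]
    nst = st_host.shape[0]
    nexp = ncm + nst
    ng = rg_k.shape[0]

    # per-model incremental contexts
    cm_ctx = np.zeros(ncm, dtype=np.int64)
    cm_rc = np.zeros(ncm, dtype=np.int64)
    st_ctx = np.zeros(nst, dtype=np.int64)
    st_left = np.empty(nst, dtype=np.int64)
    st_hist = np.zeros(nst, dtype=np.uint64)
    st_len = np.zeros(nst, dtype=np.int64)
    st_fails = np.zeros(nst, dtype=np.int64)
    for j in range(nst):
        st_left[j] = st_subs[j]
    rg_kmer = np.zeros(ng, dtype=np.int64)
    rg_rc = np.zeros(ng, dtype=np.int64)

    cp_mask = (np.int64(1) << cp_k) - 1
    cp_ctx = np.int64(0)

    rstate = _seed_state(seed)

    # coder state
    enc_st = np.zeros(3, dtype=np.uint64)   # low, cache, cache_size
    enc_st[2] = U64(1)
    out_pos = np.int64(0)
    rng32 = U64(0xFFFFFFFF)
    code = U64(0)
    in_pos = np.int64(0)
    if mode == 1:
        in_pos = 1  # leading zero byte from the encoder cache
        for _ in range(4):
            b = U64(0)
            if in_pos < payload.shape[0]:
                b = U64(payload[in_pos])
            in_pos += 1
            code = ((code << U64(8)) | b) & U64(0xFFFFFFFF)

    dists = np.empty((nexp, 4), dtype=np.float64)
    belief = np.empty(4, dtype=np.float64)
    tops = np.empty(nst, dtype=np.int64)
    counts = np.empty(4, dtype=np.int64)
    cm_mix = np.empty(4, dtype=np.float64)
    rm_mix = np.empty(4, dtype=np.float64)
    norm = np.empty(4, dtype=np.float64)
    ft = np.empty(4, dtype=np.int64)
    total_rpn = ri_ptr.shape[0]
    r_q = np.empty(total_rpn, dtype=np.float64)
    r_wn = np.empty(total_rpn, dtype=np.float64)
    r_u = np.empty(total_rpn, dtype=np.float64)

    for i in range(n):
        # ---- class 0 predictions ------------------------------------
        for m in range(ncm):
            k = cm_k[m]
            alpha = cm_alpha[m]
            if cm_ir[m] == 1:
                qsym = cm_rc[m] & 3
                head = cm_rc[m] >> 2
                for s in range(4):
                    ctx_s = (np.int64(3 - s) << (2 * (k - 1))) | head
                    _cm_counts(m, ctx_s, cm_storage, cm_taboff, tables,
                               cm_hslotoff, cm_hbits, cm_hcoll, hkeys, hcnt,
                               counts)
                    dists[m, s] = counts[qsym]
                tot = dists[m, 0] + dists[m, 1] + dists[m, 2] + dists[m, 3]
                den = tot + 4.0 * alpha
                for s in range(4):
                    dists[m, s] = (dists[m, s] + alpha) / den
            else:
                _cm_counts(m, cm_ctx[m], cm_storage, cm_taboff, tables,
                           cm_hslotoff, cm_hbits, cm_hcoll, hkeys, hcnt,
                           counts)
                tot = counts[0] + counts[1] + counts[2] + counts[3]
                den = tot + 4.0 * alpha
                for s in range(4):
                    dists[m, s] = (counts[s] + alpha) / den
        for j in range(nst):
            e = ncm + j
            h = st_host[j]
            # ungated belief at the edited context: scored by the hit/fail
            # cache even while the model is switched off
            _cm_counts(h, st_ctx[j], cm_storage, cm_taboff, tables,
                       cm_hslotoff, cm_hbits, cm_hcoll, hkeys, hcnt, counts)
            tot = counts[0] + counts[1] + counts[2] + counts[3]
            den = tot + 4.0 * cm_alpha[h]
            best = 0
            for s in range(4):
                b = (counts[s] + cm_alpha[h]) / den
                belief[s] = b
                if s > 0 and b > belief[best]:
                    best = s
            tops[j] = best
            if st_fails[j] <= st_t[j]:
                for s in range(4):
                    dists[e, s] = belief[s]
            else:
                for s in range(4):
                    dists[e, s] = 0.25

        if nexp > 0:
            for s in range(4):
                cm_mix[s] = 0.0
            for e in range(nexp):
                w = wexp[e]
                for s in range(4):
                    cm_mix[s] += w * dists[e, s]
        else:
            for s in range(4):
                cm_mix[s] = 0.25

        # ---- class 1 predictions ------------------------------------
        # reap instances deactivated on the previous step (order-preserving)
        for g in range(ng):
            base = rg_ioff[g]
            cnt = ri_n[g]
            kept = np.int64(0)
            for t in range(cnt):
                if ri_act[base + t] == 1:
                    if kept != t:
                        ri_ptr[base + kept] = ri_ptr[base + t]
                        ri_hits[base + kept] = ri_hits[base + t]
                        ri_fails[base + kept] = ri_fails[base + t]
                        ri_orient[base + kept] = ri_orient[base + t]
                        ri_w[base + kept] = ri_w[base + t]
                        ri_act[base + kept] = 1
                    kept += 1
            ri_n[g] = kept

        n_inst = np.int64(0)
        wsum = 0.0
        for g in range(ng):
            base = rg_ioff[g]
            for t in range(ri_n[g]):
                wsum += ri_w[base + t]
                n_inst += 1
        if n_inst > 0:
            for s in range(4):
                rm_mix[s] = 0.0
            ii = np.int64(0)
            for g in range(ng):
                base = rg_ioff[g]
                for t in range(ri_n[g]):
                    idx = base + t
                    ptr = ri_ptr[idx]
                    if ptr < 0 or ptr >= i:
                        # defensive: pointer outside the coded region
                        ri_act[idx] = 0
                        ri_pred[idx] = -1
                        q = 0.25
                        g_sym = np.int64(-1)
                    else:
                        g_sym = np.int64(seq[ptr])
                        if ri_orient[idx] == 1:
                            g_sym = 3 - g_sym
                        ri_pred[idx] = np.int8(g_sym)
                        q = float(ri_hits[idx] + rg_ah[g]) / float(
                            ri_hits[idx] + ri_fails[idx] + rg_ah[g] + rg_am[g])
                    r_q[ii] = q
                    wn = ri_w[idx] / wsum
                    r_wn[ii] = wn
                    rest = (1.0 - q) / 3.0
                    for s in range(4):
                        if s == g_sym:
                            rm_mix[s] += wn * q
                        else:
                            rm_mix[s] += wn * rest
                    ii += 1
        else:
            for s in range(4):
                rm_mix[s] = 0.25

        # ---- CPCM select, code --------------------------------------
        cbase = cp_ctx * 2
        c0 = np.int64(cp_counts[cbase])
        c1 = np.int64(cp_counts[cbase + 1])
        den = c0 + c1 + 2.0 * cp_alpha
        p0 = (c0 + cp_alpha) / den
        p1 = (c1 + cp_alpha) / den
        cls = np.int64(1) if p1 > p0 else np.int64(0)

        if cls == 0:
            ssum = cm_mix[0] + cm_mix[1] + cm_mix[2] + cm_mix[3]
            for s in range(4):
                norm[s] = cm_mix[s] / ssum
        else:
            ssum = rm_mix[0] + rm_mix[1] + rm_mix[2] + rm_mix[3]
            for s in range(4):
                norm[s] = rm_mix[s] / ssum
        _quantize(norm, ft)

        if mode == 0:
            sym = np.int64(seq[i])
            cum = np.int64(0)
            for s in range(sym):
                cum += ft[s]
            r32 = rng32 >> U64(16)
            enc_st[0] = enc_st[0] + U64(cum) * r32
            rng32 = U64(ft[sym]) * r32
            while rng32 < U64(0x1000000):
                out_pos = _enc_shift_low(enc_st, payload, out_pos)
                rng32 = (rng32 << U64(8)) & U64(0xFFFFFFFF)
        else:
            r32 = rng32 >> U64(16)
            dv = np.int64(code // r32)
            if dv >= 65536:
                dv = 65535
            cum = np.int64(0)
            sym = np.int64(0)
            while sym < 3 and cum + ft[sym] <= dv:
                cum += ft[sym]
                sym += 1
            code = code - U64(cum) * r32
            rng32 = U64(ft[sym]) * r32
            while rng32 < U64(0x1000000):
                b = U64(0)
                if in_pos < payload.shape[0]:
                    b = U64(payload[in_pos])
                in_pos += 1
                code = ((code << U64(8)) | b) & U64(0xFFFFFFFF)
                rng32 = (rng32 << U64(8)) & U64(0xFFFFFFFF)
            seq[i] = np.uint8(sym)

        s_true = np.int64(seq[i])
        sel[i] = np.uint8(cls)
        fq_log[i] = np.uint32(ft[s_true])
        pcm_log[i] = cm_mix[s_true]
        prm_log[i] = rm_mix[s_true]

        # ---- weight updates -----------------------------------------
        if nexp > 0:
            total = 0.0
            for e in range(nexp):
                u = (wexp[e] ** exp_gamma[e]) * dists[e, s_true]
                if u < 1e-12:
                    u = 1e-12
                wexp[e] = u
                total += u
            for e in range(nexp):
                wexp[e] /= total

        if n_inst > 0:
            tot_u = 0.0
            ii = np.int64(0)
            for g in range(ng):
                base = rg_ioff[g]
                for t in range(ri_n[g]):
                    idx = base + t
                    q = r_q[ii]
                    if ri_pred[idx] == s_true:
                        d_true = q
                    else:
                        d_true = (1.0 - q) / 3.0
                    u = (r_wn[ii] ** rg_gamma[g]) * d_true
                    if u < 1e-12:
                        u = 1e-12
                    r_u[ii] = u
                    tot_u += u
                    ii += 1
            ii = np.int64(0)
            for g in range(ng):
                base = rg_ioff[g]
                for t in range(ri_n[g]):
                    ri_w[base + t] = r_u[ii] / tot_u
                    ii += 1

        # ---- context-model counter/context updates ------------------
        for j in range(nst):
            # STCM edit uses the host's pre-update context; do it first
            h = st_host[j]
            top = tops[j]
            fail = np.int64(0) if top == s_true else np.int64(1)
            lw = st_l[j]
            if st_len[j] == lw:
                oldest = np.int64((st_hist[j] >> U64(lw - 1)) & U64(1))
                st_fails[j] -= oldest
                st_hist[j] = ((st_hist[j] << U64(1))
                              & ((U64(1) << U64(lw)) - U64(1))) | U64(fail)
            else:
                st_hist[j] = (st_hist[j] << U64(1)) | U64(fail)
                st_len[j] += 1
            st_fails[j] += fail
            if fail == 1:
                if st_left[j] > 0:
                    st_ctx[j] = ((st_ctx[j] << 2) | top) & cm_mask[h]
                    st_left[j] -= 1
                else:
                    st_ctx[j] = ((cm_ctx[h] << 2) | s_true) & cm_mask[h]
                    st_left[j] = st_subs[j]
            else:
                st_ctx[j] = ((st_ctx[j] << 2) | s_true) & cm_mask[h]
                if st_len[j] == lw and st_fails[j] == 0:
                    st_left[j] = st_subs[j]

        for m in range(ncm):
            k = cm_k[m]
            rc_new = (np.int64(3 - s_true) << (2 * (k - 1))) | (cm_rc[m] >> 2)
            _cm_incr(m, cm_ctx[m], s_true, counter_max, cm_storage, cm_taboff,
                     tables, cm_hslotoff, cm_hbits, cm_hcoll, cm_hbucketoff,
                     hkeys, hcnt, hfifo)
            if cm_ir[m] != 0 and i >= k:
                _cm_incr(m, rc_new, cm_rc[m] & 3, counter_max, cm_storage,
                         cm_taboff, tables, cm_hslotoff, cm_hbits, cm_hcoll,
                         cm_hbucketoff, hkeys, hcnt, hfifo)
            cm_ctx[m] = ((cm_ctx[m] << 2) | s_true) & cm_mask[m]
            cm_rc[m] = rc_new

        # ---- repeat instance updates --------------------------------
        for g in range(ng):
            base = rg_ioff[g]
            for t in range(ri_n[g]):
                idx = base + t
                if ri_act[idx] == 0:
                    continue
                if ri_pred[idx] == s_true:
                    ri_hits[idx] += 1
                else:
                    ri_fails[idx] += 1
                if ri_orient[idx] == 0:
                    ri_ptr[idx] += 1
                else:
                    ri_ptr[idx] -= 1
                q = float(ri_hits[idx] + rg_ah[g]) / float(
                    ri_hits[idx] + ri_fails[idx] + rg_ah[g] + rg_am[g])
                if q < rg_deact[g] or ri_ptr[idx] < 0:
                    ri_act[idx] = 0

        # ---- winner into CPCM ---------------------------------------
        w_cls = np.int64(1) if prm_log[i] > pcm_log[i] else np.int64(0)
        win[i] = np.uint8(w_cls)
        cbase = cp_ctx * 2
        if cp_counts[cbase + w_cls] >= counter_max:
            cp_counts[cbase] //= 2
            cp_counts[cbase + 1] //= 2
        cp_counts[cbase + w_cls] += 1
        cp_ctx = ((cp_ctx << 1) | w_cls) & cp_mask

        # ---- spawn + index ------------------------------------------
        for g in range(ng):
            kr = rg_k[g]
            rg_kmer[g] = ((rg_kmer[g] << 2) | s_true) & rg_mask[g]
            rg_rc[g] = (np.int64(3 - s_true) << (2 * (kr - 1))) | (rg_rc[g] >> 2)
            if i + 1 < kr:
                continue
            base = rg_ioff[g]
            # forward spawn
            if ri_n[g] < rg_rpn[g]:
                c, _p = _index_lookup_pick(g, rg_kmer[g], 0, ig_bits,
                                           ig_keyoff, ig_posoff, rg_maxpos,
                                           ikeys, icnt, ififo, ipos)
                if c > 0:
                    rstate, draw = _rng_next(rstate)
                    r = np.int64(draw % U64(c))
                    c, p = _index_lookup_pick(g, rg_kmer[g], r, ig_bits,
                                              ig_keyoff, ig_posoff, rg_maxpos,
                                              ikeys, icnt, ififo, ipos)
                    idx = base + ri_n[g]
                    ri_ptr[idx] = p
                    ri_hits[idx] = 0
                    ri_fails[idx] = 0
                    ri_orient[idx] = 0
                    ri_act[idx] = 1
                    ri_pred[idx] = -1
                    ri_w[idx] = 1.0 / (ri_n[g] + 1)
                    ri_n[g] += 1
            # inverted-repeat spawn
            if rg_ir[g] == 1 and ri_n[g] < rg_rpn[g]:
                c, _p = _index_lookup_pick(g, rg_rc[g], 0, ig_bits, ig_keyoff,
                                           ig_posoff, rg_maxpos, ikeys, icnt,
                                           ififo, ipos)
                if c > 0:
                    rstate, draw = _rng_next(rstate)
                    r = np.int64(draw % U64(c))
                    c, p = _index_lookup_pick(g, rg_rc[g], r, ig_bits,
                                              ig_keyoff, ig_posoff, rg_maxpos,
                                              ikeys, icnt, ififo, ipos)
                    ptr = p - kr - 1
                    if ptr >= 0:
                        idx = base + ri_n[g]
                        ri_ptr[idx] = ptr
                        ri_hits[idx] = 0
                        ri_fails[idx] = 0
                        ri_orient[idx] = 1
                        ri_act[idx] = 1
                        ri_pred[idx] = -1
                        ri_w[idx] = 1.0 / (ri_n[g] + 1)
                        ri_n[g] += 1
            _index_add(g, rg_kmer[g], i + 1, ig_bits, ig_keyoff, ig_posoff,
                       rg_maxpos, ikeys, icnt, ififo, ipos)

        # ---- state checksum at checkpoints --------------------------
        if ckpt_interval > 0 and (i + 1) % ckpt_interval == 0:
            h64 = U64(0x9E3779B97F4A7C15)
            h64 = _mix64(h64 ^ U64(i + 1))
            h64 = _mix64(h64 ^ U64(cp_ctx))
            h64 = _mix64(h64 ^ rstate)
            for m in range(ncm):
                h64 = _mix64(h64 ^ U64(cm_ctx[m]))
                h64 = _mix64(h64 ^ U64(cm_rc[m]))
            for e in range(nexp):
                h64 = _mix64(h64 ^ U64(np.int64(wexp[e] * 4294967296.0)))
            for g in range(ng):
                h64 = _mix64(h64 ^ U64(ri_n[g]))
                base = rg_ioff[g]
                for t in range(ri_n[g]):
                    idx = base + t
                    h64 = _mix64(h64 ^ U64(ri_ptr[idx]))
                    h64 = _mix64(h64 ^ U64(ri_hits[idx]))
                    h64 = _mix64(h64 ^ U64(ri_fails[idx]))
                    h64 = _mix64(h64 ^ U64(np.int64(ri_orient[idx])))
                    h64 = _mix64(h64 ^ U64(np.int64(ri_w[idx] * 4294967296.0)))
            cks[ncks[0]] = h64
            ncks[0] += 1

    if mode == 0:
        for _ in range(5):
            out_pos = _enc_shift_low(enc_st, payload, out_pos)
    plen[0] = out_pos
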