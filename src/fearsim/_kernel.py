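"""Compiled inner loop for running one behavioural episode.

This module flattens a :class:`~fearsim.circuit_builder.Network` into
plain arrays and runs the per-iteration update (synaptic input sums,
k-WTA gating, Euler integration, spiking/reset, nearest-neighbour STDP)
in a numba-jitted kernel.  The semantics are exactly those of the
documented per-module operations; the pure-NumPy reference path in
``protocol_engine`` composes those operations directly and is checked
against this kernel step-for-step in the test suite.

External inputs are encoded as negative source codes: Context units are
an analog binary pattern, CS/US/LC are single units.  The kernel's only
randomness is the per-step membrane noise, seeded per episode.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .plasticity import NO_SPIKE, PAIRING_CUTOFF_STEPS

__all__ = ["pack_network", "unpack_weights", "episode_kernel"]

SRC_CONTEXT = -1
SRC_CS = -2
SRC_US = -3
SRC_LC = -4
_EXT_CODE = {"Context": SRC_CONTEXT, "CS": SRC_CS, "US": SRC_US, "LC": SRC_LC}

STDP_CUTOFF_STEPS = PAIRING_CUTOFF_STEPS


def pack_network(network, us_in_episode: bool = False) -> dict:
    """Flatten regions, connections and weights into kernel arrays.

    ``us_in_episode`` disables plasticity on ``us_gated`` projections
    (extinction-circuit learning is vetoed on reinforced trials).
    """
    spec = network.spec
    names = network.region_names
    n_regions = len(names)
    offsets = np.zeros(n_regions + 1, dtype=np.int64)
    for i, name in enumerate(names):
        offsets[i + 1] = offsets[i] + network.sizes[name]
    n_total = int(offsets[-1])

    def per_region(attr):
        return np.array(
            [getattr(network.params[n], attr) for n in names], dtype=float
        )

    region_of = np.empty(n_total, dtype=np.int64)
    for i in range(n_regions):
        region_of[offsets[i]: offsets[i + 1]] = i

    conns = list(spec.connections)
    c_src = np.empty(len(conns), dtype=np.int64)
    c_tgt = np.empty(len(conns), dtype=np.int64)
    c_exc = np.empty(len(conns), dtype=np.bool_)
    c_ne = np.empty(len(conns), dtype=np.bool_)
    c_plastic = np.empty(len(conns), dtype=np.bool_)
    c_lr = np.empty(len(conns), dtype=float)
    c_wmax = np.empty(len(conns), dtype=float)
    c_woff = np.empty(len(conns), dtype=np.int64)
    c_nsrc = np.empty(len(conns), dtype=np.int64)
    c_norm = np.empty(len(conns), dtype=float)
    total = 0
    for i, c in enumerate(conns):
        c_src[i] = (
            _EXT_CODE[c.source]
            if c.source in _EXT_CODE
            else network.region_index[c.source]
        )
        c_tgt[i] = network.region_index[c.target]
        c_exc[i] = c.sign > 0
        c_ne[i] = c.ne_modulated
        c_plastic[i] = c.plastic and not (c.us_gated and us_in_episode)
        c_lr[i] = c.lr
        c_wmax[i] = c.w_max if c.w_max is not None else spec.stdp.w_max
        c_nsrc[i] = network._source_size(c.source)
        c_norm[i] = network.source_norm(c.source)
        c_woff[i] = total
        total += network.sizes[c.target] * c_nsrc[i]
    # stored source-major: entry (pre i, post j) lives at woff + i*n_tgt + j,
    # so accumulating one presynaptic unit's contribution is a contiguous pass
    w_flat = np.empty(total, dtype=float)
    for i, c in enumerate(conns):
        block = network.weights[c.key]
        w_flat[c_woff[i]: c_woff[i] + block.size] = block.T.ravel()

    return {
        "offsets": offsets,
        "region_of": region_of,
        "e_leak": per_region("leak_reversal"),
        "e_exc": per_region("exc_reversal"),
        "e_inh": per_region("inh_reversal"),
        "v_th": per_region("threshold"),
        "v_reset": per_region("reset"),
        "v_peak": per_region("peak"),
        "v_floor": per_region("floor"),
        "noise_mu": per_region("noise_mean"),
        "noise_sd": per_region("noise_sd"),
        "refrac_steps": np.array(
            [network.params[n].refractory_steps for n in names], dtype=np.int64
        ),
        "c_src": c_src,
        "c_tgt": c_tgt,
        "c_exc": c_exc,
        "c_ne": c_ne,
        "c_plastic": c_plastic,
        "c_lr": c_lr,
        "c_wmax": c_wmax,
        "c_woff": c_woff,
        "c_nsrc": c_nsrc,
        "c_norm": c_norm,
        "w_flat": w_flat,
        "conns": conns,
    }


def unpack_weights(network, packed: dict) -> None:
    """Copy the (possibly plasticity-updated) flat buffer back."""
    for i, c in enumerate(packed["conns"]):
        block = network.weights[c.key]
        off = packed["c_woff"][i]
        flat = packed["w_flat"][off: off + block.size]
        block[...] = flat.reshape(block.shape[1], block.shape[0]).T


@njit(cache=True)
def episode_kernel(
    n_iter,
    offsets,
    region_of,
    e_leak,
    e_exc,
    e_inh,
    v_th,
    v_reset,
    v_peak,
    v_floor,
    noise_mu,
    noise_sd,
    refrac_steps,
    k_arr,
    kw_exc,
    kw_inib,
    c_src,
    c_tgt,
    c_exc,
    c_ne,
    c_plastic,
    c_lr,
    c_wmax,
    c_woff,
    c_nsrc,
    c_norm,
    c_usamp,
    w_flat,
    ctx_pattern,
    cs_on,
    us_lo,
    us_hi,
    us_gain,
    beta_ne,
    a_plus,
    a_minus_abs,
    tau_w,
    tau_plus,
    tau_minus,
    w_min,
    w_max,
    v,
    refrac,
    last_spike,
    ctx_last,
    cs_last,
    us_last,
    cem_region,
    noise_seed,
):
    np.random.seed(noise_seed)
    n_total = v.shape[0]
    n_regions = offsets.shape[0] - 1
    n_conns = c_src.shape[0]
    n_ctx = ctx_pattern.shape[0]

    spiked = np.zeros(n_total, np.bool_)
    g_exc = np.zeros(n_total)
    g_inh = np.zeros(n_total)
    cem_counts = np.zeros(n_iter, np.int64)

    max_n = 0
    for r in range(n_regions):
        size = offsets[r + 1] - offsets[r]
        if size > max_n:
            max_n = size
    act_idx = np.empty(max_n, np.int64)
    winner = np.zeros(max_n, np.bool_)
    score = np.zeros(max_n)
    gbuf = np.zeros(max_n)
    # per-region list of depression-eligible neurons (silent this step but
    # spiked within the pairing window), rebuilt once per iteration
    elig_idx = np.empty(n_total, np.int64)
    elig_off = np.zeros(n_regions + 1, np.int64)

    # exponential pairing-window lookup tables
    exp_p = np.empty(STDP_CUTOFF_STEPS + 1)
    exp_m = np.empty(STDP_CUTOFF_STEPS + 1)
    for d in range(STDP_CUTOFF_STEPS + 1):
        exp_p[d] = math.exp(-d / tau_plus)
        exp_m[d] = math.exp(-d / tau_minus)

    for t in range(n_iter):
        in_window = us_lo <= t < us_hi
        us_act = us_gain if in_window else 0.0

        # ---- synaptic conductance sums (previous-step spikes) -----------
        for n in range(n_total):
            g_exc[n] = 0.0
            g_inh[n] = 0.0
        for ci in range(n_conns):
            tgt = c_tgt[ci]
            t0 = offsets[tgt]
            n_tgt = offsets[tgt + 1] - t0
            ns = c_nsrc[ci]
            woff = c_woff[ci]
            mult = (1.0 + beta_ne) if c_ne[ci] else 1.0
            src = c_src[ci]
            if src >= 0:
                s0 = offsets[src]
                n_act = 0
                for i in range(ns):
                    if spiked[s0 + i]:
                        act_idx[n_act] = i
                        n_act += 1
                if n_act == 0:
                    continue
                for j in range(n_tgt):
                    gbuf[j] = 0.0
                for a in range(n_act):
                    base = woff + act_idx[a] * n_tgt
                    for j in range(n_tgt):
                        gbuf[j] += w_flat[base + j]
                scale = mult / c_norm[ci]
                if c_exc[ci]:
                    for j in range(n_tgt):
                        g_exc[t0 + j] += scale * gbuf[j]
                else:
                    for j in range(n_tgt):
                        g_inh[t0 + j] += scale * gbuf[j]
            elif src == SRC_CONTEXT:
                for j in range(n_tgt):
                    gbuf[j] = 0.0
                for i in range(n_ctx):
                    a = ctx_pattern[i]
                    if a != 0.0:
                        base = woff + i * n_tgt
                        for j in range(n_tgt):
                            gbuf[j] += w_flat[base + j] * a
                scale = mult / c_norm[ci]
                if c_exc[ci]:
                    for j in range(n_tgt):
                        g_exc[t0 + j] += scale * gbuf[j]
                else:
                    for j in range(n_tgt):
                        g_inh[t0 + j] += scale * gbuf[j]
            else:
                if src == SRC_CS:
                    a = cs_on
                elif src == SRC_US:
                    a = us_act * c_usamp[ci]
                else:  # LC: tonic unit drive
                    a = 1.0
                if a == 0.0:
                    continue
                for j in range(n_tgt):
                    g = mult * w_flat[woff + j] * a
                    if c_exc[ci]:
                        g_exc[t0 + j] += g
                    else:
                        g_inh[t0 + j] += g

        # ---- k-winner-take-all gating ----------------------------------
        # winners (by net input current) keep w_exc-scaled excitation;
        # losers lose their excitatory drive and receive the pooled
        # global inhibition so their net drive cannot be positive.
        for r in range(n_regions):
            k = k_arr[r]
            if k <= 0:
                continue
            r0 = offsets[r]
            size = offsets[r + 1] - r0
            for j in range(size):
                winner[j] = False
                score[j] = (
                    g_exc[r0 + j] * (e_exc[r] - v[r0 + j])
                    + g_inh[r0 + j] * (e_inh[r] - v[r0 + j])
                )
            # top-k selection, lowest index wins ties
            if k > 8:
                order = np.argsort(-score[:size], kind="mergesort")
                for p_ in range(k):
                    winner[order[p_]] = True
            else:
                for _pick in range(k):
                    best = -1
                    best_val = -1.0e300
                    for j in range(size):
                        if not winner[j] and score[j] > best_val:
                            best_val = score[j]
                            best = j
                    winner[best] = True
            g_win = 0.0
            for j in range(size):
                if winner[j]:
                    g_win += g_exc[r0 + j]
            g_pool = kw_inib[r] * g_win / k
            for j in range(size):
                if winner[j]:
                    g_exc[r0 + j] *= kw_exc[r]
                else:
                    g_exc[r0 + j] = 0.0
                    g_inh[r0 + j] += g_pool

        # ---- exponential-integrator update, spiking, reset --------------
        for n in range(n_total):
            r = region_of[n]
            if refrac[n] > 0:
                refrac[n] -= 1
                v[n] = v_reset[r]
                spiked[n] = False
            else:
                tot = 1.0 + g_exc[n] + g_inh[n]
                vb = (
                    e_leak[r]
                    + g_exc[n] * e_exc[r]
                    + g_inh[n] * e_inh[r]
                ) / tot
                vn = vb + (v[n] - vb) * math.exp(-tot) + noise_mu[r]
                sd = noise_sd[r]
                if sd > 0.0:
                    # draw noise only when it can change the spike decision;
                    # far from threshold the fluctuation is immaterial
                    margin = vn - v_th[r]
                    if -6.0 * sd < margin <= 6.0 * sd:
                        vn += np.random.normal(0.0, sd)
                if vn < v_floor[r]:
                    vn = v_floor[r]
                elif vn > v_peak[r]:
                    vn = v_peak[r]
                if vn > v_th[r]:
                    spiked[n] = True
                    v[n] = v_reset[r]
                    refrac[n] = refrac_steps[r]
                    last_spike[n] = t
                else:
                    spiked[n] = False
                    v[n] = vn

        # external unit spike bookkeeping
        for i in range(n_ctx):
            if ctx_pattern[i] > 0.0:
                ctx_last[i] = t
        if cs_on > 0.0:
            cs_last[0] = t
        if us_act > 0.0:
            us_last[0] = t

        # ---- nearest-neighbour STDP on plastic projections --------------
        pos = 0
        for r in range(n_regions):
            elig_off[r] = pos
            for n in range(offsets[r], offsets[r + 1]):
                if not spiked[n]:
                    pls = last_spike[n]
                    if pls != NO_SPIKE and t - pls <= STDP_CUTOFF_STEPS:
                        elig_idx[pos] = n - offsets[r]
                        pos += 1
        elig_off[n_regions] = pos
        for ci in range(n_conns):
            if not c_plastic[ci]:
                continue
            tgt = c_tgt[ci]
            t0 = offsets[tgt]
            n_tgt = offsets[tgt + 1] - t0
            ns = c_nsrc[ci]
            woff = c_woff[ci]
            src = c_src[ci]
            lr = c_lr[ci]
            wmax = c_wmax[ci]
            for j in range(n_tgt):
                if not spiked[t0 + j]:
                    continue
                # post spiked now: pre-before-post potentiation
                for i in range(ns):
                    if src >= 0:
                        pls = last_spike[offsets[src] + i]
                    elif src == SRC_CONTEXT:
                        pls = ctx_last[i]
                    elif src == SRC_CS:
                        pls = cs_last[0]
                    else:
                        pls = us_last[0]
                    if pls == NO_SPIKE:
                        continue
                    d = t - pls
                    if d > STDP_CUTOFF_STEPS:
                        continue
                    idx = woff + i * n_tgt + j
                    w = w_flat[idx]
                    w += lr * (wmax - w) * a_plus * exp_p[d] / tau_w
                    if w > wmax:
                        w = wmax
                    elif w < w_min:
                        w = w_min
                    w_flat[idx] = w
            e0 = elig_off[tgt]
            e1 = elig_off[tgt + 1]
            if e1 == e0:
                continue
            for i in range(ns):
                if src >= 0:
                    pre_now = spiked[offsets[src] + i]
                elif src == SRC_CONTEXT:
                    pre_now = ctx_pattern[i] > 0.0
                elif src == SRC_CS:
                    pre_now = cs_on > 0.0
                else:
                    pre_now = us_act > 0.0
                if not pre_now:
                    continue
                # pre spiked now: post-before-pre depression on the
                # recently-active silent posts only
                for e in range(e0, e1):
                    j = elig_idx[e]
                    d = t - last_spike[t0 + j]
                    if d <= 0:
                        continue
                    idx = woff + i * n_tgt + j
                    w = w_flat[idx]
                    w += lr * (w_min - w) * a_minus_abs * exp_m[d] / tau_w
                    if w > wmax:
                        w = wmax
                    elif w < w_min:
                        w = w_min
                    w_flat[idx] = w

        # ---- output raster ----------------------------------------------
        c0 = offsets[cem_region]
        c1 = offsets[cem_region + 1]
        cnt = 0
        for n in range(c0, c1):
            if spiked[n]:
                cnt += 1
        cem_counts[t] = cnt

    return cem_counts
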