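"""Numba kernels for the reference simulators.

All kernels draw randomness from numba's internal generator, seeded
explicitly at kernel entry, so identical arguments give bit-identical
output.  Connectivity uses a separate seed from the dynamics so that two
differently weighted networks can share both the wiring realization and the
dynamic random stream.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def sample_fixed_indegree(N_sizes, offsets, K_int, seed, allow_autapse):
    """Fixed in-degree random connectivity without multapses or autapses.

    Returns (out_indptr, out_targets): CSR adjacency by *source* neuron.
    ``K_int[a, b]`` is the integer in-degree of a target in population ``a``
    from population ``b``.  Sources per target are drawn uniformly without
    replacement by partial Fisher-Yates.
    """
    np.random.seed(seed)
    npop = N_sizes.size
    N = 0
    for a in range(npop):
        N += N_sizes[a]
    total = 0
    for a in range(npop):
        for b in range(npop):
            total += N_sizes[a] * K_int[a, b]
    # first pass: in-edge source list per target block
    src = np.empty(total, dtype=np.int32)
    tgt = np.empty(total, dtype=np.int32)
    perms = [np.arange(N_sizes[b], dtype=np.int32) for b in range(npop)]
    pos = 0
    for a in range(npop):
        for t_local in range(N_sizes[a]):
            t_global = offsets[a] + t_local
            for b in range(npop):
                k = K_int[a, b]
                if k == 0:
                    continue
                perm = perms[b]
                nb = N_sizes[b]
                for i in range(k):
                    j = i + np.random.randint(nb - i)
                    tmp = perm[i]
                    perm[i] = perm[j]
                    perm[j] = tmp
                if (not allow_autapse) and a == b:
                    for i in range(k):
                        if perm[i] == t_local:
                            # replace the self-loop with the next unused source
                            tmp = perm[i]
                            perm[i] = perm[k]
                            perm[k] = tmp
                            break
                for i in range(k):
                    src[pos] = offsets[b] + perm[i]
                    tgt[pos] = t_global
                    pos += 1
    # second pass: bucket by source
    counts = np.zeros(N + 1, dtype=np.int64)
    for e in range(total):
        counts[src[e] + 1] += 1
    indptr = np.cumsum(counts)
    fill = indptr[:-1].copy()
    out_targets = np.empty(total, dtype=np.int32)
    for e in range(total):
        s = src[e]
        out_targets[fill[s]] = tgt[e]
        fill[s] += 1
    return indptr, out_targets


@numba.njit(cache=True)
def run_binary(
    pop_of,
    n_per_pop,
    out_indptr,
    out_targets,
    J_pop,
    theta,
    m_ext,
    s_ext,
    tau,
    T,
    burn_in,
    seed,
    sample_dt,
    record_ids,
    init_state,
):
    """Event-driven binary network simulation.

    Each neuron is updated at Poisson times with rate 1/tau; on update the
    state becomes Theta(h + x - theta) with ``h`` the cached recurrent input
    and ``x`` a fresh Gaussian external sample.  Returns time-averaged
    population activities (after ``burn_in``), population state counts on
    the ``sample_dt`` grid, and states of ``record_ids`` on the same grid.
    """
    np.random.seed(seed)
    N = pop_of.size
    npop = n_per_pop.size
    state = init_state.copy()
    h = np.zeros(N)
    n_active = np.zeros(npop)
    for j in range(N):
        if state[j] == 1:
            n_active[pop_of[j]] += 1.0
            for e in range(out_indptr[j], out_indptr[j + 1]):
                tg = out_targets[e]
                h[tg] += J_pop[pop_of[tg], pop_of[j]]
    n_samples = int(T / sample_dt) + 1
    pop_counts = np.zeros((n_samples, npop), dtype=np.int32)
    rec_states = np.zeros((n_samples, record_ids.size), dtype=np.int8)
    act_time = np.zeros(npop)
    t = 0.0
    mean_wait = tau / N
    next_sample = 0
    while True:
        dt = np.random.exponential(mean_wait)
        t_new = t + dt
        while next_sample < n_samples and next_sample * sample_dt <= t_new:
            for p in range(npop):
                pop_counts[next_sample, p] = np.int32(n_active[p])
            for i in range(record_ids.size):
                rec_states[next_sample, i] = state[record_ids[i]]
            next_sample += 1
        if t_new >= T:
            seg = T - max(t, burn_in)
            if seg > 0:
                for p in range(npop):
                    act_time[p] += n_active[p] * seg
            break
        seg = t_new - max(t, burn_in)
        if seg > 0:
            for p in range(npop):
                act_time[p] += n_active[p] * seg
        t = t_new
        j = np.random.randint(N)
        pj = pop_of[j]
        x = m_ext[pj] + s_ext[pj] * np.random.normal()
        new = 1 if h[j] + x - theta[pj] >= 0.0 else 0
        if new != state[j]:
            delta = np.float64(new - state[j])
            state[j] = new
            n_active[pj] += delta
            for e in range(out_indptr[j], out_indptr[j + 1]):
                tg = out_targets[e]
                h[tg] += delta * J_pop[pop_of[tg], pop_of[j]]
    mean_act = act_time / ((T - burn_in) * n_per_pop)
    return mean_act, pop_counts, rec_states


@numba.njit(cache=True)
def run_lif(
    pop_of,
    out_indptr,
    out_targets,
    J_pop,
    d_steps_pop,
    tau_m,
    tau_s,
    tau_ref,
    theta,
    V_r,
    I_dc,
    lam_e,
    lam_i,
    J_ext,
    g_ext,
    dt,
    n_steps,
    burn_steps,
    seed,
    max_spikes,
    record_spikes,
):
    """Clock-driven LIF simulation with exact subthreshold integration.

    Synaptic events add ``J tau_m / tau_s`` to the synaptic current; delayed
    delivery uses a circular buffer in units of ``dt``.  External drive is a
    balanced pair of Poisson trains (rates per step ``lam_e``, ``lam_i``)
    plus a DC current.  Returns spike counts per neuron (after
    ``burn_steps``) and, if requested, flat (neuron, step) spike records.
    """
    np.random.seed(seed)
    N = pop_of.size
    V = np.zeros(N)
    Isyn = np.zeros(N)
    refrac = np.zeros(N, dtype=np.int32)
    max_delay = int(d_steps_pop.max()) + 1
    buf = np.zeros((max_delay, N))
    counts = np.zeros(N, dtype=np.int64)
    spk_neuron = np.empty(max_spikes if record_spikes else 1, dtype=np.int32)
    spk_step = np.empty(max_spikes if record_spikes else 1, dtype=np.int32)
    n_spk = 0
    overflow = False
    # per-population propagators since tau may differ
    npop = tau_m.size
    pm_a = np.empty(npop)
    ps_a = np.empty(npop)
    pc_a = np.empty(npop)
    for p in range(npop):
        pm_a[p] = np.exp(-dt / tau_m[p])
        ps_a[p] = np.exp(-dt / tau_s[p])
        pc_a[p] = tau_s[p] / (tau_s[p] - tau_m[p]) * (ps_a[p] - pm_a[p])
    ref_steps = np.empty(npop, dtype=np.int32)
    for p in range(npop):
        ref_steps[p] = int(np.round(tau_ref[p] / dt))
    amp_ext = np.empty(npop)
    for p in range(npop):
        amp_ext[p] = J_ext[p] * tau_m[p] / tau_s[p]
    for step in range(n_steps):
        slot = step % max_delay
        for j in range(N):
            p = pop_of[j]
            V[j] = V[j] * pm_a[p] + I_dc[p] * (1.0 - pm_a[p]) + Isyn[j] * pc_a[p]
            Isyn[j] = Isyn[j] * ps_a[p] + buf[slot, j]
            buf[slot, j] = 0.0
            if lam_e[p] > 0.0 or lam_i[p] > 0.0:
                ne = np.random.poisson(lam_e[p])
                ni = np.random.poisson(lam_i[p])
                Isyn[j] += (ne - g_ext[p] * ni) * amp_ext[p]
            if refrac[j] > 0:
                refrac[j] -= 1
                V[j] = V_r[p]
            elif V[j] >= theta[p]:
                V[j] = V_r[p]
                refrac[j] = ref_steps[p]
                if step >= burn_steps:
                    counts[j] += 1
                    if record_spikes:
                        if n_spk >= max_spikes:
                            overflow = True
                        else:
                            spk_neuron[n_spk] = j
                            spk_step[n_spk] = step
                            n_spk += 1
                # deliver outgoing spikes
                for e in range(out_indptr[j], out_indptr[j + 1]):
                    tg = out_targets[e]
                    q = pop_of[tg]
                    ds = d_steps_pop[q, p]
                    buf[(step + ds) % max_delay, tg] += (
                        J_pop[q, p] * tau_m[q] / tau_s[q]
                    )
    return counts, spk_neuron[:n_spk], spk_step[:n_spk], overflow
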