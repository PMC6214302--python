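"""Compiled kernels of the classifier engine.

The rule population is stored structure-of-arrays so that the trial loop can
run compiled.  Every kernel receives the same fixed tuple of population
arrays (see :class:`rbnxcs.xcs.Population`):

``cmask, cval`` : int64
    Ternary condition encoded as a pair of bit masks over the N state bits
    (node 1 = most significant).  A '#' has a 0 in ``cmask``; a literal has a
    1 in ``cmask`` and its value in ``cval``.  A condition matches state
    ``s`` iff ``(s & cmask) == cval``.
``cact`` : int64
    Action in [0, N]; 0 is "no action".
``pred, err, fit, asz`` : float64
    Prediction, prediction error, fitness, action-set-size estimate.
``num, expn, ts, gen`` : int64
    Numerosity, experience, GA time stamp, and a per-slot generation counter
    that invalidates stale slot references after a deletion re-uses a slot.
``alive`` : bool
    Slot occupancy.
``free`` : int64
    Stack of dead slots below the high-water mark.
``meta`` : int64[4]
    ``[high_water, free_top, micro_count, time]``.

The parameter vector ``prm`` uses the slot layout from :mod:`rbnxcs.params`.
All randomness flows through the PCG32 state array from :mod:`rbnxcs._rng`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rng import rand_below, rand_uniform
from .params import (
    P_ALPHA,
    P_BETA,
    P_CHI,
    P_DELTA,
    P_DO_AS_SUB,
    P_DO_GA_SUB,
    P_EPS0,
    P_EPS_INIT,
    P_F_INIT,
    P_GAMMA,
    P_HASH,
    P_INIT,
    P_MU,
    P_NU,
    P_R,
    P_THETA_DEL,
    P_THETA_GA,
    P_THETA_MNA,
    P_THETA_SUB,
)

META_HW = 0
META_FREE = 1
META_MICRO = 2
META_TIME = 3


# ---------------------------------------------------------------------------
# condition helpers


@njit(cache=True, inline="always")
def _n_wildcards(mask, n_bits):
    c = 0
    for i in range(n_bits):
        if (mask >> i) & 1:
            c += 1
    return n_bits - c


@njit(cache=True, inline="always")
def _more_general(gmask, gval, smask, sval):
    """Strict generality: g covers s, with strictly more wildcards."""
    return (gmask & smask) == gmask and gmask != smask and gval == (sval & gmask)


# ---------------------------------------------------------------------------
# population bookkeeping


@njit(cache=True)
def _insert(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    m, v, a, p0, e0, f0, n0, x0, a0, t0,
):
    """Insert a (possibly multi-copy) classifier, merging duplicates.

    Returns the slot used.  ``micro_count`` grows by ``n0`` either way.
    """
    hw = meta[META_HW]
    for i in range(hw):
        if alive[i] and cact[i] == a and cmask[i] == m and cval[i] == v:
            num[i] += n0
            meta[META_MICRO] += n0
            return i
    if meta[META_FREE] > 0:
        meta[META_FREE] -= 1
        slot = free[meta[META_FREE]]
    else:
        slot = hw
        meta[META_HW] = hw + 1
    cmask[slot] = m
    cval[slot] = v
    cact[slot] = a
    pred[slot] = p0
    err[slot] = e0
    fit[slot] = f0
    num[slot] = n0
    expn[slot] = x0
    asz[slot] = a0
    ts[slot] = t0
    alive[slot] = True
    meta[META_MICRO] += n0
    return slot


@njit(cache=True, inline="always")
def _kill_slot(num, gen, alive, free, meta, slot):
    alive[slot] = False
    num[slot] = 0
    gen[slot] += 1
    free[meta[META_FREE]] = slot
    meta[META_FREE] += 1


@njit(cache=True)
def _deletion_votes(fit, num, expn, asz, alive, hw, prm, votes):
    """Fill ``votes`` for every slot; returns (total_vote, mean_fitness)."""
    fsum = 0.0
    nsum = 0
    for i in range(hw):
        if alive[i]:
            fsum += fit[i]
            nsum += num[i]
    mean_fit = fsum / nsum if nsum > 0 else 0.0
    total = 0.0
    for i in range(hw):
        votes[i] = 0.0
        if alive[i]:
            v = asz[i] * num[i]
            fpm = fit[i] / num[i]
            if fpm < 1e-12:
                fpm = 1e-12
            if expn[i] > prm[P_THETA_DEL] and fpm < prm[P_DELTA] * mean_fit:
                v *= mean_fit / fpm
            votes[i] = v
            total += v
    return total


@njit(cache=True)
def _delete_to_capacity(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    prm, rng,
):
    """Roulette-delete single micro-copies until micro_count <= R."""
    cap = np.int64(prm[P_R])
    while meta[META_MICRO] > cap:
        hw = meta[META_HW]
        votes = np.empty(hw, np.float64)
        total = _deletion_votes(fit, num, expn, asz, alive, hw, prm, votes)
        r = rand_uniform(rng) * total
        acc = 0.0
        chosen = -1
        for i in range(hw):
            if alive[i]:
                acc += votes[i]
                chosen = i
                if acc > r:
                    break
        if chosen < 0:
            break
        num[chosen] -= 1
        meta[META_MICRO] -= 1
        if num[chosen] <= 0:
            _kill_slot(num, gen, alive, free, meta, chosen)


# ---------------------------------------------------------------------------
# matching, covering, prediction


@njit(cache=True)
def _find_matches(cmask, cval, alive, hw, s, midx):
    cnt = 0
    for i in range(hw):
        if alive[i] and (s & cmask[i]) == cval[i]:
            midx[cnt] = i
            cnt += 1
    return cnt


@njit(cache=True)
def _cover_new(s, present, n_bits, n_actions, prm, rng):
    """Draw one covering classifier condition/action for state ``s``.

    The action is uniform over the actions absent from ``present``; the
    condition starts as the state and each character independently becomes
    '#' with probability P_#.  Caller guarantees an absent action exists.
    """
    absent = 0
    for a in range(n_actions):
        if not present[a]:
            absent += 1
    j = rand_below(rng, absent)
    act = 0
    c = 0
    for a in range(n_actions):
        if not present[a]:
            if c == j:
                act = a
                break
            c += 1
    m = (np.int64(1) << n_bits) - 1
    v = s
    for i in range(n_bits):
        if rand_uniform(rng) < prm[P_HASH]:
            b = np.int64(1) << (n_bits - 1 - i)
            m &= ~b
            v &= ~b
    return m, v, act


@njit(cache=True)
def _match_covering(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    s, n_bits, n_actions, prm, rng, midx, present,
):
    """Build the match set, covering until theta_mna distinct actions exist."""
    while True:
        cnt = _find_matches(cmask, cval, alive, meta[META_HW], s, midx)
        for a in range(n_actions):
            present[a] = False
        distinct = 0
        for t in range(cnt):
            a = cact[midx[t]]
            if not present[a]:
                present[a] = True
                distinct += 1
        if distinct >= prm[P_THETA_MNA] or distinct == n_actions:
            return cnt
        m, v, act = _cover_new(s, present, n_bits, n_actions, prm, rng)
        _insert(
            cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive,
            free, meta,
            m, v, act,
            prm[P_INIT], prm[P_EPS_INIT], prm[P_F_INIT], 1, 0, 1.0,
            meta[META_TIME],
        )
        _delete_to_capacity(
            cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive,
            free, meta, prm, rng,
        )


@njit(cache=True)
def _prediction_array(cact, pred, fit, midx, cnt, pa, fsum, usum, nsup):
    """Fitness-weighted mean prediction per action over the match set.

    Actions whose total fitness is zero fall back to the unweighted mean.
    ``nsup[a]`` is the number of supporting macroclassifiers.
    """
    n_actions = pa.shape[0]
    for a in range(n_actions):
        pa[a] = 0.0
        fsum[a] = 0.0
        usum[a] = 0.0
        nsup[a] = 0
    for t in range(cnt):
        i = midx[t]
        a = cact[i]
        pa[a] += pred[i] * fit[i]
        fsum[a] += fit[i]
        usum[a] += pred[i]
        nsup[a] += 1
    for a in range(n_actions):
        if nsup[a] > 0:
            if fsum[a] > 0.0:
                pa[a] /= fsum[a]
            else:
                pa[a] = usum[a] / nsup[a]
    return 0


@njit(cache=True)
def _select_action(pa, nsup, greedy, rng):
    """Deterministic payoff-threshold chooser.

    Greedy mode or best prediction > 500: the argmax (ties to the smallest
    action index); otherwise a uniformly random present action (a best
    prediction of exactly 500 explores).
    """
    n_actions = pa.shape[0]
    best = -1
    bv = 0.0
    for a in range(n_actions):
        if nsup[a] > 0 and (best < 0 or pa[a] > bv):
            best = a
            bv = pa[a]
    if best < 0:
        return np.int64(-1)
    if greedy or bv > 500.0:
        return np.int64(best)
    npresent = 0
    for a in range(n_actions):
        if nsup[a] > 0:
            npresent += 1
    j = rand_below(rng, npresent)
    c = 0
    for a in range(n_actions):
        if nsup[a] > 0:
            if c == j:
                return np.int64(a)
            c += 1
    return np.int64(best)


# ---------------------------------------------------------------------------
# reinforcement updates and subsumption


@njit(cache=True, inline="always")
def _accuracy(e, prm):
    if e < prm[P_EPS0]:
        return 1.0
    return prm[P_ALPHA] * (e / prm[P_EPS0]) ** (-prm[P_NU])


@njit(cache=True)
def _action_set_subsumption(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    aidx, agen, acnt, n_bits, prm,
):
    """The most general accurate, experienced member absorbs the rest."""
    best = -1
    best_h = -1
    for t in range(acnt):
        i = aidx[t]
        if (
            alive[i]
            and gen[i] == agen[t]
            and expn[i] > prm[P_THETA_SUB]
            and err[i] < prm[P_EPS0]
        ):
            h = _n_wildcards(cmask[i], n_bits)
            if h > best_h:
                best_h = h
                best = i
    if best < 0:
        return
    for t in range(acnt):
        i = aidx[t]
        if i == best or not (alive[i] and gen[i] == agen[t]):
            continue
        if _more_general(cmask[best], cval[best], cmask[i], cval[i]):
            num[best] += num[i]
            _kill_slot(num, gen, alive, free, meta, i)


@njit(cache=True)
def _update_action_set(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    aidx, agen, acnt, target_p, n_bits, prm,
):
    """Two-tier (MAM) update of p, eps, as_size, then accuracy-based fitness.

    The error moves toward |P - p| computed with the pre-update prediction;
    components younger than 1/beta updates average incrementally, older ones
    use the Widrow-Hoff rate beta.  Fitness uses the plain beta rate on the
    numerosity-weighted relative accuracy.  Finally, action-set subsumption
    runs if enabled.
    """
    beta = prm[P_BETA]
    inv_beta = 1.0 / beta
    numsum = 0
    for t in range(acnt):
        i = aidx[t]
        if alive[i] and gen[i] == agen[t]:
            numsum += num[i]
    if numsum == 0:
        return
    for t in range(acnt):
        i = aidx[t]
        if not (alive[i] and gen[i] == agen[t]):
            continue
        expn[i] += 1
        e = expn[i]
        d_err = abs(target_p - pred[i]) - err[i]
        d_p = target_p - pred[i]
        d_a = numsum - asz[i]
        if e < inv_beta:
            err[i] += d_err / e
            pred[i] += d_p / e
            asz[i] += d_a / e
        else:
            err[i] += beta * d_err
            pred[i] += beta * d_p
            asz[i] += beta * d_a
    ksum = 0.0
    for t in range(acnt):
        i = aidx[t]
        if alive[i] and gen[i] == agen[t]:
            ksum += _accuracy(err[i], prm) * num[i]
    if ksum > 0.0:
        for t in range(acnt):
            i = aidx[t]
            if alive[i] and gen[i] == agen[t]:
                rel = _accuracy(err[i], prm) * num[i] / ksum
                fit[i] += beta * (rel - fit[i])
    if prm[P_DO_AS_SUB] != 0.0:
        _action_set_subsumption(
            cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive,
            free, meta, aidx, agen, acnt, n_bits, prm,
        )


# ---------------------------------------------------------------------------
# genetic algorithm


@njit(cache=True)
def _roulette_fitness(fit, num, alive, gen, aidx, agen, acnt, rng):
    """Fitness-proportionate parent choice over the (live) action set."""
    total = 0.0
    nlive = 0
    last = -1
    for t in range(acnt):
        i = aidx[t]
        if alive[i] and gen[i] == agen[t]:
            total += fit[i]
            nlive += 1
            last = i
    if nlive == 0:
        return np.int64(-1)
    if total <= 0.0:
        j = rand_below(rng, nlive)
        c = 0
        for t in range(acnt):
            i = aidx[t]
            if alive[i] and gen[i] == agen[t]:
                if c == j:
                    return np.int64(i)
                c += 1
        return np.int64(last)
    r = rand_uniform(rng) * total
    acc = 0.0
    for t in range(acnt):
        i = aidx[t]
        if alive[i] and gen[i] == agen[t]:
            acc += fit[i]
            last = i
            if acc > r:
                break
    return np.int64(last)


@njit(cache=True)
def _crossover_segment(m1, v1, m2, v2, n_bits, x, y):
    """Swap condition characters in [x, y) between the two conditions."""
    seg = ((np.int64(1) << (n_bits - x)) - 1) ^ ((np.int64(1) << (n_bits - y)) - 1)
    nm1 = (m1 & ~seg) | (m2 & seg)
    nv1 = (v1 & ~seg) | (v2 & seg)
    nm2 = (m2 & ~seg) | (m1 & seg)
    nv2 = (v2 & ~seg) | (v1 & seg)
    return nm1, nv1, nm2, nv2


@njit(cache=True)
def _crossover_two_point(m1, v1, m2, v2, n_bits, rng):
    x = rand_below(rng, n_bits + 1)
    y = rand_below(rng, n_bits + 1)
    if x > y:
        x, y = y, x
    return _crossover_segment(m1, v1, m2, v2, n_bits, x, y)


@njit(cache=True)
def _mutate(m, v, a, sigma, n_bits, n_actions, prm, rng):
    """Niche mutation against the current situation ``sigma``.

    Each condition index flips between '#' and the situation's literal with
    probability mu; the action is replaced by a different random action with
    probability mu.  The mutated condition always still matches ``sigma``.
    """
    mu = prm[P_MU]
    for i in range(n_bits):
        if rand_uniform(rng) < mu:
            b = np.int64(1) << (n_bits - 1 - i)
            if m & b:
                m &= ~b
                v &= ~b
            else:
                m |= b
                if sigma & b:
                    v |= b
                else:
                    v &= ~b
    if rand_uniform(rng) < mu:
        j = rand_below(rng, n_actions - 1)
        if j >= a:
            j += 1
        a = j
    return m, v, a


@njit(cache=True, inline="always")
def _can_subsume(expn_i, err_i, prm):
    return expn_i > prm[P_THETA_SUB] and err_i < prm[P_EPS0]


@njit(cache=True)
def _run_ga(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    aidx, agen, acnt, sigma, n_bits, n_actions, prm, rng,
):
    """GA on one action set: trigger test, reproduction, subsumption, insert.

    Fires only when the numerosity-weighted mean time stamp lags the engine
    clock by more than theta_ga; on firing all members are re-stamped.
    Children copy their parents (numerosity 1, experience 0), cross over with
    probability chi, mutate, and carry the parents' mean p, eps, F (and mean
    action-set-size estimate).  An eligible more-general parent subsumes its
    child; capacity is enforced afterwards.
    """
    numsum = 0
    tsum = 0.0
    for t in range(acnt):
        i = aidx[t]
        if alive[i] and gen[i] == agen[t]:
            numsum += num[i]
            tsum += ts[i] * num[i]
    if numsum == 0:
        return
    now = meta[META_TIME]
    if now - tsum / numsum <= prm[P_THETA_GA]:
        return
    for t in range(acnt):
        i = aidx[t]
        if alive[i] and gen[i] == agen[t]:
            ts[i] = now
    p1 = _roulette_fitness(fit, num, alive, gen, aidx, agen, acnt, rng)
    p2 = _roulette_fitness(fit, num, alive, gen, aidx, agen, acnt, rng)
    if p1 < 0 or p2 < 0:
        return
    m1, v1, a1 = cmask[p1], cval[p1], cact[p1]
    m2, v2, a2 = cmask[p2], cval[p2], cact[p2]
    if rand_uniform(rng) < prm[P_CHI]:
        m1, v1, m2, v2 = _crossover_two_point(m1, v1, m2, v2, n_bits, rng)
    child_p = 0.5 * (pred[p1] + pred[p2])
    child_e = 0.5 * (err[p1] + err[p2])
    child_f = 0.5 * (fit[p1] + fit[p2])
    child_a = 0.5 * (asz[p1] + asz[p2])
    m1, v1, a1 = _mutate(m1, v1, a1, sigma, n_bits, n_actions, prm, rng)
    m2, v2, a2 = _mutate(m2, v2, a2, sigma, n_bits, n_actions, prm, rng)
    for child in range(2):
        if child == 0:
            cm, cv, ca = m1, v1, a1
        else:
            cm, cv, ca = m2, v2, a2
        if prm[P_DO_GA_SUB] != 0.0 and (
            alive[p1]
            and cact[p1] == ca
            and _can_subsume(expn[p1], err[p1], prm)
            and _more_general(cmask[p1], cval[p1], cm, cv)
        ):
            num[p1] += 1
            meta[META_MICRO] += 1
        elif prm[P_DO_GA_SUB] != 0.0 and (
            alive[p2]
            and cact[p2] == ca
            and _can_subsume(expn[p2], err[p2], prm)
            and _more_general(cmask[p2], cval[p2], cm, cv)
        ):
            num[p2] += 1
            meta[META_MICRO] += 1
        else:
            _insert(
                cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen,
                alive, free, meta,
                cm, cv, ca, child_p, child_e, child_f, 1, 0, child_a, now,
            )
    _delete_to_capacity(
        cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive,
        free, meta, prm, rng,
    )


# ---------------------------------------------------------------------------
# the trial loop


@njit(cache=True)
def _run_one_trial(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    succ, target, start, max_steps, n_bits, n_actions, prm, rng,
    midx, present, pa, fsum, usum, nsup, cur_idx, cur_gen, prev_idx, prev_gen,
):
    """One learning trial from ``start`` until the target attractor or cap.

    Implements the multi-step loop: situation -> match set (with covering) ->
    prediction array -> action -> execute (flip + natural update, or natural
    update alone) -> payoff.  From the second cycle on, the previous action
    set is updated with P = gamma * max(current prediction array) and the GA
    may run on it with the previous situation.  On reaching the target the
    current action set receives a final update with the trial payoff
    1000 * (steps - interventions) / steps and a final GA iteration; a trial
    that hits ``max_steps`` receives a final update with payoff 0 instead.
    """
    gamma = prm[P_GAMMA]
    state = start
    steps = 0
    interv = 0
    prev_cnt = 0
    prev_sigma = np.int64(0)
    reward = 0.0
    reached = False
    while True:
        meta[META_TIME] += 1
        mcnt = _match_covering(
            cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive,
            free, meta, state, n_bits, n_actions, prm, rng, midx, present,
        )
        _prediction_array(cact, pred, fit, midx, mcnt, pa, fsum, usum, nsup)
        maxpa = 0.0
        first_seen = True
        for a in range(n_actions):
            if nsup[a] > 0 and (first_seen or pa[a] > maxpa):
                maxpa = pa[a]
                first_seen = False
        action = _select_action(pa, nsup, False, rng)
        acnt = 0
        for t in range(mcnt):
            i = midx[t]
            if cact[i] == action:
                cur_idx[acnt] = i
                cur_gen[acnt] = gen[i]
                acnt += 1
        if action != 0:
            nxt = succ[state ^ (np.int64(1) << (n_bits - action))]
            steps += 2
            interv += 1
        else:
            nxt = succ[state]
            steps += 1
        if prev_cnt > 0:
            _update_action_set(
                cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen,
                alive, free, meta,
                prev_idx, prev_gen, prev_cnt, gamma * maxpa, n_bits, prm,
            )
            _run_ga(
                cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen,
                alive, free, meta,
                prev_idx, prev_gen, prev_cnt, prev_sigma, n_bits, n_actions,
                prm, rng,
            )
        if target[nxt]:
            reached = True
            reward = 1000.0 * (steps - interv) / steps
            _update_action_set(
                cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen,
                alive, free, meta,
                cur_idx, cur_gen, acnt, reward, n_bits, prm,
            )
            _run_ga(
                cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen,
                alive, free, meta,
                cur_idx, cur_gen, acnt, state, n_bits, n_actions, prm, rng,
            )
            break
        if steps >= max_steps:
            _update_action_set(
                cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen,
                alive, free, meta,
                cur_idx, cur_gen, acnt, 0.0, n_bits, prm,
            )
            break
        for t in range(acnt):
            prev_idx[t] = cur_idx[t]
            prev_gen[t] = cur_gen[t]
        prev_cnt = acnt
        prev_sigma = state
        state = nxt
    return steps, interv, reached, reward


@njit(cache=True)
def _run_trials(
    cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive, free, meta,
    succ, target, starts, n_trials, max_steps, n_bits, n_actions, prm, rng,
):
    """Run ``n_trials`` learning trials from uniformly drawn non-target starts."""
    cap = cmask.shape[0]
    midx = np.empty(cap, np.int64)
    present = np.zeros(n_actions, np.bool_)
    pa = np.zeros(n_actions, np.float64)
    fsum = np.zeros(n_actions, np.float64)
    usum = np.zeros(n_actions, np.float64)
    nsup = np.zeros(n_actions, np.int64)
    cur_idx = np.empty(cap, np.int64)
    cur_gen = np.empty(cap, np.int64)
    prev_idx = np.empty(cap, np.int64)
    prev_gen = np.empty(cap, np.int64)
    for _ in range(n_trials):
        start = starts[rand_below(rng, starts.shape[0])]
        _run_one_trial(
            cmask, cval, cact, pred, err, fit, num, expn, asz, ts, gen, alive,
            free, meta,
            succ, target, start, max_steps, n_bits, n_actions, prm, rng,
            midx, present, pa, fsum, usum, nsup, cur_idx, cur_gen,
            prev_idx, prev_gen,
        )
    return 0
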