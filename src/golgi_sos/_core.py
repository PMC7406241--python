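"""Jit-compiled Gillespie kernel.

The exact stochastic simulation keeps the five event-class propensities in
O(1) by maintaining running sums over the compartment population:

    S_i = sum_a phi_i(a)          (boundary fusion, fusion)
    Q_i = sum_a phi_i(a)^2        (fusion diagonal correction)
    C_i = sum_a n_i(a)            (conversion)
    Bsat = sum_{n_a>=2} n_a * (#identities present in a)
    Blin = sum_{n_a>=2} n_a

so that the total inter-compartment fusion propensity is
sum_i (S_i^2 - Q_i) / 2, the boundary propensities are alpha_ER*S_cis and
alpha_TGN*S_trans, budding is kb*Bsat (or kb*Blin) and conversion is
km*(C_cis + C_medial).  Selecting the concrete compartment(s) for a chosen
class costs one O(M) weighted scan.  The sums are rebuilt from scratch at
every kernel entry (i.e. every observer sampling interval) so incremental
floating-point drift never accumulates beyond a few thousand events.

The kernel is driven in chunks from Python (`engine.Simulation`): each call
advances to a target time or event budget and appends to preallocated event
and transport-event logs, returning a status code when it needs the caller
to flush logs or grow the slot arrays.

Randomness is a self-contained xoshiro256++ stream (seeded via a
splitmix64 expansion), so identical seeds give identical trajectories
across processes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Event kind codes (also used in exported event logs).
EV_INJECTION = 0
EV_FUSION = 1
EV_BOUNDARY_FUSION = 2
EV_BUDDING = 3
EV_CONVERSION = 4

EVENT_KIND_NAMES = {
    EV_INJECTION: "injection",
    EV_FUSION: "fusion",
    EV_BOUNDARY_FUSION: "boundary_fusion",
    EV_BUDDING: "budding",
    EV_CONVERSION: "conversion",
}

# Pseudo acceptor ids for boundary fusion rows.
ACCEPTOR_ER = -1
ACCEPTOR_TGN = -2

# istate slots
I_M = 0            # number of active compartments
I_NEXT_UID = 1
I_INJECTED = 2     # cumulative patches injected
I_EXIT_ER = 3      # cumulative patches exited via ER
I_EXIT_TGN = 4     # cumulative patches exited via TGN
I_CARGO_INJ = 5
I_CARGO_ER = 6
I_CARGO_TGN = 7
I_PULSE = 8        # cargo pulse: remaining vesicles to tag
I_NEVENTS = 9      # cumulative executed events
ISTATE_LEN = 10

# fstate slots
F_TIME = 0
FSTATE_LEN = 1

# pf (parameter vector) slots
P_J = 0
P_KB = 1
P_KM = 2
P_AER = 3
P_ATGN = 4
P_FUSION_ON = 5
P_LINEAR = 6
P_CARGO_CONT = 7   # probability of tagging an injected vesicle (continuous mode)
PF_LEN = 8

# status codes returned by _advance
OK = 0
MAX_EVENTS = 1
SLOTS_FULL = 2
EVLOG_FULL = 3
TRLOG_FULL = 4
INVALID = 5

EV_COLS = 13   # time,kind,donor_id,acceptor_id,identity,donor n+counts,acceptor counts,cargo
TR_COLS = 13   # time,identity,donor phi x3,acceptor phi x3,cargo,back_fusion,is_exit,uids


@njit(cache=True, inline="always")
def _u01(rstate):
    """xoshiro256++ -> uniform double in (0, 1)."""
    s0 = rstate[0]
    s1 = rstate[1]
    s2 = rstate[2]
    s3 = rstate[3]
    tmp = s0 + s3
    result = ((tmp << np.uint64(23)) | (tmp >> np.uint64(41))) + s0
    t = s1 << np.uint64(17)
    s2 = s2 ^ s0
    s3 = s3 ^ s1
    s1 = s1 ^ s2
    s0 = s0 ^ s3
    s2 = s2 ^ t
    s3 = (s3 << np.uint64(45)) | (s3 >> np.uint64(19))
    rstate[0] = s0
    rstate[1] = s1
    rstate[2] = s2
    rstate[3] = s3
    return (np.float64(result >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


def seed_state(seed: int) -> np.ndarray:
    """xoshiro256++ state for an integer seed, expanded via splitmix64."""
    mask = (1 << 64) - 1
    s = int(seed) & mask
    out = []
    for _ in range(4):
        s = (s + 0x9E3779B97F4A7C15) & mask
        z = s
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        out.append(z ^ (z >> 31))
    return np.array(out, dtype=np.uint64)


@njit(cache=True, inline="always")
def _contrib(cnt, s, sign, S, Q, C, agg):
    """Add (sign=+1) or remove (sign=-1) slot s from the running sums."""
    n = cnt[s, 0] + cnt[s, 1] + cnt[s, 2]
    fn = np.float64(n)
    k = 0
    for i in range(3):
        ci = cnt[s, i]
        if ci > 0:
            k += 1
        phi = np.float64(ci) / fn
        S[i] += sign * phi
        Q[i] += sign * phi * phi
        C[i] += sign * ci
    if n >= 2:
        agg[0] += sign * fn * np.float64(k)
        agg[1] += sign * fn


@njit(cache=True)
def _rebuild_sums(cnt, order, m, S, Q, C, agg):
    for i in range(3):
        S[i] = 0.0
        Q[i] = 0.0
        C[i] = 0
    agg[0] = 0.0
    agg[1] = 0.0
    for idx in range(m):
        _contrib(cnt, order[idx], 1, S, Q, C, agg)


@njit(cache=True)
def _sample_phi(cnt, order, m, ident, target):
    """Slot with probability proportional to phi_ident; target in (0, S_ident)."""
    acc = 0.0
    last = -1
    for idx in range(m):
        s = order[idx]
        n = cnt[s, 0] + cnt[s, 1] + cnt[s, 2]
        w = np.float64(cnt[s, ident]) / np.float64(n)
        if w > 0.0:
            last = s
            acc += w
            if acc >= target:
                return s
    return last


@njit(cache=True)
def _sample_count(cnt, order, m, ident, target):
    """Slot with probability proportional to the count n_ident."""
    acc = 0.0
    last = -1
    for idx in range(m):
        s = order[idx]
        c = cnt[s, ident]
        if c > 0:
            last = s
            acc += np.float64(c)
            if acc >= target:
                return s
    return last


@njit(cache=True)
def _sample_budding(cnt, order, m, linear, target):
    """Slot with probability proportional to its total budding weight."""
    acc = 0.0
    last = -1
    for idx in range(m):
        s = order[idx]
        n = cnt[s, 0] + cnt[s, 1] + cnt[s, 2]
        if n < 2:
            continue
        if linear:
            w = np.float64(n)
        else:
            k = 0
            for i in range(3):
                if cnt[s, i] > 0:
                    k += 1
            w = np.float64(n * k)
        last = s
        acc += w
        if acc >= target:
            return s
    return last


@njit(cache=True)
def _validate(cnt, cargo, order, m, istate):
    total = 0
    total_cargo = 0
    for idx in range(m):
        s = order[idx]
        n = 0
        for i in range(3):
            if cnt[s, i] < 0:
                return False
            n += cnt[s, i]
        if n < 1:
            return False
        if cargo[s] < 0:
            return False
        total += n
        total_cargo += cargo[s]
    if total != istate[I_INJECTED] - istate[I_EXIT_ER] - istate[I_EXIT_TGN]:
        return False
    if total_cargo != istate[I_CARGO_INJ] - istate[I_CARGO_ER] - istate[I_CARGO_TGN]:
        return False
    return True


@njit(cache=True)
def _log_event(ev, ev_n, t, kind, donor_id, acceptor_id, ident,
               dn, dc, dm, dt_, ac, am, at_, cargo_moved):
    r = ev_n[0]
    ev[r, 0] = t
    ev[r, 1] = kind
    ev[r, 2] = donor_id
    ev[r, 3] = acceptor_id
    ev[r, 4] = ident
    ev[r, 5] = dn
    ev[r, 6] = dc
    ev[r, 7] = dm
    ev[r, 8] = dt_
    ev[r, 9] = ac
    ev[r, 10] = am
    ev[r, 11] = at_
    ev[r, 12] = cargo_moved
    ev_n[0] = r + 1


@njit(cache=True)
def _log_transport(tr, tr_n, t, ident, d0, d1, d2, a0, a1, a2,
                   cargo, back_fusion, is_exit, donor_uid, acceptor_uid):
    r = tr_n[0]
    tr[r, 0] = t
    tr[r, 1] = ident
    tr[r, 2] = d0
    tr[r, 3] = d1
    tr[r, 4] = d2
    tr[r, 5] = a0
    tr[r, 6] = a1
    tr[r, 7] = a2
    tr[r, 8] = cargo
    tr[r, 9] = back_fusion
    tr[r, 10] = is_exit
    tr[r, 11] = donor_uid
    tr[r, 12] = acceptor_uid
    tr_n[0] = r + 1


@njit(cache=True)
def _advance(cnt, cargo, uid, bud_flag, bud_ident, bud_donor_uid, bud_phi,
             bud_time, order, pos, fstate, istate, rstate, pf,
             t_end, max_events, ev, ev_n, tr, tr_n, log_events, validate):
    """Advance the system to ``t_end`` or by ``max_events`` events.

    Mutates all state arrays in place; returns a status code.
    """
    cap = order.shape[0]
    j = pf[P_J]
    kb = pf[P_KB]
    km = pf[P_KM]
    aer = pf[P_AER]
    atgn = pf[P_ATGN]
    fusion_on = pf[P_FUSION_ON] > 0.5
    linear = pf[P_LINEAR] > 0.5
    cargo_cont = pf[P_CARGO_CONT]

    S = np.zeros(3, dtype=np.float64)
    Q = np.zeros(3, dtype=np.float64)
    C = np.zeros(3, dtype=np.int64)
    agg = np.zeros(2, dtype=np.float64)
    m = istate[I_M]
    _rebuild_sums(cnt, order, m, S, Q, C, agg)

    t = fstate[F_TIME]
    done = np.int64(0)

    while True:
        if done >= max_events:
            fstate[F_TIME] = t
            return MAX_EVENTS
        if m + 1 >= cap:
            fstate[F_TIME] = t
            return SLOTS_FULL
        if log_events and ev_n[0] >= ev.shape[0]:
            fstate[F_TIME] = t
            return EVLOG_FULL
        if tr_n[0] + 2 >= tr.shape[0]:
            fstate[F_TIME] = t
            return TRLOG_FULL

        # --- class propensities ---
        r_inj = j
        r_fus = 0.0
        if fusion_on and m >= 2:
            for i in range(3):
                d = S[i] * S[i] - Q[i]
                if d > 0.0:
                    r_fus += d
            r_fus *= 0.5
        r_er = aer * S[0]
        r_tgn = atgn * S[2]
        r_bud = kb * (agg[1] if linear else agg[0])
        r_conv = km * np.float64(C[0] + C[1])
        r_total = r_inj + r_fus + r_er + r_tgn + r_bud + r_conv

        if r_total <= 0.0:
            fstate[F_TIME] = t_end
            return OK

        dt = -np.log(_u01(rstate)) / r_total
        if t + dt > t_end:
            fstate[F_TIME] = t_end
            return OK
        t += dt

        u = _u01(rstate) * r_total

        if u < r_inj:
            # ---- injection: a new pure cis vesicle from the ER ----
            s = order[m]
            cnt[s, 0] = 1
            cnt[s, 1] = 0
            cnt[s, 2] = 0
            c_new = 0
            if istate[I_PULSE] > 0:
                c_new = 1
                istate[I_PULSE] -= 1
            elif cargo_cont > 0.0 and _u01(rstate) < cargo_cont:
                c_new = 1
            cargo[s] = c_new
            istate[I_CARGO_INJ] += c_new
            uid[s] = istate[I_NEXT_UID]
            istate[I_NEXT_UID] += 1
            bud_flag[s] = 0
            pos[s] = m
            m += 1
            istate[I_INJECTED] += 1
            _contrib(cnt, s, 1, S, Q, C, agg)
            if log_events:
                _log_event(ev, ev_n, t, EV_INJECTION, uid[s], -3, 0,
                           1, 1, 0, 0, -1, -1, -1, c_new)
        elif u < r_inj + r_fus:
            # ---- inter-compartment fusion ----
            # identity of the matching contact site
            v = _u01(rstate) * (2.0 * r_fus)
            ident = 2
            acc = 0.0
            for i in range(3):
                d = S[i] * S[i] - Q[i]
                if d > 0.0:
                    acc += d
                    if acc >= v:
                        ident = i
                        break
            # rejection-sample an unordered distinct pair ~ phi_i(a)*phi_i(b)
            a = -1
            b = -1
            for _try in range(10000):
                a = _sample_phi(cnt, order, m, ident, _u01(rstate) * S[ident])
                b = _sample_phi(cnt, order, m, ident, _u01(rstate) * S[ident])
                if a != b and a >= 0 and b >= 0:
                    break
            if a == b or a < 0 or b < 0:
                # numerically degenerate (e.g. single compartment carries all
                # of S_i); treat as a no-flux tick
                continue
            na = cnt[a, 0] + cnt[a, 1] + cnt[a, 2]
            nb = cnt[b, 0] + cnt[b, 1] + cnt[b, 2]
            fa0 = np.float64(cnt[a, 0]) / na
            fa1 = np.float64(cnt[a, 1]) / na
            fa2 = np.float64(cnt[a, 2]) / na
            fb0 = np.float64(cnt[b, 0]) / nb
            fb1 = np.float64(cnt[b, 1]) / nb
            fb2 = np.float64(cnt[b, 2]) / nb
            # transport bookkeeping: a budded vesicle carrying cargo fuses
            if bud_flag[a] == 1 and cargo[a] > 0:
                back = 1.0 if uid[b] == bud_donor_uid[a] else 0.0
                _log_transport(tr, tr_n, t, bud_ident[a],
                               bud_phi[a, 0], bud_phi[a, 1], bud_phi[a, 2],
                               fb0, fb1, fb2, cargo[a], back, 0.0,
                               bud_donor_uid[a], uid[b])
            if bud_flag[b] == 1 and cargo[b] > 0:
                back = 1.0 if uid[a] == bud_donor_uid[b] else 0.0
                _log_transport(tr, tr_n, t, bud_ident[b],
                               bud_phi[b, 0], bud_phi[b, 1], bud_phi[b, 2],
                               fa0, fa1, fa2, cargo[b], back, 0.0,
                               bud_donor_uid[b], uid[a])
            if log_events:
                _log_event(ev, ev_n, t, EV_FUSION, uid[a], uid[b], ident,
                           na, cnt[a, 0], cnt[a, 1], cnt[a, 2],
                           cnt[b, 0], cnt[b, 1], cnt[b, 2], cargo[b])
            _contrib(cnt, a, -1, S, Q, C, agg)
            _contrib(cnt, b, -1, S, Q, C, agg)
            for i in range(3):
                cnt[a, i] += cnt[b, i]
            cargo[a] += cargo[b]
            bud_flag[a] = 0
            # swap-remove b from the dense order list
            pb = pos[b]
            last_slot = order[m - 1]
            order[pb] = last_slot
            pos[last_slot] = pb
            order[m - 1] = b
            pos[b] = m - 1
            m -= 1
            _contrib(cnt, a, 1, S, Q, C, agg)
        elif u < r_inj + r_fus + r_er + r_tgn:
            # ---- boundary fusion (exit) ----
            if u < r_inj + r_fus + r_er:
                ident = 0
                acceptor = ACCEPTOR_ER
            else:
                ident = 2
                acceptor = ACCEPTOR_TGN
            a = _sample_phi(cnt, order, m, ident, _u01(rstate) * S[ident])
            if a < 0:
                continue
            na = cnt[a, 0] + cnt[a, 1] + cnt[a, 2]
            if bud_flag[a] == 1 and cargo[a] > 0:
                a0 = 1.0 if acceptor == ACCEPTOR_ER else 0.0
                a2 = 1.0 if acceptor == ACCEPTOR_TGN else 0.0
                _log_transport(tr, tr_n, t, bud_ident[a],
                               bud_phi[a, 0], bud_phi[a, 1], bud_phi[a, 2],
                               a0, 0.0, a2, cargo[a], 0.0, 1.0,
                               bud_donor_uid[a], acceptor)
            if log_events:
                _log_event(ev, ev_n, t, EV_BOUNDARY_FUSION, uid[a], acceptor,
                           ident, na, cnt[a, 0], cnt[a, 1], cnt[a, 2],
                           -1, -1, -1, cargo[a])
            _contrib(cnt, a, -1, S, Q, C, agg)
            if acceptor == ACCEPTOR_ER:
                istate[I_EXIT_ER] += na
                istate[I_CARGO_ER] += cargo[a]
            else:
                istate[I_EXIT_TGN] += na
                istate[I_CARGO_TGN] += cargo[a]
            pa = pos[a]
            last_slot = order[m - 1]
            order[pa] = last_slot
            pos[last_slot] = pa
            order[m - 1] = a
            pos[a] = m - 1
            m -= 1
        elif u < r_inj + r_fus + r_er + r_tgn + r_bud:
            # ---- vesicle budding ----
            w_total = agg[1] if linear else agg[0]
            a = _sample_budding(cnt, order, m, linear, _u01(rstate) * w_total)
            if a < 0:
                continue
            na = cnt[a, 0] + cnt[a, 1] + cnt[a, 2]
            # identity: uniform over present identities (saturated) or ~ n_i
            if linear:
                v = _u01(rstate) * np.float64(na)
                ident = 2
                acc = 0.0
                for i in range(3):
                    acc += np.float64(cnt[a, i])
                    if acc >= v:
                        ident = i
                        break
            else:
                k = 0
                for i in range(3):
                    if cnt[a, i] > 0:
                        k += 1
                pick = np.int64(_u01(rstate) * k)
                if pick >= k:
                    pick = k - 1
                ident = 0
                seen = -1
                for i in range(3):
                    if cnt[a, i] > 0:
                        seen += 1
                        if seen == pick:
                            ident = i
                            break
            f0 = np.float64(cnt[a, 0]) / na
            f1 = np.float64(cnt[a, 1]) / na
            f2 = np.float64(cnt[a, 2]) / na
            # each cargo joins the vesicle independently with probability 1/n
            moved = 0
            if cargo[a] > 0:
                inv_n = 1.0 / np.float64(na)
                for _c in range(cargo[a]):
                    if _u01(rstate) < inv_n:
                        moved += 1
            _contrib(cnt, a, -1, S, Q, C, agg)
            cnt[a, ident] -= 1
            cargo[a] -= moved
            _contrib(cnt, a, 1, S, Q, C, agg)
            s = order[m]
            cnt[s, 0] = 0
            cnt[s, 1] = 0
            cnt[s, 2] = 0
            cnt[s, ident] = 1
            cargo[s] = moved
            uid[s] = istate[I_NEXT_UID]
            istate[I_NEXT_UID] += 1
            bud_flag[s] = 1
            bud_ident[s] = ident
            bud_donor_uid[s] = uid[a]
            bud_phi[s, 0] = f0
            bud_phi[s, 1] = f1
            bud_phi[s, 2] = f2
            bud_time[s] = t
            pos[s] = m
            m += 1
            _contrib(cnt, s, 1, S, Q, C, agg)
            if log_events:
                _log_event(ev, ev_n, t, EV_BUDDING, uid[a], uid[s], ident,
                           na, cnt[a, 0], cnt[a, 1], cnt[a, 2],
                           cnt[s, 0], cnt[s, 1], cnt[s, 2], moved)
        else:
            # ---- biochemical conversion (cis->medial or medial->trans) ----
            v = _u01(rstate) * np.float64(C[0] + C[1])
            src = 0 if v < np.float64(C[0]) else 1
            a = _sample_count(cnt, order, m, src, _u01(rstate) * np.float64(C[src]))
            if a < 0:
                continue
            _contrib(cnt, a, -1, S, Q, C, agg)
            cnt[a, src] -= 1
            cnt[a, src + 1] += 1
            _contrib(cnt, a, 1, S, Q, C, agg)
            if log_events:
                na = cnt[a, 0] + cnt[a, 1] + cnt[a, 2]
                _log_event(ev, ev_n, t, EV_CONVERSION, uid[a], -3, src,
                           na, cnt[a, 0], cnt[a, 1], cnt[a, 2],
                           -1, -1, -1, 0)

        done += 1
        istate[I_NEVENTS] += 1
        istate[I_M] = m
        if validate:
            if not _validate(cnt, cargo, order, m, istate):
                fstate[F_TIME] = t
                return INVALID

    # unreachable
    fstate[F_TIME] = t
    return OK
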