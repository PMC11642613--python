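"""Numba kernel for the kinetic Monte Carlo evolution of the lattice model.

The state lives in arrays indexed by chamber ``ch = row * n_cols + col``:

* ``cnt[4, n_chambers]`` -- per-type occupancies (melanoma, active T,
  exhausted T, TAM in that order),
* ``total[n_chambers]`` -- per-chamber totals (capped at ``cap``),
* per-type occupied-chamber lists (``occ``, ``occ_len``, ``occ_pos``) for
  O(1) uniform sampling of a cell of a given type by rejection,
* ``pair[0]`` -- number of (active T, melanoma) contact pairs under the
  contact neighborhood (a shared chamber counts as contact),
* ``pair[1]`` -- number of (active T, TAM) same-chamber pairs.

Pair counts are integers maintained incrementally, so event rates are exact
at every step.  Sampling a uniform cell of a type draws a uniformly random
occupied chamber and accepts it with probability ``count / cap``; sampling
the active T cell of a contact pair additionally accepts with probability
proportional to its local partner count.  Both rejection loops terminate
almost surely whenever the corresponding aggregate rate is positive.

Everything is written as closures inside one jitted function: numba inlines
closure calls, which keeps the event loop free of function-call overhead.
Random numbers come from an inline splitmix64 stream seeded per run, so a
fixed seed yields a bit-identical trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEL, TA, TEX, TAM = 0, 1, 2, 3

# order of entries in the flat rate-parameter vector handed to the kernel
RATE_FIELDS = (
    "r_prolif_mel",
    "l",
    "bC",
    "bM",
    "r_death_ex",
    "r_hop_T",
    "r_hop_M",
    "r_prolif_T0",
    "k_prolif",
    "r_recruit0",
    "k_recruit",
    "dt_feedback",
)

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def run_kmc(
    counts0,  # (4, n_chambers) int64, flattened row-major chambers
    nr,
    nc,
    cap,
    rates,  # float64 vector ordered as RATE_FIELDS
    t_end,
    rec_times,  # float64, strictly increasing, rec_times[0] == 0
    snap_times,  # float64, strictly increasing (may be empty)
    contact_moore,  # bool: Moore-8 contact neighborhood (else von Neumann-4)
    hop_moore,  # bool: Moore-8 hop neighborhood (else von Neumann-4)
    seed,  # uint64
):
    """Run one stochastic trajectory; returns (counts_out, snaps, n_events).

    ``counts_out`` holds the four population counts at each recording time
    (last state carried forward); ``snaps`` holds full lattices at the
    requested snapshot times.
    """
    nch = nr * nc
    cnt = counts0.copy()
    total = np.zeros(nch, np.int64)
    occ = np.zeros((4, nch), np.int64)
    occ_len = np.zeros(4, np.int64)
    occ_pos = np.full((4, nch), -1, np.int64)
    ncells = np.zeros(4, np.int64)
    # monotone upper bound on the per-chamber occupancy of each type; used
    # as the rejection-sampling envelope (never decreased, so always valid;
    # stays tight for small caps and adapts when cap is effectively infinite)
    maxb = np.ones(4, np.int64)
    pair = np.zeros(2, np.int64)
    rs = np.empty(1, np.uint64)
    rs[0] = np.uint64(seed)

    def rand():
        # splitmix64, mapped to a float in [0, 1)
        rs[0] += _GAMMA
        z = rs[0]
        z = (z ^ (z >> np.uint64(30))) * _MIX1
        z = (z ^ (z >> np.uint64(27))) * _MIX2
        z = z ^ (z >> np.uint64(31))
        return np.float64(z >> np.uint64(11)) * _INV53

    def csum(tp, ch):
        # occupancy of type tp summed over the contact neighborhood of ch
        r = ch // nc
        c = ch % nc
        s = cnt[tp, ch]
        if r > 0:
            s += cnt[tp, ch - nc]
        if r < nr - 1:
            s += cnt[tp, ch + nc]
        if c > 0:
            s += cnt[tp, ch - 1]
        if c < nc - 1:
            s += cnt[tp, ch + 1]
        if contact_moore:
            if r > 0 and c > 0:
                s += cnt[tp, ch - nc - 1]
            if r > 0 and c < nc - 1:
                s += cnt[tp, ch - nc + 1]
            if r < nr - 1 and c > 0:
                s += cnt[tp, ch + nc - 1]
            if r < nr - 1 and c < nc - 1:
                s += cnt[tp, ch + nc + 1]
        return s

    def apply(tp, ch, d):
        # add (d=+1) or remove (d=-1) one cell of type tp at chamber ch,
        # maintaining occupancies, occupied lists, and the pair counts; the
        # pair updates read only the partner type, so call order is free
        if tp == MEL:
            pair[0] += d * csum(TA, ch)
        elif tp == TA:
            pair[0] += d * csum(MEL, ch)
            pair[1] += d * cnt[TAM, ch]
        elif tp == TAM:
            pair[1] += d * cnt[TA, ch]
        old = cnt[tp, ch]
        cnt[tp, ch] = old + d
        total[ch] += d
        ncells[tp] += d
        if cnt[tp, ch] > maxb[tp]:
            maxb[tp] = cnt[tp, ch]
        if d > 0 and old == 0:
            occ_pos[tp, ch] = occ_len[tp]
            occ[tp, occ_len[tp]] = ch
            occ_len[tp] += 1
        elif d < 0 and old == 1:
            i = occ_pos[tp, ch]
            last = occ_len[tp] - 1
            moved = occ[tp, last]
            occ[tp, i] = moved
            occ_pos[tp, moved] = i
            occ_len[tp] = last
            occ_pos[tp, ch] = -1

    def sample(tp):
        # chamber of a uniformly random cell of type tp (caller guarantees
        # ncells[tp] > 0)
        ch = np.int64(-1)
        while ch < 0:
            j = np.int64(rand() * occ_len[tp])
            if j >= occ_len[tp]:
                j = occ_len[tp] - 1
            c0 = occ[tp, j]
            if rand() * maxb[tp] < cnt[tp, c0]:
                ch = c0
        return ch

    def place_daughter(tp, ch):
        # newborn goes to its parent's chamber if that has capacity, else to
        # a uniformly chosen hop-neighborhood chamber with capacity, else
        # the division is a null event
        if total[ch] < cap:
            apply(tp, ch, 1)
        else:
            r = ch // nc
            c = ch % nc
            free = np.empty(8, np.int64)
            nfree = 0
            if r > 0 and total[ch - nc] < cap:
                free[nfree] = ch - nc
                nfree += 1
            if r < nr - 1 and total[ch + nc] < cap:
                free[nfree] = ch + nc
                nfree += 1
            if c > 0 and total[ch - 1] < cap:
                free[nfree] = ch - 1
                nfree += 1
            if c < nc - 1 and total[ch + 1] < cap:
                free[nfree] = ch + 1
                nfree += 1
            if hop_moore:
                if r > 0 and c > 0 and total[ch - nc - 1] < cap:
                    free[nfree] = ch - nc - 1
                    nfree += 1
                if r > 0 and c < nc - 1 and total[ch - nc + 1] < cap:
                    free[nfree] = ch - nc + 1
                    nfree += 1
                if r < nr - 1 and c > 0 and total[ch + nc - 1] < cap:
                    free[nfree] = ch + nc - 1
                    nfree += 1
                if r < nr - 1 and c < nc - 1 and total[ch + nc + 1] < cap:
                    free[nfree] = ch + nc + 1
                    nfree += 1
            if nfree > 0:
                k = np.int64(rand() * nfree)
                if k >= nfree:
                    k = nfree - 1
                apply(tp, free[k], 1)

    # ---- initial bookkeeping -------------------------------------------
    for t4 in range(4):
        for ch in range(nch):
            if cnt[t4, ch] > 0:
                total[ch] += cnt[t4, ch]
                occ_pos[t4, ch] = occ_len[t4]
                occ[t4, occ_len[t4]] = ch
                occ_len[t4] += 1
                ncells[t4] += cnt[t4, ch]
                if cnt[t4, ch] > maxb[t4]:
                    maxb[t4] = cnt[t4, ch]
    for ch in range(nch):
        if cnt[TA, ch] > 0:
            pair[0] += cnt[TA, ch] * csum(MEL, ch)
            pair[1] += cnt[TA, ch] * cnt[TAM, ch]

    rpm = rates[0]
    lys = rates[1]
    bC = rates[2]
    bM = rates[3]
    rdx = rates[4]
    rhT = rates[5]
    rhM = rates[6]
    rpT0 = rates[7]
    kp = rates[8]
    rrec0 = rates[9]
    krec = rates[10]
    dt_fb = rates[11]

    n_rec = rec_times.size
    n_snap = snap_times.size
    out = np.zeros((n_rec, 4), np.int64)
    snaps = np.zeros((n_snap, 4, nch), np.int64)
    ri = 0
    si = 0

    t = 0.0
    lysed_window = 0  # melanoma lysed in the current feedback window
    L = 0.0  # lysed count of the previous completed window
    next_win = dt_fb
    n_events = 0

    while t < t_end:
        r_pm = rpm * ncells[MEL]
        r_ly = lys * pair[0]
        r_bc = bC * pair[0]
        r_bm = bM * pair[1]
        r_pt = (rpT0 + kp * L) * ncells[TA]
        r_rc = rrec0 + krec * L
        r_dx = rdx * ncells[TEX]
        r_ht = rhT * ncells[TA]
        r_he = rhT * ncells[TEX]
        r_hm = rhM * ncells[TAM]
        r_tot = r_pm + r_ly + r_bc + r_bm + r_pt + r_rc + r_dx + r_ht + r_he + r_hm
        if r_tot <= 0.0:
            break
        u = rand()
        while u <= 0.0:
            u = rand()
        t_next = t - np.log(u) / r_tot

        if t_next >= next_win and next_win < t_end:
            # cross the feedback-window boundary: no event fires there, but
            # the feedback rates change, so redraw the waiting time from the
            # boundary (valid by memorylessness of the exponential clock)
            while ri < n_rec and rec_times[ri] <= next_win:
                out[ri, 0] = ncells[0]
                out[ri, 1] = ncells[1]
                out[ri, 2] = ncells[2]
                out[ri, 3] = ncells[3]
                ri += 1
            while si < n_snap and snap_times[si] <= next_win:
                snaps[si] = cnt
                si += 1
            t = next_win
            L = float(lysed_window)
            lysed_window = 0
            next_win += dt_fb
            continue

        if t_next >= t_end:
            t = t_end
            break

        # record states strictly before the event (carry-forward convention)
        while ri < n_rec and rec_times[ri] < t_next:
            out[ri, 0] = ncells[0]
            out[ri, 1] = ncells[1]
            out[ri, 2] = ncells[2]
            out[ri, 3] = ncells[3]
            ri += 1
        while si < n_snap and snap_times[si] < t_next:
            snaps[si] = cnt
            si += 1
        t = t_next
        n_events += 1

        x = rand() * r_tot
        if x < r_pm:
            # melanoma division
            place_daughter(MEL, sample(MEL))
        elif x < r_pm + r_ly:
            # lysis: pick the active T of a uniform (T, melanoma) contact
            # pair, then remove a uniform melanoma cell among its contacts
            wmax = (9 if contact_moore else 5) * maxb[MEL]
            ch = np.int64(-1)
            while ch < 0:
                c0 = sample(TA)
                if rand() * wmax < csum(MEL, c0):
                    ch = c0
            w = np.int64(rand() * csum(MEL, ch))
            r = ch // nc
            c = ch % nc
            victim = np.int64(-1)
            # walk the neighborhood in the same deterministic order as csum
            w -= cnt[MEL, ch]
            if w < 0:
                victim = ch
            if victim < 0 and r > 0:
                w -= cnt[MEL, ch - nc]
                if w < 0:
                    victim = ch - nc
            if victim < 0 and r < nr - 1:
                w -= cnt[MEL, ch + nc]
                if w < 0:
                    victim = ch + nc
            if victim < 0 and c > 0:
                w -= cnt[MEL, ch - 1]
                if w < 0:
                    victim = ch - 1
            if victim < 0 and c < nc - 1:
                w -= cnt[MEL, ch + 1]
                if w < 0:
                    victim = ch + 1
            if victim < 0 and contact_moore:
                if r > 0 and c > 0:
                    w -= cnt[MEL, ch - nc - 1]
                    if w < 0:
                        victim = ch - nc - 1
                if victim < 0 and r > 0 and c < nc - 1:
                    w -= cnt[MEL, ch - nc + 1]
                    if w < 0:
                        victim = ch - nc + 1
                if victim < 0 and r < nr - 1 and c > 0:
                    w -= cnt[MEL, ch + nc - 1]
                    if w < 0:
                        victim = ch + nc - 1
                if victim < 0 and r < nr - 1 and c < nc - 1:
                    w -= cnt[MEL, ch + nc + 1]
                    if w < 0:
                        victim = ch + nc + 1
            if victim < 0:
                victim = ch  # guard; unreachable with exact integer weights
            apply(MEL, victim, -1)
            lysed_window += 1
        elif x < r_pm + r_ly + r_bc:
            # exhaustion of an active T by melanoma contact
            wmax = (9 if contact_moore else 5) * maxb[MEL]
            ch = np.int64(-1)
            while ch < 0:
                c0 = sample(TA)
                if rand() * wmax < csum(MEL, c0):
                    ch = c0
            apply(TA, ch, -1)
            apply(TEX, ch, 1)
        elif x < r_pm + r_ly + r_bc + r_bm:
            # exhaustion of an active T by a TAM in the same chamber
            ch = np.int64(-1)
            while ch < 0:
                c0 = sample(TA)
                if rand() * maxb[TAM] < cnt[TAM, c0]:
                    ch = c0
            apply(TA, ch, -1)
            apply(TEX, ch, 1)
        elif x < r_pm + r_ly + r_bc + r_bm + r_pt:
            # active T division
            place_daughter(TA, sample(TA))
        elif x < r_pm + r_ly + r_bc + r_bm + r_pt + r_rc:
            # recruitment of an active T into a uniform chamber with capacity
            ntot = ncells[0] + ncells[1] + ncells[2] + ncells[3]
            if ntot < cap * nch:
                ch = np.int64(-1)
                while ch < 0:
                    c0 = np.int64(rand() * nch)
                    if c0 >= nch:
                        c0 = nch - 1
                    if total[c0] < cap:
                        ch = c0
                apply(TA, ch, 1)
        elif x < r_pm + r_ly + r_bc + r_bm + r_pt + r_rc + r_dx:
            # death of an exhausted T
            apply(TEX, sample(TEX), -1)
        else:
            # diffusive hop of an active T, exhausted T, or TAM
            if x < r_pm + r_ly + r_bc + r_bm + r_pt + r_rc + r_dx + r_ht:
                tp = TA
            elif x < r_pm + r_ly + r_bc + r_bm + r_pt + r_rc + r_dx + r_ht + r_he:
                tp = TEX
            else:
                tp = TAM
            ch = sample(tp)
            r = ch // nc
            c = ch % nc
            ndir = 8 if hop_moore else 4
            k = np.int64(rand() * ndir)
            if k >= ndir:
                k = ndir - 1
            if k == 0:
                r2, c2 = r - 1, c
            elif k == 1:
                r2, c2 = r + 1, c
            elif k == 2:
                r2, c2 = r, c - 1
            elif k == 3:
                r2, c2 = r, c + 1
            elif k == 4:
                r2, c2 = r - 1, c - 1
            elif k == 5:
                r2, c2 = r - 1, c + 1
            elif k == 6:
                r2, c2 = r + 1, c - 1
            else:
                r2, c2 = r + 1, c + 1
            if 0 <= r2 < nr and 0 <= c2 < nc:
                ch2 = r2 * nc + c2
                if total[ch2] < cap:
                    apply(tp, ch, -1)
                    apply(tp, ch2, 1)
            # off-grid or full target: null event (reflecting boundary)

    # flush remaining recording / snapshot times with the final state
    while ri < n_rec:
        out[ri, 0] = ncells[0]
        out[ri, 1] = ncells[1]
        out[ri, 2] = ncells[2]
        out[ri, 3] = ncells[3]
        ri += 1
    while si < n_snap:
        snaps[si] = cnt
        si += 1
    return out, snaps, n_events
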