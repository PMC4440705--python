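"""Compiled SSA kernel.

Flat-array implementation of the exact (direct-method) stochastic simulation
over the dynamic channel set of one cell.  The event mechanics are the same
as the object-level :mod:`mitoqc.events` module, which serves as the readable
reference; this kernel exists because desk-scale ensembles execute tens of
millions of events.

State layout (row ``i`` = one mitochondrion, rows ``0..n-1`` active):

* ``segW[i, k]``, ``segM[i, k]`` — WT/mutant nucleoid counts of the ``k``-th
  subcompartment; ``nseg[i]`` chain length; ``comp[i]`` compartment index.
* removal is swap-with-last, so row order carries no meaning.

Parameter vector ``P`` (powers of the threshold midpoints are precomputed):
``[k_D, r_D_max, K_D^m, m, a_R0/N_ss, r_R_max, K_R^m, k_R, a_fus_eff,
r_fusion_max, K_fusion^m, V_F_eff, K_F^n, n]``.
Flag vector: ``[replication, mitophagy, fusion, fission, retrograde_uses_cell
fraction, track_episodes]``.

Mutant-rich episode bookkeeping is per row (per mitochondrion lineage): an
episode opens when a row's mutant fraction first exceeds the threshold and
closes when that row's fraction drops back, the row fuses away, or the row is
removed.  Episodes still open at ``t_end`` are closed there and counted as
censored.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EMPTY = 1  # population extinct (terminated-empty cell)
STATUS_CAP_MITO = 2  # mitochondria capacity exhausted — retry larger
STATUS_CAP_SEG = 3  # chain capacity exhausted — retry larger
STATUS_SATURATED = 4  # nucleoid count hit the divergence guard; state frozen

# indices into the out[] vector
O_MITO_DAYS = 0
O_EP_STARTS = 1
O_EP_COUNT = 2
O_EP_DURSUM = 3
O_EP_CENSORED = 4
O_N_EVENTS = 5
O_N_FINAL = 6


@njit(cache=True, inline="always")
def _update_cache(i, segW, segM, nseg, totW, totM, R, aD, fis, rsel, P):
    w = 0
    m_ = 0
    for k in range(nseg[i]):
        w += segW[i, k]
        m_ += segM[i, k]
    totW[i] = w
    totM[i] = m_
    tot = w + m_
    r = m_ / tot
    R[i] = r
    if r > 0.0:
        rm = r ** P[3]
        sD = rm / (P[2] + rm)
        sF = rm / (P[10] + rm)
    else:
        sD = 0.0
        sF = 0.0
    aD[i] = P[0] * (P[1] * sD + 1.0)
    rsel[i] = 1.0 - P[9] * sF
    if tot < 2:
        fis[i] = 0.0
    else:
        tn = float(tot) ** P[13]
        fis[i] = P[11] * tn / (P[12] + tn)


@njit(cache=True, inline="always")
def _emit(ri, n, Wtot, Mtot, R, snap_r, snap_nm, snap_nuc, snap_rbar, snap_cov):
    snap_nm[ri] = n
    snap_nuc[ri] = Wtot + Mtot
    if n == 0 or Wtot + Mtot == 0:
        snap_r[ri] = np.nan
        snap_rbar[ri] = np.nan
        snap_cov[ri] = np.nan
        return
    snap_r[ri] = Mtot / (Wtot + Mtot)
    mean = 0.0
    for i in range(n):
        mean += R[i]
    mean /= n
    snap_rbar[ri] = mean
    if n >= 2 and mean > 0.0:
        var = 0.0
        for i in range(n):
            d = R[i] - mean
            var += d * d
        snap_cov[ri] = np.sqrt(var / n) / mean
    else:
        snap_cov[ri] = np.nan


@njit(cache=True)
def run_ssa(
    seed,
    t0,
    t_end,
    rec,
    P,
    flags,
    thresh,
    nuc_cap,
    nbr,
    deg,
    edges,
    segW,
    segM,
    nseg,
    comp,
    n_mito_in,
    snap_r,
    snap_nm,
    snap_nuc,
    snap_rbar,
    snap_cov,
    ep_durs,
    out,
):
    np.random.seed(seed)
    cap_m, cap_s = segW.shape
    nc = nbr.shape[0]
    ne = edges.shape[0]

    totW = np.zeros(cap_m, np.int64)
    totM = np.zeros(cap_m, np.int64)
    R = np.zeros(cap_m)
    aD = np.zeros(cap_m)
    fis = np.zeros(cap_m)
    rsel = np.zeros(cap_m)
    rich = np.zeros(cap_m, np.uint8)
    ep_start = np.zeros(cap_m)

    n = n_mito_in
    Wtot = 0
    Mtot = 0
    for i in range(n):
        _update_cache(i, segW, segM, nseg, totW, totM, R, aD, fis, rsel, P)
        Wtot += totW[i]
        Mtot += totM[i]

    rep_on = flags[0] == 1
    mito_on = flags[1] == 1
    fus_on = flags[2] == 1
    fis_on = flags[3] == 1
    retro_cell = flags[4] == 1
    track = flags[5] == 1

    ep_starts = 0
    ep_cnt = 0
    ep_dursum = 0.0
    censored = 0
    mito_days = 0.0
    nev = 0

    if track:
        for i in range(n):
            if R[i] > thresh:
                rich[i] = 1
                ep_start[i] = t0
                ep_starts += 1

    t = t0
    ri = 0
    nrec = rec.shape[0]
    S = np.zeros(nc)
    Q = np.zeros(nc)
    status = STATUS_OK

    while True:
        # ---- total propensity from cached per-row values ---------------
        aDtot = 0.0
        fistot = 0.0
        sumR = 0.0
        for c in range(nc):
            S[c] = 0.0
            Q[c] = 0.0
        for i in range(n):
            aDtot += aD[i]
            fistot += fis[i]
            sumR += R[i]
            c = comp[i]
            rs = rsel[i]
            S[c] += rs
            Q[c] += rs * rs
        fustot = 0.0
        if fus_on:
            for c in range(nc):
                v = (S[c] * S[c] - Q[c]) * 0.5
                if v > 0.0:
                    fustot += v
            for e in range(ne):
                fustot += S[edges[e, 0]] * S[edges[e, 1]]
            fustot *= P[8]
        if not mito_on:
            aDtot = 0.0
        if not fis_on:
            fistot = 0.0
        reptot = 0.0
        if rep_on and n > 0:
            if retro_cell:
                rbar_in = Mtot / (Wtot + Mtot)
            else:
                rbar_in = sumR / n
            if rbar_in > 0.0:
                rm = rbar_in ** P[3]
                sR = rm / (P[6] + rm)
            else:
                sR = 0.0
            reptot = P[4] * (P[5] * sR + 1.0) * (Wtot + P[7] * Mtot)

        A = reptot + aDtot + fistot + fustot
        if A <= 0.0 or n == 0:
            while ri < nrec:
                _emit(ri, n, Wtot, Mtot, R, snap_r, snap_nm, snap_nuc, snap_rbar, snap_cov)
                ri += 1
            mito_days += n * (t_end - t)
            t = t_end
            break

        dt = -np.log(np.random.random()) / A
        tnew = t + dt
        if tnew >= t_end:
            # the state is frozen past t_end, so flush every remaining
            # sample (grid endpoints may sit a rounding error above t_end)
            while ri < nrec:
                _emit(ri, n, Wtot, Mtot, R, snap_r, snap_nm, snap_nuc, snap_rbar, snap_cov)
                ri += 1
            mito_days += n * (t_end - t)
            t = t_end
            break
        while ri < nrec and rec[ri] <= tnew:
            _emit(ri, n, Wtot, Mtot, R, snap_r, snap_nm, snap_nuc, snap_rbar, snap_cov)
            ri += 1
        mito_days += n * dt
        t = tnew
        nev += 1

        u = np.random.random() * A
        # ---- replication ----------------------------------------------
        if u < reptot:
            um = np.random.random() * (Wtot + P[7] * Mtot)
            is_mut = um >= Wtot
            sel = -1
            if is_mut:
                tgt = np.random.random() * Mtot
                acc = 0.0
                last = -1
                for i in range(n):
                    if totM[i] > 0:
                        last = i
                        acc += totM[i]
                        if tgt < acc:
                            sel = i
                            break
                if sel < 0:
                    sel = last
                tg2 = np.random.random() * totM[sel]
                acc = 0.0
                ks = 0
                for k in range(nseg[sel]):
                    if segM[sel, k] > 0:
                        ks = k
                        acc += segM[sel, k]
                        if tg2 < acc:
                            break
                segM[sel, ks] += 1
                Mtot += 1
            else:
                tgt = np.random.random() * Wtot
                acc = 0.0
                last = -1
                for i in range(n):
                    if totW[i] > 0:
                        last = i
                        acc += totW[i]
                        if tgt < acc:
                            sel = i
                            break
                if sel < 0:
                    sel = last
                tg2 = np.random.random() * totW[sel]
                acc = 0.0
                ks = 0
                for k in range(nseg[sel]):
                    if segW[sel, k] > 0:
                        ks = k
                        acc += segW[sel, k]
                        if tg2 < acc:
                            break
                segW[sel, ks] += 1
                Wtot += 1
            _update_cache(sel, segW, segM, nseg, totW, totM, R, aD, fis, rsel, P)
            if track:
                nr = R[sel] > thresh
                if nr and rich[sel] == 0:
                    rich[sel] = 1
                    ep_start[sel] = t
                    ep_starts += 1
                elif (not nr) and rich[sel] == 1:
                    rich[sel] = 0
                    d = t - ep_start[sel]
                    ep_dursum += d
                    if ep_cnt < ep_durs.shape[0]:
                        ep_durs[ep_cnt] = d
                    ep_cnt += 1
            if Wtot + Mtot >= nuc_cap:
                # runaway retrograde-driven growth: freeze the state and
                # carry the current statistics through the remaining samples
                status = STATUS_SATURATED
                while ri < nrec:
                    _emit(ri, n, Wtot, Mtot, R, snap_r, snap_nm, snap_nuc,
                          snap_rbar, snap_cov)
                    ri += 1
                mito_days += n * (t_end - t)
                t = t_end
                break
            continue

        # ---- mitophagy -------------------------------------------------
        u -= reptot
        if u < aDtot:
            tgt = u  # reuse the residual as the selection variate
            acc = 0.0
            sel = n - 1
            for i in range(n):
                acc += aD[i]
                if tgt < acc:
                    sel = i
                    break
            if track and rich[sel] == 1:
                rich[sel] = 0
                d = t - ep_start[sel]
                ep_dursum += d
                if ep_cnt < ep_durs.shape[0]:
                    ep_durs[ep_cnt] = d
                ep_cnt += 1
            Wtot -= totW[sel]
            Mtot -= totM[sel]
            last = n - 1
            if sel != last:
                for k in range(nseg[last]):
                    segW[sel, k] = segW[last, k]
                    segM[sel, k] = segM[last, k]
                nseg[sel] = nseg[last]
                comp[sel] = comp[last]
                totW[sel] = totW[last]
                totM[sel] = totM[last]
                R[sel] = R[last]
                aD[sel] = aD[last]
                fis[sel] = fis[last]
                rsel[sel] = rsel[last]
                rich[sel] = rich[last]
                ep_start[sel] = ep_start[last]
            n -= 1
            if n == 0:
                status = STATUS_EMPTY
                while ri < nrec:
                    _emit(ri, n, Wtot, Mtot, R, snap_r, snap_nm, snap_nuc,
                          snap_rbar, snap_cov)
                    ri += 1
                break
            continue

        # ---- fission ---------------------------------------------------
        u -= aDtot
        if u < fistot:
            if n + 1 > cap_m:
                status = STATUS_CAP_MITO
                break
            tgt = u
            acc = 0.0
            sel = -1
            last = -1
            for i in range(n):
                if fis[i] > 0.0:
                    last = i
                    acc += fis[i]
                    if tgt < acc:
                        sel = i
                        break
            if sel < 0:
                sel = last
            if sel < 0:
                continue  # numerically empty fission class
            j = n
            ns = nseg[sel]
            if ns > 1:
                # a site is viable only if some exchange outcome leaves >=1
                # nucleoid on both sides (empty subcompartments can make a
                # site degenerate); degenerate sites are redrawn, i.e. the
                # site is uniform over the viable ones
                site = 1
                leftrest = 0
                rightrest = 0
                wp = 0
                mp = 0
                for _ in range(10000):
                    site = np.random.randint(1, ns)
                    leftrest = 0
                    for k in range(site - 1):
                        leftrest += segW[sel, k] + segM[sel, k]
                    rightrest = 0
                    for k in range(site + 1, ns):
                        rightrest += segW[sel, k] + segM[sel, k]
                    wp = segW[sel, site - 1] + segW[sel, site]
                    mp = segM[sel, site - 1] + segM[sel, site]
                    lo = 1 - leftrest
                    if lo < 0:
                        lo = 0
                    hi = wp + mp - (1 - rightrest if rightrest < 1 else 0)
                    if hi >= lo:
                        break
                wl = 0
                ml = 0
                for _ in range(1000000):
                    wl = np.random.binomial(wp, 0.5) if wp > 0 else 0
                    ml = np.random.binomial(mp, 0.5) if mp > 0 else 0
                    if (leftrest + wl + ml >= 1
                            and rightrest + (wp - wl) + (mp - ml) >= 1):
                        break
                segW[sel, site - 1] = wl
                segM[sel, site - 1] = ml
                segW[sel, site] = wp - wl
                segM[sel, site] = mp - ml
                cnt = 0
                for k in range(site, ns):
                    segW[j, cnt] = segW[sel, k]
                    segM[j, cnt] = segM[sel, k]
                    cnt += 1
                nseg[j] = cnt
                nseg[sel] = site
            else:
                tot = totW[sel] + totM[sel]
                kk = np.random.randint(1, tot)
                mrem = totM[sel]
                wrem = totW[sel]
                mtake = 0
                for _ in range(kk):
                    if np.random.random() * (mrem + wrem) < mrem:
                        mtake += 1
                        mrem -= 1
                    else:
                        wrem -= 1
                segW[j, 0] = kk - mtake
                segM[j, 0] = mtake
                nseg[j] = 1
                segW[sel, 0] = totW[sel] - (kk - mtake)
                segM[sel, 0] = totM[sel] - mtake
                nseg[sel] = 1
            comp[j] = comp[sel]
            n += 1
            # displacement: fair coin picks the displaced daughter, which is
            # placed uniformly over {original compartment} + neighbors
            dcomp = comp[sel]
            opt = np.random.randint(0, deg[dcomp] + 1)
            move_parent_row = np.random.random() < 0.5
            trow = sel if move_parent_row else j
            if opt > 0:
                comp[trow] = nbr[dcomp, opt - 1]
            _update_cache(sel, segW, segM, nseg, totW, totM, R, aD, fis, rsel, P)
            _update_cache(j, segW, segM, nseg, totW, totM, R, aD, fis, rsel, P)
            if track:
                nr = R[sel] > thresh
                if nr and rich[sel] == 0:
                    rich[sel] = 1
                    ep_start[sel] = t
                    ep_starts += 1
                elif (not nr) and rich[sel] == 1:
                    rich[sel] = 0
                    d = t - ep_start[sel]
                    ep_dursum += d
                    if ep_cnt < ep_durs.shape[0]:
                        ep_durs[ep_cnt] = d
                    ep_cnt += 1
                rich[j] = 0
                if R[j] > thresh:
                    rich[j] = 1
                    ep_start[j] = t
                    ep_starts += 1
            continue

        # ---- fusion ----------------------------------------------------
        # channel = within-compartment pair set or adjacent-compartment pair
        # set; weights from the compartment sums of the selectivity factors.
        tgt = np.random.random() * fustot / P[8]
        ci = -1
        cj = -1
        acc = 0.0
        for c in range(nc):
            v = (S[c] * S[c] - Q[c]) * 0.5
            if v > 0.0:
                acc += v
                if tgt < acc:
                    ci = c
                    cj = c
                    break
        if ci < 0:
            laste = -1
            for e in range(ne):
                v = S[edges[e, 0]] * S[edges[e, 1]]
                if v > 0.0:
                    laste = e
                    acc += v
                    if tgt < acc:
                        ci = edges[e, 0]
                        cj = edges[e, 1]
                        break
            if ci < 0 and laste >= 0:
                ci = edges[laste, 0]
                cj = edges[laste, 1]
        if ci < 0:
            continue  # no positive-weight fusion channel (numerical edge)
        # partner i from compartment ci, weighted by its selectivity factor
        tgt2 = np.random.random() * S[ci]
        acc = 0.0
        si = -1
        last = -1
        for i in range(n):
            if comp[i] == ci and rsel[i] > 0.0:
                last = i
                acc += rsel[i]
                if tgt2 < acc:
                    si = i
                    break
        if si < 0:
            si = last
        if si < 0:
            continue
        # partner j from compartment cj, excluding i when cj == ci
        wj = S[cj] - (rsel[si] if cj == ci else 0.0)
        if wj <= 0.0:
            continue
        tgt3 = np.random.random() * wj
        acc = 0.0
        sj = -1
        last = -1
        for i in range(n):
            if i == si or comp[i] != cj or rsel[i] <= 0.0:
                continue
            last = i
            acc += rsel[i]
            if tgt3 < acc:
                sj = i
                break
        if sj < 0:
            sj = last
        if sj < 0:
            continue
        # donor/acceptor by fair coin
        if np.random.random() < 0.5:
            dnr = si
            acp = sj
        else:
            dnr = sj
            acp = si
        if nseg[acp] + nseg[dnr] > cap_s:
            status = STATUS_CAP_SEG
            break
        base = nseg[acp]
        for k in range(nseg[dnr]):
            segW[acp, base + k] = segW[dnr, k]
            segM[acp, base + k] = segM[dnr, k]
        nseg[acp] = base + nseg[dnr]
        _update_cache(acp, segW, segM, nseg, totW, totM, R, aD, fis, rsel, P)
        if track:
            nr = R[acp] > thresh
            if nr and rich[acp] == 0:
                rich[acp] = 1
                ep_start[acp] = t
                ep_starts += 1
            elif (not nr) and rich[acp] == 1:
                rich[acp] = 0
                d = t - ep_start[acp]
                ep_dursum += d
                if ep_cnt < ep_durs.shape[0]:
                    ep_durs[ep_cnt] = d
                ep_cnt += 1
            if rich[dnr] == 1:  # fusion ends the donor's episode
                rich[dnr] = 0
                d = t - ep_start[dnr]
                ep_dursum += d
                if ep_cnt < ep_durs.shape[0]:
                    ep_durs[ep_cnt] = d
                ep_cnt += 1
        # remove the donor row
        last = n - 1
        if dnr != last:
            for k in range(nseg[last]):
                segW[dnr, k] = segW[last, k]
                segM[dnr, k] = segM[last, k]
            nseg[dnr] = nseg[last]
            comp[dnr] = comp[last]
            totW[dnr] = totW[last]
            totM[dnr] = totM[last]
            R[dnr] = R[last]
            aD[dnr] = aD[last]
            fis[dnr] = fis[last]
            rsel[dnr] = rsel[last]
            rich[dnr] = rich[last]
            ep_start[dnr] = ep_start[last]
        n -= 1
        continue

    # close episodes still open at the end of the run
    if track and status != STATUS_CAP_MITO and status != STATUS_CAP_SEG:
        for i in range(n):
            if rich[i] == 1:
                d = t - ep_start[i]
                ep_dursum += d
                if ep_cnt < ep_durs.shape[0]:
                    ep_durs[ep_cnt] = d
                ep_cnt += 1
                censored += 1

    out[O_MITO_DAYS] = mito_days
    out[O_EP_STARTS] = ep_starts
    out[O_EP_COUNT] = ep_cnt
    out[O_EP_DURSUM] = ep_dursum
    out[O_EP_CENSORED] = censored
    out[O_N_EVENTS] = nev
    out[O_N_FINAL] = n
    return status
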