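"""Compiled inner loops for landscape-scale heat-balance evaluation.

The scalar reference implementation lives in :mod:`thermorange.endotherm`;
this module repeats the identical arithmetic (closed-form per-part surface
temperatures, torso-skin cutaneous evaporation, the thermoregulatory cascade)
as flat numba loops over variants x cells x months x hours, which is what
makes the iterative sensitivity analysis and the intraspecific ensemble
affordable.  Agreement between the two paths is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STEFAN_BOLTZMANN = 5.670374419e-8
SURFACE_EMISSIVITY = 0.95
FREE_CONVECTION_H = 4.0
LATENT_COEFF = 0.622 * 2.43e6 / (1006.0 * 101.325)


@njit(cache=True, fastmath=False)
def _esat_kpa(temp_c):
    return 0.61078 * np.exp(17.27 * temp_c / (temp_c + 237.3))


@njit(cache=True, fastmath=False)
def _m_state(
    s, ta, sol, tr, eair, ws, hr,
    gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade_s,
    tb, atot, fresp, wf,
):
    """Required metabolic rate of one variant in one hourly state."""
    n_parts = area_v.shape[0]
    cond = 0.0
    gc0 = 0.0
    ts0 = 0.0
    h0 = FREE_CONVECTION_H
    shaded = shade_s[s]
    for p in range(n_parts):
        h = hcoef_v[p] * ws
        if h < FREE_CONVECTION_H:
            h = FREE_CONVECTION_H
        if sol > 0.0 and not shaded:
            q = qabs_v[p] * sol
        else:
            q = 0.0
        g = gc_v[p, s]
        ts = (g * tb + h * ta + hr * tr + q) / (g + h + hr)
        cond += area_v[p] * g * (tb - ts)
        if p == 0:
            gc0 = g
            ts0 = ts
            h0 = h
    wet = wet_v[s]
    if wet > 0.0:
        tskin = tb - gc0 * (tb - ts0) * rflt_v[s]
        deficit = _esat_kpa(tskin) - eair
        if deficit < 0.0:
            deficit = 0.0
        ecut = wet * atot * LATENT_COEFF * h0 * deficit
    else:
        ecut = 0.0
    return (cond + ecut) / ((1.0 - fresp) * (1.0 - wf))


@njit(cache=True, fastmath=False)
def _cascade(
    ta, sol, tr, eair, ws, hr, target,
    gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade_s,
    tb, atot, fresp, wf, bmr, n_cold_end,
):
    """Thermoregulatory cascade; returns (M_required, heat_death flag)."""
    hi = 1.05 * target
    lo = 0.95 * target
    m = _m_state(
        0, ta, sol, tr, eair, ws, hr,
        gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade_s, tb, atot, fresp, wf,
    )
    if lo <= m <= hi:
        return m, False
    n_states = shade_s.shape[0]
    if m > hi:
        # cold stress: vasoconstrict then ptiloerect; with no solar load the
        # ladder is strictly monotone, so jump straight to the extreme state
        # when even that one stays cold-stressed
        if sol <= 0.0:
            mext = _m_state(
                n_cold_end, ta, sol, tr, eair, ws, hr,
                gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade_s, tb, atot, fresp, wf,
            )
            if mext > hi:
                return mext, False
        for s in range(1, n_cold_end + 1):
            m = _m_state(
                s, ta, sol, tr, eair, ws, hr,
                gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade_s, tb, atot, fresp, wf,
            )
            if m <= hi:
                return m, False
        return m, False
    # heat stress: vasodilate, wet the skin, then seek shade
    for s in range(n_cold_end + 1, n_states):
        m = _m_state(
            s, ta, sol, tr, eair, ws, hr,
            gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade_s, tb, atot, fresp, wf,
        )
        if m >= lo:
            return m, False
    return m, (m < lo) and (m < bmr)


@njit(cache=True, fastmath=False)
def run_maps(
    ta, sol, tr, eair, wsqrt, active,
    gc, area, hcoef, qabs, rflt, wet, shade,
    tb, tcore, bmr, fresp, weff, act_mult, breed_mult, ceil_mult,
    n_cold_end, do_breeding, early_exit,
    surv, breed, maxmult,
):
    """Monthly survival/breeding energetics for every variant and cell.

    Environment arrays have shape (n_cells, 12, 24) except ``wsqrt``
    (n_cells, 12); variant parameter arrays lead with the variant axis.
    Outputs: ``surv``/``breed`` (nv, n_cells, 12) uint8 and ``maxmult``
    (nv, n_cells) holding the largest monthly daily-mean multiple of BMR.
    """
    nv = area.shape[0]
    n_cells = ta.shape[0]
    atot_all = np.zeros(nv)
    for v in range(nv):
        t = 0.0
        for p in range(area.shape[1]):
            t += area[v, p]
        atot_all[v] = t
    for v in range(nv):
        tb_v = tb[v]
        tcore_v = tcore[v]
        bmr_v = bmr[v]
        atot = atot_all[v]
        gc_v = gc[v]
        area_v = area[v]
        hcoef_v = hcoef[v]
        qabs_v = qabs[v]
        rflt_v = rflt[v]
        wet_v = wet[v]
        fresp_v = fresp[v]
        weff_v = weff[v]
        for c in range(n_cells):
            mm = -1.0e30
            alive = True
            for mo in range(12):
                if early_exit and not alive:
                    surv[v, c, mo] = 0
                    if do_breeding:
                        breed[v, c, mo] = 0
                    continue
                msum = 0.0
                died = False
                for h in range(24):
                    ta_h = ta[c, mo, h]
                    hr = (
                        4.0
                        * SURFACE_EMISSIVITY
                        * STEFAN_BOLTZMANN
                        * (0.5 * (ta_h + tcore_v) + 273.15) ** 3
                    )
                    if active[c, mo, h]:
                        tgt = bmr_v * act_mult[v]
                        wf = weff_v
                    else:
                        tgt = bmr_v
                        wf = 0.0
                    m, hd = _cascade(
                        ta_h, sol[c, mo, h], tr[c, mo, h], eair[c, mo, h],
                        wsqrt[c, mo], hr, tgt,
                        gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade,
                        tb_v, atot, fresp_v, wf, bmr_v, n_cold_end,
                    )
                    if hd:
                        died = True
                    if m > 0.0:
                        msum += m
                mean_mult = msum / 24.0 / bmr_v
                ok = (mean_mult <= ceil_mult[v]) and not died
                surv[v, c, mo] = 1 if ok else 0
                if not ok:
                    alive = False
                if mean_mult > mm:
                    mm = mean_mult
                if do_breeding:
                    bsum = 0.0
                    bdied = False
                    for h in range(24):
                        ta_h = ta[c, mo, h]
                        hr = (
                            4.0
                            * SURFACE_EMISSIVITY
                            * STEFAN_BOLTZMANN
                            * (0.5 * (ta_h + tcore_v) + 273.15) ** 3
                        )
                        if active[c, mo, h]:
                            tgt = bmr_v * act_mult[v] * breed_mult[v]
                            wf = weff_v
                        else:
                            tgt = bmr_v * breed_mult[v]
                            wf = 0.0
                        m, hd = _cascade(
                            ta_h, sol[c, mo, h], tr[c, mo, h], eair[c, mo, h],
                            wsqrt[c, mo], hr, tgt,
                            gc_v, area_v, hcoef_v, qabs_v, rflt_v, wet_v, shade,
                            tb_v, atot, fresp_v, wf, bmr_v, n_cold_end,
                        )
                        if hd:
                            bdied = True
                        if m > 0.0:
                            bsum += m
                    bmean = bsum / 24.0 / bmr_v
                    breed[v, c, mo] = 1 if (bmean <= ceil_mult[v] and not bdied) else 0
            maxmult[v, c] = mm
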