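"""Human ventricular myocyte host model with the Markov Na+ channel.

The host electrophysiology follows the ten Tusscher-Panfilov (2006)
epicardial formulation: L-type Ca2+ current with voltage-, Ca2+- and
slow-gate inactivation, rapid and slow delayed rectifiers, inward rectifier,
transient outward current, Na+/K+ pump, Na+/Ca2+ exchanger, background and
pump Ca2+ currents, a CICR release model with junctional subspace, and
dynamic intracellular Na+, K+ and Ca2+ with analytic buffering.  The
Hodgkin-Huxley Na+ current of the host is replaced by the DIII-VSD Markov
model; a background chloride conductance is exposed as the repolarization
calibration scalar.

Numerics: fixed-rule adaptive explicit stepping (Rush-Larsen for the host
gates, forward Euler for concentrations) with the Markov block advanced by
backward Euler, which is unconditionally stable and conserves total
occupancy exactly.  Everything is compiled with numba; runs are
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .channel import EDGES, N_STATES, OPEN, A1_STATES, A2_STATES, BOUND_STATES
from .params import ConstructParameters
from .rates import compose

RTF = 26.713  # mV at 310 K

# host state layout
NV, NCAI, NCASR, NCASS, NNAI, NKI = 0, 1, 2, 3, 4, 5
ND, NF, NF2, NFCASS, NR, NS, NXR1, NXR2, NXS, NRR = 6, 7, 8, 9, 10, 11, 12, 13, 14, 15
N_HOST = 16

#: default initial host state (quiescent epicardial myocyte)
Y0_HOST = np.array([
    -85.23, 0.000126, 3.64, 0.00036, 8.604, 136.89,
    3.373e-5, 0.7888, 0.9755, 0.9953, 2.42e-8, 0.999998,
    0.00621, 0.4712, 0.0095, 0.9073,
])


def edge_arrays(params: ConstructParameters):
    """Flatten the channel topology + rate laws into numba-friendly arrays."""
    laws = params.effective_laws()
    values = {k: (law.A, law.inv_b) for k, law in laws.items()}
    for k, v in params.scalars().items():
        values[k] = (v, 0.0)

    def mono_to_law(mono):
        log_a, inv_b = 0.0, 0.0
        for name, exp in mono.items():
            a, ib = values[name]
            if a == 0.0:
                return 0.0, 0.0
            log_a += exp * np.log(a)
            inv_b += exp * ib
        return float(np.exp(log_a)), float(inv_b)

    n = len(EDGES)
    src = np.empty(n, np.int64)
    dst = np.empty(n, np.int64)
    af = np.empty(n)
    ibf = np.empty(n)
    ab = np.empty(n)
    ibb = np.empty(n)
    bind = np.zeros(n, np.int64)
    for i, e in enumerate(EDGES):
        src[i], dst[i] = e.src, e.dst
        af[i], ibf[i] = mono_to_law(e.fwd)
        ab[i], ibb[i] = mono_to_law(e.bwd)
        bind[i] = 1 if e.binding else 0
    return src, dst, af, ibf, ab, ibb, bind


@njit(cache=True)
def markov_generator(src, dst, af, ibf, ab, ibb, bind, v, drug):
    g = np.zeros((N_STATES, N_STATES))
    for i in range(src.shape[0]):
        kf = af[i] * np.exp(ibf[i] * v)
        kb = ab[i] * np.exp(ibb[i] * v)
        if bind[i] == 1:
            kf *= drug
        s, d = src[i], dst[i]
        g[d, s] += kf
        g[s, s] -= kf
        g[s, d] += kb
        g[d, d] -= kb
    return g


@njit(cache=True)
def host_currents(y, po, gna, gcl, gkr_scale, gks_scale, ko, nao, cao):
    """All membrane currents (A/F); returns (i_total_without_stim, i_na)."""
    v = y[NV]
    cai, cass = y[NCAI], y[NCASS]
    nai, ki = y[NNAI], y[NKI]
    ek = RTF * np.log(ko / ki)
    ena = RTF * np.log(nao / nai)
    eks = RTF * np.log((ko + 0.03 * nao) / (ki + 0.03 * nai))
    eca = 0.5 * RTF * np.log(cao / cai)
    ecl = -61.5

    i_na = gna * po * (v - ena)
    ikr = gkr_scale * 0.153 * np.sqrt(ko / 5.4) * y[NXR1] * y[NXR2] * (v - ek)
    iks = gks_scale * 0.392 * y[NXS] * y[NXS] * (v - eks)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (v - ek + 100.0)) + np.exp(0.1 * (v - ek - 10.0))) / (
        1.0 + np.exp(-0.5 * (v - ek)))
    ik1 = 5.405 * np.sqrt(ko / 5.4) * (ak1 / (ak1 + bk1)) * (v - ek)
    ito = 0.294 * y[NR] * y[NS] * (v - ek)
    vf = (v - 15.0) / RTF
    if np.abs(vf) < 1e-6:
        vf = 1e-6
    ical = (3.98e-5 * y[ND] * y[NF] * y[NF2] * y[NFCASS] * 4.0 * (v - 15.0)
            * 96485.3415 / RTF
            * (0.25 * cass * np.exp(2.0 * vf) - cao) / (np.exp(2.0 * vf) - 1.0))
    inak = (2.724 * ko / (ko + 1.0) * nai / (nai + 40.0)
            / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF) + 0.0353 * np.exp(-v / RTF)))
    incx = (1000.0 * (np.exp(0.35 * v / RTF) * nai ** 3 * cao
                      - np.exp(-0.65 * v / RTF) * nao ** 3 * cai * 2.5)
            / ((87.5 ** 3 + nao ** 3) * (1.38 + cao)
               * (1.0 + 0.1 * np.exp(-0.65 * v / RTF))))
    ipca = 0.1238 * cai / (0.0005 + cai)
    ipk = 0.0146 * (v - ek) / (1.0 + np.exp((25.0 - v) / 5.98))
    ibna = 0.00029 * (v - ena)
    ibca = 0.000592 * (v - eca)
    iclb = gcl * (v - ecl)
    total = (i_na + ikr + iks + ik1 + ito + ical + inak + incx + ipca + ipk
             + ibna + ibca + iclb)
    return total, i_na, ical, incx, inak, ik1, ito, ikr, iks, ipca, ipk, ibna, ibca, iclb


@njit(cache=True)
def step_host(y, po, dt, i_stim, gna, gcl, gkr_scale, gks_scale, ko, nao, cao):
    """One explicit step of the host model; returns dV/dt used."""
    v = y[NV]
    res = host_currents(y, po, gna, gcl, gkr_scale, gks_scale, ko, nao, cao)
    i_tot = res[0]
    i_na, ical, incx, inak = res[1], res[2], res[3], res[4]
    ik1, ito, ikr, iks, ipca, ipk, ibna, ibca, iclb = res[5:14]

    dvdt = -(i_tot + i_stim)

    # -- gate updates (Rush-Larsen) --
    dinf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    taud = ad * bd + gd
    finf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tauf = (1102.5 * np.exp(-(v + 27.0) ** 2 / 225.0)
            + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
            + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    f2inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * np.exp(-(v + 27.0) ** 2 / 240.0)
             + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
             + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))
    cass = y[NCASS]
    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    rinf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    taur = 9.5 * np.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    sinf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    taus = (85.0 * np.exp(-(v + 45.0) ** 2 / 320.0)
            + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)
    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1
    xr2inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2
    xsinf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tauxs = axs * bxs + 80.0

    y[ND] = dinf - (dinf - y[ND]) * np.exp(-dt / taud)
    y[NF] = finf - (finf - y[NF]) * np.exp(-dt / tauf)
    y[NF2] = f2inf - (f2inf - y[NF2]) * np.exp(-dt / tauf2)
    y[NFCASS] = fcassinf - (fcassinf - y[NFCASS]) * np.exp(-dt / taufcass)
    y[NR] = rinf - (rinf - y[NR]) * np.exp(-dt / taur)
    y[NS] = sinf - (sinf - y[NS]) * np.exp(-dt / taus)
    y[NXR1] = xr1inf - (xr1inf - y[NXR1]) * np.exp(-dt / tauxr1)
    y[NXR2] = xr2inf - (xr2inf - y[NXR2]) * np.exp(-dt / tauxr2)
    y[NXS] = xsinf - (xsinf - y[NXS]) * np.exp(-dt / tauxs)

    # -- calcium subsystem --
    casr, cai = y[NCASR], y[NCAI]
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    y[NRR] += dt * (0.005 * (1.0 - y[NRR]) - k2 * cass * y[NRR])
    oo = k1 * cass * cass * y[NRR] / (0.06 + k1 * cass * cass)
    irel = 0.102 * oo * (casr - cass)
    iup = 0.006375 / (1.0 + 0.00025 ** 2 / (cai * cai))
    ileak = 0.00036 * (casr - cai)
    ixfer = 0.0038 * (cass - cai)

    vc, vsr, vss = 0.016404, 0.001094, 0.00005468
    cap = 0.185
    f_const = 96485.3415
    inv2vcf = cap / (2.0 * vc * f_const)
    inv2vssf = cap / (2.0 * vss * f_const)
    invvcf = cap / (vc * f_const)

    # CaSR with analytic CSQN buffering
    bufsr, kbufsr = 10.0, 0.3
    cacsqn = bufsr * casr / (casr + kbufsr)
    dcasr = dt * (iup - irel - ileak)
    bj = bufsr - cacsqn - dcasr - casr + kbufsr
    cj = kbufsr * (cacsqn + dcasr + casr)
    y[NCASR] = (np.sqrt(bj * bj + 4.0 * cj) - bj) / 2.0

    # CaSS with buffering
    bufss, kbufss = 0.4, 0.00025
    cassbuf = bufss * cass / (cass + kbufss)
    dcass = dt * (-ixfer * (vc / vss) + irel * (vsr / vss) - ical * inv2vssf)
    bs = bufss - cassbuf - dcass - cass + kbufss
    cs = kbufss * (cassbuf + dcass + cass)
    y[NCASS] = (np.sqrt(bs * bs + 4.0 * cs) - bs) / 2.0

    # Cai with buffering
    bufc, kbufc = 0.2, 0.001
    cabuf = bufc * cai / (cai + kbufc)
    dcai = dt * (-(ibca + ipca - 2.0 * incx) * inv2vcf
                 - (iup - ileak) * (vsr / vc) + ixfer)
    bc = bufc - cabuf - dcai - cai + kbufc
    cc = kbufc * (cabuf + dcai + cai)
    y[NCAI] = (np.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

    y[NNAI] += dt * (-(i_na + ibna + 3.0 * inak + 3.0 * incx) * invvcf)
    y[NKI] += dt * (-(i_stim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * invvcf)
    y[NV] = v + dt * dvdt
    return dvdt


@njit(cache=True)
def run_cell_kernel(y0, p0, src, dst, af, ibf, ab, ibb, bind,
                    gna, drug, gcl, gkr_scale, gks_scale, w1, w2,
                    bcl, n_beats, stim_amp, stim_dur,
                    ko, nao, cao,
                    out_v, out_ina, out_f, out_cai, dvdt_max):
    """Pace the coupled cell for n_beats; record at 1-ms resolution."""
    y = y0.copy()
    p = p0.copy()
    eye = np.eye(N_STATES)
    t = 0.0
    t_end = bcl * n_beats
    next_sample = 0.0
    k = 0
    dvdt_prev = 0.0
    while t < t_end - 1e-9:
        phase = t % bcl
        stim = stim_amp if phase < stim_dur else 0.0
        v = y[NV]
        # fixed-rule adaptive step
        if np.abs(dvdt_prev) > 2.0 or (phase < stim_dur + 2.0):
            dt = 0.005
        elif np.abs(dvdt_prev) < 0.05 and v < -75.0:
            dt = 0.25
        else:
            dt = 0.02
        if t + dt > t_end:
            dt = t_end - t
        # do not step across a stimulus onset
        next_stim = (np.floor(t / bcl) + 1.0) * bcl
        if t < next_stim and t + dt > next_stim:
            dt = next_stim - t
        # Markov backward Euler at the current voltage
        g = markov_generator(src, dst, af, ibf, ab, ibb, bind, v, drug)
        p = np.linalg.solve(eye - dt * g, p)
        for i in range(N_STATES):
            if p[i] < 0.0:
                p[i] = 0.0
        p /= p.sum()
        po = p[OPEN]
        dvdt = step_host(y, po, dt, stim, gna, gcl, gkr_scale, gks_scale, ko, nao, cao)
        dvdt_prev = dvdt
        beat = int(t / bcl)
        if dvdt > dvdt_max[beat]:
            dvdt_max[beat] = dvdt
        t += dt
        while next_sample <= t + 1e-9 and k < out_v.shape[0]:
            out_v[k] = y[NV]
            out_ina[k] = gna * po * (y[NV] - RTF * np.log(nao / y[NNAI]))
            fa1 = 0.0
            fa2 = 0.0
            for i in range(4, 8):
                fa1 += p[i]
            for i in range(8, N_STATES):
                fa2 += p[i]
            out_f[k] = w1 * fa1 + w2 * fa2
            out_cai[k] = y[NCAI]
            k += 1
            next_sample += 1.0
    return y, p
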