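"""ten Tusscher–Panfilov (2006) human ventricular cell model.

Numba-compiled implementation with Rush–Larsen updates for the eleven
voltage-dependent gates and forward-Euler updates for the calcium
subsystem, intracellular concentrations and membrane potential. All
voltage-dependent rate expressions and current coefficients are
pre-tabulated on a membrane-potential grid (one fused row per voltage, so
a node's whole table lookup touches two contiguous rows) and linearly
interpolated; this is what makes desk-scale tissue simulation feasible.

State layout: the membrane potential lives in its own contiguous array
``V (n,)``; the remaining 18 state variables are rows of ``S (n, 18)``
(gates, calcium subsystem, Na/K concentrations).

Units follow the original model: mV, ms, pA/pF, mM. A depolarising
stimulus is passed in the model's own sign convention (negative Istim
depolarises).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------- constants

R = 8314.472        # J / (kmol K)
T = 310.0           # K
F = 96485.3415      # C / mmol
RTONF = R * T / F   # mV

KO = 5.4            # mM
NAO = 140.0
CAO = 2.0

CM = 0.185          # membrane capacitance used in concentration updates
VC = 0.016404       # cytoplasmic volume
VSR = 0.001094
VSS = 0.00005468

# Maximal conductances / fluxes (epicardial parameter set)
GNA = 14.838        # nS/pF
GK1 = 5.405
GKR = 0.153
GKS_EPI = 0.392
GKS_M = 0.098
GTO_EPI = 0.294
GTO_ENDO = 0.073
GCAL = 0.0000398
GBNA = 0.00029
GBCA = 0.000592
GPK = 0.0146
GPCA = 0.1238
KPCA = 0.0005
PNAK = 2.724
KMK = 1.0
KMNA = 40.0
KNACA = 1000.0
KSAT = 0.1
GAMMA = 0.35
KMNAI = 87.5
KMCA = 1.38
NACA_ALPHA = 2.5
PKNA = 0.03

VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038

BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025

# Columns of the (n, 18) non-voltage state array
NSV = 18
CM_, CH, CJ, CXR1, CXR2, CXS, CR, CS, CD, CF, CF2, CFCASS, CRBAR, \
    CCAI, CCASR, CCASS, CNAI, CKI = range(NSV)

#: Resting V plus the 18 non-voltage states (model paper values;
#: pre-pacing is always applied before measurement).
V_REST = -85.23
INITIAL_SV = np.array([
    0.00172,     # m
    0.7444,      # h
    0.7045,      # j
    0.00621,     # xr1
    0.4712,      # xr2
    0.0095,      # xs
    2.42e-8,     # r
    0.999998,    # s
    3.373e-5,    # d
    0.7888,      # f
    0.9755,      # f2
    0.9953,      # fcass
    0.9073,      # Rbar
    0.000126,    # Cai
    3.64,        # CaSR
    0.00036,     # CaSS
    8.604,       # Nai
    136.89,      # Ki
])

# Voltage grid for the fused lookup table
VT_MIN = -100.0
VT_MAX = 100.0
VT_STEP = 0.05
# IK1 inward-rectifier table is indexed by (V - EK)
UT_MIN = -150.0
UT_MAX = 350.0
UT_STEP = 0.05

N_GATES = 11  # m h j xr1 xr2 xs r s d f f2 (fcass handled analytically)
# Fused table columns: [inf_g, rl_g] pairs for the 11 gates, then the six
# current coefficients.
TCOL_ICALA = 22
TCOL_ICALB = 23
TCOL_INAK = 24
TCOL_NACA1 = 25
TCOL_NACA2 = 26
TCOL_IPK = 27
NTCOL = 28


def _gate_rates(v: np.ndarray, subtype: str):
    """inf and tau for the 11 voltage-dependent gates on grid ``v``."""
    exp = np.exp
    inf = np.empty((N_GATES, v.size))
    tau = np.empty((N_GATES, v.size))

    # m
    inf[0] = 1.0 / (1.0 + exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + exp((v - 50.0) / 200.0))
    tau[0] = am * bm
    # h
    inf[1] = 1.0 / (1.0 + exp((v + 71.55) / 7.43)) ** 2
    ah = np.where(v < -40.0, 0.057 * exp(-(v + 80.0) / 6.8), 0.0)
    bh = np.where(
        v < -40.0,
        2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v),
        0.77 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1))),
    )
    tau[1] = 1.0 / (ah + bh)
    # j
    inf[2] = inf[1]
    aj = np.where(
        v < -40.0,
        (-2.5428e4 * exp(0.2444 * v) - 6.948e-6 * exp(-0.04391 * v))
        * (v + 37.78) / (1.0 + exp(0.311 * (v + 79.23))),
        0.0,
    )
    bj = np.where(
        v < -40.0,
        0.02424 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14))),
        0.6 * exp(0.057 * v) / (1.0 + exp(-0.1 * (v + 32.0))),
    )
    tau[2] = 1.0 / (aj + bj)
    # xr1
    inf[3] = 1.0 / (1.0 + exp((-26.0 - v) / 7.0))
    tau[3] = (450.0 / (1.0 + exp((-45.0 - v) / 10.0))) * (
        6.0 / (1.0 + exp((v + 30.0) / 11.5)))
    # xr2
    inf[4] = 1.0 / (1.0 + exp((v + 88.0) / 24.0))
    tau[4] = (3.0 / (1.0 + exp((-60.0 - v) / 20.0))) * (
        1.12 / (1.0 + exp((v - 60.0) / 20.0)))
    # xs
    inf[5] = 1.0 / (1.0 + exp((-5.0 - v) / 14.0))
    tau[5] = (1400.0 / np.sqrt(1.0 + exp((5.0 - v) / 6.0))) * (
        1.0 / (1.0 + exp((v - 35.0) / 15.0))) + 80.0
    # r
    inf[6] = 1.0 / (1.0 + exp((20.0 - v) / 6.0))
    tau[6] = 9.5 * exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    # s
    if subtype == "endo":
        inf[7] = 1.0 / (1.0 + exp((v + 28.0) / 5.0))
        tau[7] = 1000.0 * exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    else:  # epi and M
        inf[7] = 1.0 / (1.0 + exp((v + 20.0) / 5.0))
        tau[7] = (85.0 * exp(-((v + 45.0) ** 2) / 320.0)
                  + 5.0 / (1.0 + exp((v - 20.0) / 5.0)) + 3.0)
    # d
    inf[8] = 1.0 / (1.0 + exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + exp((50.0 - v) / 20.0))
    tau[8] = ad * bd + gd
    # f
    inf[9] = 1.0 / (1.0 + exp((v + 20.0) / 7.0))
    tau[9] = (1102.5 * exp(-((v + 27.0) ** 2) / 225.0)
              + 200.0 / (1.0 + exp((13.0 - v) / 10.0))
              + 180.0 / (1.0 + exp((v + 30.0) / 10.0)) + 20.0)
    # f2
    inf[10] = 0.67 / (1.0 + exp((v + 35.0) / 7.0)) + 0.33
    tau[10] = (562.0 * exp(-((v + 27.0) ** 2) / 240.0)
               + 31.0 / (1.0 + exp((25.0 - v) / 10.0))
               + 80.0 / (1.0 + exp((v + 30.0) / 10.0)))
    return inf, tau


def build_tables(dt: float, subtype: str = "epi"):
    """Pre-tabulate gate and current coefficients for a fixed time step.

    Returns ``(tab, k1tab)``. ``tab`` has one row per voltage-grid point;
    columns hold, per gate, the steady state and the Rush–Larsen
    multiplier ``exp(-dt/tau)``, followed by the ICaL driving-term
    coefficient, ``exp(2(V-15)F/RT)``, the INaK voltage factor, the two
    INaCa exponentials and the IpK activation. ``k1tab`` is the IK1
    rectification factor on the (V − EK) grid.
    """
    v = np.arange(VT_MIN, VT_MAX + VT_STEP / 2, VT_STEP)
    inf, tau = _gate_rates(v, subtype)
    rl = np.exp(-dt / tau)

    tab = np.empty((v.size, NTCOL))
    for g in range(N_GATES):
        tab[:, 2 * g] = inf[g]
        tab[:, 2 * g + 1] = rl[g]

    z = 2.0 * (v - 15.0) * F / (R * T)
    ez = np.exp(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 4.0 * (v - 15.0) * F * F / (R * T) / (ez - 1.0)
    a[np.abs(v - 15.0) < 1e-9] = 2.0 * F  # limit as V -> 15 mV
    tab[:, TCOL_ICALA] = a
    tab[:, TCOL_ICALB] = ez
    tab[:, TCOL_INAK] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTONF)
                               + 0.0353 * np.exp(-v / RTONF))
    tab[:, TCOL_NACA1] = np.exp(GAMMA * v / RTONF)
    tab[:, TCOL_NACA2] = np.exp((GAMMA - 1.0) * v / RTONF)
    tab[:, TCOL_IPK] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))

    u = np.arange(UT_MIN, UT_MAX + UT_STEP / 2, UT_STEP)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (u - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (u + 100.0)) + np.exp(0.1 * (u - 10.0)))
           / (1.0 + np.exp(-0.5 * u)))
    k1tab = ak1 / (ak1 + bk1)

    return np.ascontiguousarray(tab), np.ascontiguousarray(k1tab)


def default_conductances(subtype: str = "epi"):
    """(g_Na, g_Kr, g_Ks, g_to) for a transmural subtype."""
    if subtype == "epi":
        return GNA, GKR, GKS_EPI, GTO_EPI
    if subtype == "endo":
        return GNA, GKR, GKS_EPI, GTO_ENDO
    if subtype == "M":
        return GNA, GKR, GKS_M, GTO_EPI
    raise ValueError(f"unknown subtype {subtype!r}")


def initial_state(n: int):
    """(V, S) resting-state arrays for ``n`` nodes."""
    V = np.full(n, V_REST)
    S = np.tile(INITIAL_SV, (n, 1))
    return V, np.ascontiguousarray(S)


@njit(cache=True, fastmath=True)
def ionic_pass(V, S, gna, gkr, gks, gto, dt, tab, k1tab, istim, active,
               erev, refresh_erev):
    """Advance every active node's cell state by one time step in place.

    ``V (n,)`` membrane potential, ``S (n, 18)`` remaining state,
    ``gna/gkr/gks/gto`` per-node maximal conductances, ``istim`` stimulus
    current (pA/pF, negative depolarises), ``active`` conducting-node
    mask. ``erev (n, 4)`` caches the Nernst reversal potentials
    (EK, ENa, EKs, ECa), recomputed from the concentrations only when
    ``refresh_erev`` is set — they drift on the scale of beats, far
    slower than the refresh interval used by the drivers (~1 ms).
    Returns the maximum |V| encountered (blow-up detection).
    """
    n = V.shape[0]
    inv_v = 1.0 / VT_STEP
    inv_u = 1.0 / UT_STEP
    nv = tab.shape[0] - 1
    nu = k1tab.shape[0] - 1
    sqrtko = np.sqrt(KO / 5.4)
    vmax_seen = 0.0
    for k in range(n):
        if not active[k]:
            continue
        v = V[k]
        row = S[k]
        cai = row[CCAI]
        casr = row[CCASR]
        cass = row[CCASS]
        nai = row[CNAI]
        ki = row[CKI]

        # fused-table row lookup
        x = (v - VT_MIN) * inv_v
        if x < 0.0:
            x = 0.0
        elif x > nv:
            x = float(nv)
        i0 = int(x)
        if i0 >= nv:
            i0 = nv - 1
        fr = x - i0
        t0 = tab[i0]
        t1 = tab[i0 + 1]

        if refresh_erev:
            ek = RTONF * np.log(KO / ki)
            ena = RTONF * np.log(NAO / nai)
            eks = RTONF * np.log((KO + PKNA * NAO) / (ki + PKNA * nai))
            eca = 0.5 * RTONF * np.log(CAO / cai)
            erev[k, 0] = ek
            erev[k, 1] = ena
            erev[k, 2] = eks
            erev[k, 3] = eca
        else:
            ek = erev[k, 0]
            ena = erev[k, 1]
            eks = erev[k, 2]
            eca = erev[k, 3]

        m = row[CM_]; h = row[CH]; j = row[CJ]
        xr1 = row[CXR1]; xr2 = row[CXR2]; xs = row[CXS]
        rr = row[CR]; ss = row[CS]
        d = row[CD]; f = row[CF]; f2 = row[CF2]; fcass = row[CFCASS]

        ina = gna[k] * m * m * m * h * j * (v - ena)
        icala = t0[TCOL_ICALA] + fr * (t1[TCOL_ICALA] - t0[TCOL_ICALA])
        icalb = t0[TCOL_ICALB] + fr * (t1[TCOL_ICALB] - t0[TCOL_ICALB])
        ical = GCAL * d * f * f2 * fcass * icala * (0.25 * cass * icalb - CAO)
        ito = gto[k] * rr * ss * (v - ek)
        ikr = gkr[k] * sqrtko * xr1 * xr2 * (v - ek)
        iks = gks[k] * xs * xs * (v - eks)
        # IK1 from the (V - EK) table
        u = (v - ek - UT_MIN) * inv_u
        if u < 0.0:
            u = 0.0
        elif u > nu:
            u = float(nu)
        iu = int(u)
        if iu >= nu:
            iu = nu - 1
        fu = u - iu
        xk1 = k1tab[iu] + fu * (k1tab[iu + 1] - k1tab[iu])
        ik1 = GK1 * sqrtko * xk1 * (v - ek)
        e1 = t0[TCOL_NACA1] + fr * (t1[TCOL_NACA1] - t0[TCOL_NACA1])
        e2 = t0[TCOL_NACA2] + fr * (t1[TCOL_NACA2] - t0[TCOL_NACA2])
        inaca = (KNACA
                 * (e1 * nai * nai * nai * CAO
                    - e2 * NAO * NAO * NAO * cai * NACA_ALPHA)
                 / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO)
                    * (1.0 + KSAT * e2)))
        fnak = t0[TCOL_INAK] + fr * (t1[TCOL_INAK] - t0[TCOL_INAK])
        inak = PNAK * (KO / (KO + KMK)) * (nai / (nai + KMNA)) * fnak
        ipca = GPCA * cai / (KPCA + cai)
        fpk = t0[TCOL_IPK] + fr * (t1[TCOL_IPK] - t0[TCOL_IPK])
        ipk = GPK * fpk * (v - ek)
        ibna = GBNA * (v - ena)
        ibca = GBCA * (v - eca)

        itot = (ina + ical + ito + ikr + iks + ik1 + inaca + inak
                + ipca + ipk + ibna + ibca + istim[k])

        # --- calcium subsystem
        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
        k1 = K1P / kcasr
        k2 = K2P * kcasr
        rbar = row[CRBAR]
        rbar += dt * (-k2 * cass * rbar + K4 * (1.0 - rbar))
        o = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
        irel = VREL * o * (casr - cass)
        ileak = VLEAK * (casr - cai)
        iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
        ixfer = VXFER * (cass - cai)

        bc = 1.0 / (1.0 + BUFC * KBUFC / ((cai + KBUFC) ** 2))
        bsr = 1.0 / (1.0 + BUFSR * KBUFSR / ((casr + KBUFSR) ** 2))
        bss = 1.0 / (1.0 + BUFSS * KBUFSS / ((cass + KBUFSS) ** 2))

        cai += dt * bc * (
            -(ibca + ipca - 2.0 * inaca) * CM / (2.0 * VC * F)
            + (ileak - iup) * VSR / VC + ixfer)
        casr += dt * bsr * (iup - irel - ileak)
        cass += dt * bss * (
            -ical * CM / (2.0 * VSS * F)
            + irel * VSR / VSS - ixfer * VC / VSS)
        nai += dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca) * CM / (VC * F))
        ki += dt * (-(istim[k] + ik1 + ito + ikr + iks - 2.0 * inak + ipk)
                    * CM / (VC * F))

        # --- Rush-Larsen gate updates from the fused row
        for g in range(N_GATES):
            gi = t0[2 * g] + fr * (t1[2 * g] - t0[2 * g])
            grl = t0[2 * g + 1] + fr * (t1[2 * g + 1] - t0[2 * g + 1])
            row[g] = gi + (row[g] - gi) * grl
        fc2 = (cass / 0.05) ** 2
        fcinf = 0.6 / (1.0 + fc2) + 0.4
        taufc = 80.0 / (1.0 + fc2) + 2.0
        # 2nd-order expansion of exp(-dt/tau); dt/tau <= dt/2 << 1
        xfc = dt / taufc
        row[CFCASS] = fcinf + (fcass - fcinf) * (1.0 - xfc + 0.5 * xfc * xfc)

        vnew = v - dt * itot
        V[k] = vnew
        row[CRBAR] = rbar
        row[CCAI] = cai
        row[CCASR] = casr
        row[CCASS] = cass
        row[CNAI] = nai
        row[CKI] = ki
        av = abs(vnew)
        if av > vmax_seen:
            vmax_seen = av
    return vmax_seen


@njit(cache=True, fastmath=True)
def run_cell(V, S, gna, gkr, gks, gto, dt, n_steps, stim_starts, stim_dur,
             stim_amp, tab, k1tab, rec_every):
    """Integrate a single cell in place; returns (t, V) sampled every
    ``rec_every`` steps plus the failing step index (-1 if none).
    ``stim_amp`` is depolarising-positive.
    """
    active = np.ones(1, dtype=np.bool_)
    istim = np.zeros(1)
    erev = np.zeros((1, 4))
    refresh_every = max(1, int(round(1.0 / dt)))
    n_rec = n_steps // rec_every + 1
    tout = np.empty(n_rec)
    vout = np.empty(n_rec)
    tout[0] = 0.0
    vout[0] = V[0]
    nrec = 1
    for step in range(n_steps):
        t = step * dt
        amp = 0.0
        for s0 in stim_starts:
            if s0 <= t < s0 + stim_dur:
                amp = -stim_amp
                break
        istim[0] = amp
        vm = ionic_pass(V, S, gna, gkr, gks, gto, dt, tab, k1tab, istim,
                        active, erev, step % refresh_every == 0)
        if vm > 200.0:
            return tout[:nrec], vout[:nrec], step
        if (step + 1) % rec_every == 0 and nrec < n_rec:
            tout[nrec] = (step + 1) * dt
            vout[nrec] = V[0]
            nrec += 1
    return tout[:nrec], vout[:nrec], -1
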