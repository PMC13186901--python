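"""Nonlinear 1D pulse-wave solver for arterial networks.

Cross-sectionally averaged mass/momentum equations in conservative (A, Q)
form per vessel, closed by the elastic thin-wall tube law

    P(A) = P_ref + (beta / A0) * (sqrt(A) - sqrt(A0)),
    beta = sqrt(pi) * E * h / (1 - nu^2),

which gives the wave speed c(A) = sqrt(beta * sqrt(A) / (2 rho A0)); at the
reference area this is the Moens-Korteweg speed sqrt(E h / (2 rho r0)) when
nu = 0 (the default).  The friction source assumes a power-law axial velocity
profile: s = -2 (gamma + 2) pi nu Q / A, gamma = 9 by default.

Numerics: MacCormack predictor-corrector on a uniform per-vessel grid.
Junctions (any number of daughters) enforce mass conservation and
total-pressure continuity together with the outgoing characteristic
invariants W = u +/- 4c; terminals couple to R-C-R windkessel elements with
a semi-implicit compliance update.  Cardiac cycles are iterated until the
relative L2 change of the inlet pressure trace between consecutive cycles
falls below the periodicity tolerance.

Hot loops are numba-compiled; the first call in a process pays the JIT cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .microcirculation import MicrovascularBed, bed_equivalent_resistance
from .network import ArterialNetwork, WindkesselTerminal

__all__ = [
    "NumericsConfig",
    "WaveformSet",
    "SolverError",
    "SolverState",
    "aortic_inflow",
    "simulate_subject",
    "wave_speed_series",
    "save_waveforms",
    "load_waveforms",
    "characteristic_impedance",
]

MMHG = 133.322


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class NumericsConfig:
    """Discretisation and physical constants (SI unless noted)."""

    target_dx: float = 0.010  # m
    min_cells: int = 3
    cfl: float = 0.8
    rho: float = 1060.0  # kg/m^3
    poisson_ratio: float = 0.0
    profile_gamma: float = 9.0  # velocity-profile exponent for friction
    heart_rate: float = 75.0  # beats/min
    max_cycles: int = 14
    periodicity_tol: float = 1.0e-3
    ref_pressure: float = 75.0 * MMHG  # tube-law anchor (diastolic inflow)
    venous_pressure: float = 5.0 * MMHG
    samples_per_cycle: int = 200
    init_pressure: float | None = None  # initial charge; None = estimate from
    # mean inflow times the parallel terminal resistance
    u_margin: float = 2.0  # m/s headroom in the CFL estimate

    def __post_init__(self) -> None:
        if not 0 < self.cfl <= 1:
            raise ValueError("CFL number must lie in (0, 1]")
        if self.rho <= 0:
            raise ValueError("blood density must be positive")
        if self.max_cycles < 2:
            raise ValueError("max_cycles must be >= 2")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass
class SolverState:
    """Converged solver state, reusable as a warm start for similar runs."""

    A: np.ndarray
    Q: np.ndarray
    tPc: np.ndarray
    a0: np.ndarray


@dataclass
class WaveformSet:
    """Per-location series over one converged cardiac cycle."""

    location: str
    time: np.ndarray  # s, uniform over [0, T)
    pressure: np.ndarray  # Pa
    flow: np.ndarray  # m^3/s
    area: np.ndarray  # m^2
    wave_speed: np.ndarray  # m/s

    @property
    def velocity(self) -> np.ndarray:
        return self.flow / self.area

    @property
    def period(self) -> float:
        return float(self.time[-1] + (self.time[1] - self.time[0]))


def save_waveforms(path, waves: dict, subject_id: str = "subject",
                   attrs: dict | None = None) -> None:
    """Append one subject's waveforms to an HDF5 store: one group per
    subject, one dataset per (location, quantity), units in attributes."""
    import h5py

    with h5py.File(path, "a") as fh:
        grp = fh.require_group(subject_id)
        for loc, w in waves.items():
            g = grp.require_group(loc.replace("/", "_"))
            for name, series, unit in (
                ("time", w.time, "s"), ("pressure", w.pressure, "Pa"),
                ("flow", w.flow, "m^3/s"), ("area", w.area, "m^2"),
                ("wave_speed", w.wave_speed, "m/s"),
            ):
                if name in g:
                    del g[name]
                ds = g.create_dataset(name, data=series)
                ds.attrs["unit"] = unit
            g.attrs["period_s"] = w.period
        for k, v in (attrs or {}).items():
            grp.attrs[k] = v


def load_waveforms(path, subject_id: str = "subject") -> dict:
    """Load one subject's waveforms back from an HDF5 store."""
    import h5py

    out: dict[str, WaveformSet] = {}
    with h5py.File(path, "r") as fh:
        grp = fh[subject_id]
        for loc, g in grp.items():
            out[loc] = WaveformSet(
                location=loc,
                time=g["time"][:],
                pressure=g["pressure"][:],
                flow=g["flow"][:],
                area=g["area"][:],
                wave_speed=g["wave_speed"][:],
            )
    return out


def wave_speed_series(area: np.ndarray, beta: float, a0: float, rho: float = 1060.0) -> np.ndarray:
    """Instantaneous tube-law wave speed c(A) = sqrt(beta sqrt(A)/(2 rho A0))."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    return np.sqrt(beta * np.sqrt(area) / (2.0 * rho * a0))


def characteristic_impedance(beta: float, a0: float, rho: float = 1060.0) -> float:
    """Z_c = rho c0 / A0 of a vessel at its reference area."""
    c0 = math.sqrt(beta / (2.0 * rho * math.sqrt(a0)))
    return rho * c0 / a0


def vessel_beta(youngs_modulus: float, wall_thickness: float, poisson_ratio: float = 0.0) -> float:
    return math.sqrt(math.pi) * youngs_modulus * wall_thickness / (1.0 - poisson_ratio**2)


# --- inflow template ---------------------------------------------------------


def aortic_inflow(co: float, heart_rate: float = 75.0,
                  systolic_fraction: float = 0.40,
                  reverse_fraction: float = 0.12,
                  reverse_amplitude: float = 0.12):
    """Parametric ascending-aorta flow template scaled to a cycle mean of
    ``co`` [m^3/s]: a sin^2 systolic lobe plus a small reverse lobe at valve
    closure, zero in diastole.  Returns ``q(t)`` periodic in 60/heart_rate."""
    period = 60.0 / heart_rate
    ts, tr = systolic_fraction, reverse_fraction
    # cycle mean of the unit-amplitude shape
    shape_mean = 0.5 * ts - reverse_amplitude * 0.5 * tr
    amp = co / shape_mean

    def q(t):
        tau = np.mod(t, period) / period
        out = np.where(
            tau < ts,
            np.sin(np.pi * tau / ts) ** 2,
            np.where(
                tau < ts + tr,
                -reverse_amplitude * np.sin(np.pi * (tau - ts) / tr) ** 2,
                0.0,
            ),
        )
        return amp * out

    return q


# --- numba kernels -----------------------------------------------------------


@njit(cache=True, fastmath=True)
def _gauss_solve(M, b):
    n = b.shape[0]
    for col in range(n):
        piv = col
        best = abs(M[col, col])
        for r in range(col + 1, n):
            if abs(M[r, col]) > best:
                best = abs(M[r, col])
                piv = r
        if piv != col:
            for c2 in range(n):
                tmp = M[col, c2]
                M[col, c2] = M[piv, c2]
                M[piv, c2] = tmp
            tmp = b[col]
            b[col] = b[piv]
            b[piv] = tmp
        inv = 1.0 / M[col, col]
        for r in range(col + 1, n):
            f = M[r, col] * inv
            if f != 0.0:
                for c2 in range(col, n):
                    M[r, c2] -= f * M[col, c2]
                b[r] -= f * b[col]
    for r in range(n - 1, -1, -1):
        s = b[r]
        for c2 in range(r + 1, n):
            s -= M[r, c2] * b[c2]
        b[r] = s / M[r, r]
    return b


@njit(cache=True, fastmath=True)
def _run_cycle(
    A, Q, Ap, Qp,
    ncell, goff, dxv, b1, sqA0, kflux, ccv,
    rho, pext, fr,
    j_parent, j_k, j_child, j_coff,
    t_vessel, tR1, tR2, tC, tPv, tPc,
    qin, dt,
    rec_cell, recA, recQ,
):
    nsteps = qin.shape[0]
    nv = ncell.shape[0]
    nj = j_parent.shape[0]
    nt = t_vessel.shape[0]
    maxk = 0
    for j in range(nj):
        if j_k[j] > maxk:
            maxk = j_k[j]
    M = np.empty((2 * maxk + 2, 2 * maxk + 2))
    r = np.empty(2 * maxk + 2)

    for step in range(nsteps):
        # ---- inlet boundary (root vessel index 0, left end) ----
        g0 = goff[0]
        Ai = A[g0 + 1]
        ui = Q[g0 + 1] / Ai
        w2 = ui - 4.0 * ccv[0] * math.sqrt(math.sqrt(Ai))
        Ab = A[g0]
        if Ab <= 0.0:
            Ab = Ai
        qn = qin[step]
        for _ in range(20):
            a4 = math.sqrt(math.sqrt(Ab))
            f = qn / Ab - 4.0 * ccv[0] * a4 - w2
            df = -qn / (Ab * Ab) - ccv[0] * a4 / Ab
            dA = f / df
            Ab -= dA
            if Ab <= 0.0:
                Ab = 0.5 * (Ab + dA)
            if abs(dA) < 1e-12 * Ab:
                break
        A[g0] = Ab
        Q[g0] = qn

        # ---- junctions ----
        for j in range(nj):
            p = j_parent[j]
            k = j_k[j]
            m = 2 * k + 2
            gp_end = goff[p] + ncell[p]  # last interior cell
            Apar = A[gp_end]
            upar = Q[gp_end] / Apar
            w1p = upar + 4.0 * ccv[p] * math.sqrt(math.sqrt(Apar))
            # initial guess from ghosts
            xA = np.empty(k + 1)
            xu = np.empty(k + 1)
            gg = gp_end + 1
            xA[0] = A[gg] if A[gg] > 0.0 else Apar
            xu[0] = Q[gg] / xA[0]
            w2c = np.empty(k)
            for i in range(k):
                c = j_child[j_coff[j] + i]
                gi = goff[c] + 1
                Ac = A[gi]
                uc = Q[gi] / Ac
                w2c[i] = uc - 4.0 * ccv[c] * math.sqrt(math.sqrt(Ac))
                gch = goff[c]
                xA[i + 1] = A[gch] if A[gch] > 0.0 else Ac
                xu[i + 1] = Q[gch] / xA[i + 1]
            qscale = abs(xA[0] * xu[0]) + 1e-8
            for _ in range(8):
                for a in range(m):
                    for b in range(m):
                        M[a, b] = 0.0
                cpar = ccv[p] * math.sqrt(math.sqrt(xA[0]))
                # r0: parent outgoing invariant
                r[0] = xu[0] + 4.0 * cpar - w1p
                M[0, 0] = cpar / xA[0]
                M[0, 1] = 1.0
                # r1: mass
                s = xA[0] * xu[0]
                M[1, 0] = xu[0]
                M[1, 1] = xA[0]
                for i in range(k):
                    s -= xA[i + 1] * xu[i + 1]
                    M[1, 2 + 2 * i] = -xu[i + 1]
                    M[1, 3 + 2 * i] = -xA[i + 1]
                r[1] = s
                pp = pext + b1[p] * (math.sqrt(xA[0]) - sqA0[p])
                dpp = 0.5 * b1[p] / math.sqrt(xA[0])
                for i in range(k):
                    c = j_child[j_coff[j] + i]
                    ai = xA[i + 1]
                    ui2 = xu[i + 1]
                    # child incoming invariant
                    ci4 = ccv[c] * math.sqrt(math.sqrt(ai))
                    r[2 + 2 * i] = ui2 - 4.0 * ci4 - w2c[i]
                    M[2 + 2 * i, 2 + 2 * i] = -ci4 / ai
                    M[2 + 2 * i, 3 + 2 * i] = 1.0
                    # total-pressure continuity
                    pi2 = pext + b1[c] * (math.sqrt(ai) - sqA0[c])
                    r[3 + 2 * i] = pp + 0.5 * rho * xu[0] * xu[0] - pi2 - 0.5 * rho * ui2 * ui2
                    M[3 + 2 * i, 0] = dpp
                    M[3 + 2 * i, 1] = rho * xu[0]
                    M[3 + 2 * i, 2 + 2 * i] = -0.5 * b1[c] / math.sqrt(ai)
                    M[3 + 2 * i, 3 + 2 * i] = -rho * ui2
                # residual rows have mixed units; scale to relative size
                nrm = abs(r[0]) / (abs(w1p) + 1.0)
                if abs(r[1]) / qscale > nrm:
                    nrm = abs(r[1]) / qscale
                for i in range(k):
                    e = abs(r[2 + 2 * i]) / (abs(w2c[i]) + 1.0)
                    if e > nrm:
                        nrm = e
                    e = abs(r[3 + 2 * i]) / (abs(pp) + 1e3)
                    if e > nrm:
                        nrm = e
                if nrm < 1e-9:
                    break
                d = _gauss_solve(M[:m, :m], r[:m])
                lim = 1.0
                for i in range(k + 1):
                    na = xA[i] - lim * d[2 * i]
                    while na <= 0.1 * xA[i]:
                        lim *= 0.5
                        na = xA[i] - lim * d[2 * i]
                for i in range(k + 1):
                    xA[i] -= lim * d[2 * i]
                    xu[i] -= lim * d[2 * i + 1]
            # write ghosts
            A[gg] = xA[0]
            Q[gg] = xA[0] * xu[0]
            for i in range(k):
                c = j_child[j_coff[j] + i]
                gch = goff[c]
                A[gch] = xA[i + 1]
                Q[gch] = xA[i + 1] * xu[i + 1]

        # ---- terminals ----
        for ti in range(nt):
            v = t_vessel[ti]
            g_end = goff[v] + ncell[v]
            Ai = A[g_end]
            ui = Q[g_end] / Ai
            w1 = ui + 4.0 * ccv[v] * math.sqrt(math.sqrt(Ai))
            pc = tPc[ti]
            Ab = A[g_end + 1]
            if Ab <= 0.0:
                Ab = Ai
            for _ in range(20):
                sqa = math.sqrt(Ab)
                a4 = math.sqrt(sqa)
                pb = pext + b1[v] * (sqa - sqA0[v])
                f = Ab * (w1 - 4.0 * ccv[v] * a4) - (pb - pc) / tR1[ti]
                df = w1 - 5.0 * ccv[v] * a4 - 0.5 * b1[v] / (sqa * tR1[ti])
                dA = f / df
                Ab -= dA
                if Ab <= 0.0:
                    Ab = 0.5 * (Ab + dA)
                if abs(dA) < 1e-12 * Ab:
                    break
            ub = w1 - 4.0 * ccv[v] * math.sqrt(math.sqrt(Ab))
            qb = Ab * ub
            A[g_end + 1] = Ab
            Q[g_end + 1] = qb
            # semi-implicit compliance update
            tPc[ti] = (pc + dt / tC[ti] * (qb + tPv[ti] / tR2[ti])) / (
                1.0 + dt / (tR2[ti] * tC[ti])
            )

        # ---- MacCormack sweep ----
        for v in range(nv):
            n = ncell[v]
            g = goff[v]
            lam = dt / dxv[v]
            kf = kflux[v]
            # predictor (forward differences), including ghosts as data
            for i in range(n + 2):
                Ap[g + i] = A[g + i]
                Qp[g + i] = Q[g + i]
            for i in range(1, n + 1):
                a0c = A[g + i]
                q0c = Q[g + i]
                a1c = A[g + i + 1]
                q1c = Q[g + i + 1]
                f1_0 = q0c
                f1_1 = q1c
                f2_0 = q0c * q0c / a0c + kf * a0c * math.sqrt(a0c)
                f2_1 = q1c * q1c / a1c + kf * a1c * math.sqrt(a1c)
                Ap[g + i] = a0c - lam * (f1_1 - f1_0)
                Qp[g + i] = q0c - lam * (f2_1 - f2_0) - dt * fr * q0c / a0c
            # corrector (backward differences on predicted values)
            for i in range(1, n + 1):
                a0c = Ap[g + i]
                q0c = Qp[g + i]
                am = Ap[g + i - 1]
                qm = Qp[g + i - 1]
                f1_0 = q0c
                f1_m = qm
                f2_0 = q0c * q0c / a0c + kf * a0c * math.sqrt(a0c)
                f2_m = qm * qm / am + kf * am * math.sqrt(am)
                An = 0.5 * (A[g + i] + a0c - lam * (f1_0 - f1_m))
                Qn = 0.5 * (Q[g + i] + q0c - lam * (f2_0 - f2_m) - dt * fr * q0c / a0c)
                A[g + i] = An
                Q[g + i] = Qn

        # ---- record ----
        for rci in range(rec_cell.shape[0]):
            recA[rci, step] = A[rec_cell[rci]]
            recQ[rci, step] = Q[rec_cell[rci]]

    return 0


# --- assembly and driver -----------------------------------------------------


@dataclass
class _Mesh:
    ids: list
    ncell: np.ndarray
    goff: np.ndarray
    dxv: np.ndarray
    b1: np.ndarray
    a0: np.ndarray
    ccv: np.ndarray
    kflux: np.ndarray
    j_parent: np.ndarray
    j_k: np.ndarray
    j_child: np.ndarray
    j_coff: np.ndarray
    t_vessel: np.ndarray
    tR1: np.ndarray
    tR2: np.ndarray
    tC: np.ndarray
    index: dict = field(default_factory=dict)


def _build_mesh(network: ArterialNetwork, cfg: NumericsConfig) -> _Mesh:
    # order vessels root-first (breadth-first) so the root has index 0
    order: list[str] = []
    queue = [network.inlet_vessel]
    while queue:
        vid = queue.pop(0)
        order.append(vid)
        queue.extend(network.children[vid])
    index = {vid: i for i, vid in enumerate(order)}
    nv = len(order)
    ncell = np.empty(nv, dtype=np.int64)
    dxv = np.empty(nv)
    b1 = np.empty(nv)
    a0 = np.empty(nv)
    ccv = np.empty(nv)
    kflux = np.empty(nv)
    for i, vid in enumerate(order):
        v = network.vessels[vid]
        n = max(cfg.min_cells, int(round(v.length / cfg.target_dx)))
        ncell[i] = n
        dxv[i] = v.length / n
        beta = vessel_beta(v.youngs_modulus, v.wall_thickness, cfg.poisson_ratio)
        a0[i] = v.reference_area
        b1[i] = beta / a0[i]
        ccv[i] = math.sqrt(b1[i] / (2.0 * cfg.rho))
        kflux[i] = b1[i] / (3.0 * cfg.rho)
    goff = np.empty(nv, dtype=np.int64)
    tot = 0
    for i in range(nv):
        goff[i] = tot
        tot += ncell[i] + 2

    j_parent, j_k, j_child, j_coff = [], [], [], []
    for vid in order:
        kids = network.children[vid]
        if kids:
            j_parent.append(index[vid])
            j_k.append(len(kids))
            j_coff.append(len(j_child))
            j_child.extend(index[c] for c in kids)

    t_vessel, tR1, tR2, tC = [], [], [], []
    for vid in network.leaves():
        t = network.terminals[vid]
        v = network.vessels[vid]
        beta = vessel_beta(v.youngs_modulus, v.wall_thickness, cfg.poisson_ratio)
        if isinstance(t, MicrovascularBed):
            r_tot = bed_equivalent_resistance(t)
            r1 = characteristic_impedance(beta, v.reference_area, cfg.rho)
            r1 = min(r1, 0.5 * r_tot)
            r2 = r_tot - r1
            c = t.compliance
        else:
            r1, r2, c = t.proximal_resistance, t.distal_resistance, t.compliance
        t_vessel.append(index[vid])
        tR1.append(r1)
        tR2.append(r2)
        tC.append(c)

    return _Mesh(
        ids=order,
        ncell=ncell,
        goff=goff,
        dxv=dxv,
        b1=b1,
        a0=a0,
        ccv=ccv,
        kflux=kflux,
        j_parent=np.array(j_parent, dtype=np.int64),
        j_k=np.array(j_k, dtype=np.int64),
        j_child=np.array(j_child, dtype=np.int64),
        j_coff=np.array(j_coff, dtype=np.int64),
        t_vessel=np.array(t_vessel, dtype=np.int64),
        tR1=np.array(tR1),
        tR2=np.array(tR2),
        tC=np.array(tC),
        index=index,
    )


def simulate_subject(
    network: ArterialNetwork,
    inflow=None,
    numerics: NumericsConfig | None = None,
    viscosity: float = 4.0e-3,
    cardiac_output: float = 9.33e-5,
    record: list[str] | None = None,
    init_state: "SolverState | None" = None,
    return_state: bool = False,
):
    """Simulate one subject to a periodic state and return last-cycle
    waveforms at the midpoints of the requested vessels (default: all).

    ``inflow`` is a callable q(t) [m^3/s]; if omitted, the packaged aortic
    template scaled to ``cardiac_output`` is used.

    ``init_state`` warm-starts from a previously converged run on a network
    with the same topology and mesh (areas are rescaled by the reference-area
    ratio); this typically saves more than half of the cardiac cycles.  With
    ``return_state`` the converged state is returned as a second value.
    """
    cfg = numerics or NumericsConfig()
    mesh = _build_mesh(network, cfg)
    period = cfg.period
    if inflow is None:
        inflow = aortic_inflow(cardiac_output, cfg.heart_rate)

    rho = cfg.rho
    nu = viscosity / rho
    fr = 2.0 * (cfg.profile_gamma + 2.0) * math.pi * nu

    # time step from the CFL bound with velocity headroom
    cmax = mesh.ccv * (1.25 * mesh.a0) ** 0.25
    dt_bound = cfg.cfl * np.min(mesh.dxv / (cmax + cfg.u_margin))
    nsteps = int(math.ceil(period / dt_bound))
    dt = period / nsteps
    qin = np.asarray(inflow(np.arange(nsteps) * dt), dtype=float)

    # initial state: network charged close to its eventual working pressure
    # (mean inflow through the parallel terminal resistance), windkessel
    # capacitors at their steady resistive-divider share; this leaves only
    # the fast wave transient to settle.
    if cfg.init_pressure is not None:
        p_init = cfg.init_pressure
    else:
        g_par = np.sum(1.0 / (mesh.tR1 + mesh.tR2))
        p_init = cfg.venous_pressure + 1.16 * max(qin.mean(), 0.0) / g_par
    tot = int(mesh.goff[-1] + mesh.ncell[-1] + 2)
    if init_state is not None and init_state.A.shape[0] == tot:
        scale = np.empty(tot)
        for i in range(len(mesh.ids)):
            sl = slice(mesh.goff[i], mesh.goff[i] + mesh.ncell[i] + 2)
            scale[sl] = mesh.a0[i] / init_state.a0[i]
        A = init_state.A * scale
        Q = init_state.Q.copy()
        tPc = init_state.tPc.copy()
    else:
        A = np.empty(tot)
        Q = np.zeros(tot)
        for i in range(len(mesh.ids)):
            s = math.sqrt(mesh.a0[i]) + (p_init - cfg.ref_pressure) / mesh.b1[i]
            Ainit = max(s, 0.5 * math.sqrt(mesh.a0[i])) ** 2
            A[mesh.goff[i] : mesh.goff[i] + mesh.ncell[i] + 2] = Ainit
        tPc = cfg.venous_pressure + (p_init - cfg.venous_pressure) * mesh.tR2 / (
            mesh.tR1 + mesh.tR2
        )
    Ap = A.copy()
    Qp = Q.copy()
    tPv = np.full_like(tPc, cfg.venous_pressure)

    if record is None:
        rec_ids = list(mesh.ids)
    else:
        missing = [r for r in record if r.split(":")[0] not in mesh.index]
        if missing:
            raise SolverError(f"unknown record locations: {missing}")
        rec_ids = list(record)
        if network.inlet_vessel not in rec_ids:
            rec_ids.append(network.inlet_vessel)

    def _rec_cell(rid: str) -> int:
        # "<vessel>" records the midpoint cell; "<vessel>:proximal" /
        # "<vessel>:distal" record the boundary (junction/terminal) states
        vid, _, where = rid.partition(":")
        vi = mesh.index[vid]
        if where == "proximal":
            return int(mesh.goff[vi])
        if where == "distal":
            return int(mesh.goff[vi] + mesh.ncell[vi] + 1)
        return int(mesh.goff[vi] + 1 + mesh.ncell[vi] // 2)

    rec_cell = np.array([_rec_cell(r) for r in rec_ids], dtype=np.int64)
    recA = np.empty((len(rec_ids), nsteps))
    recQ = np.empty((len(rec_ids), nsteps))
    inlet_row = rec_ids.index(network.inlet_vessel)

    prev_inlet = None
    converged = False
    pulse = 1.0
    delta = math.inf
    mean_hist: list[float] = []
    jumps = 0
    for cycle in range(cfg.max_cycles):
        _run_cycle(
            A, Q, Ap, Qp,
            mesh.ncell, mesh.goff, mesh.dxv, mesh.b1, np.sqrt(mesh.a0), mesh.kflux, mesh.ccv,
            rho, cfg.ref_pressure, fr,
            mesh.j_parent, mesh.j_k, mesh.j_child, mesh.j_coff,
            mesh.t_vessel, mesh.tR1, mesh.tR2, mesh.tC, tPv, tPc,
            qin, dt,
            rec_cell, recA, recQ,
        )
        if not np.all(np.isfinite(A)):
            bad = int(np.argmax(~np.isfinite(A)))
            vid = mesh.ids[int(np.searchsorted(mesh.goff, bad, side="right")) - 1]
            raise SolverError(f"instability (non-finite state) in vessel {vid!r}, cycle {cycle}")
        i_row = mesh.index[network.inlet_vessel]
        p_in = cfg.ref_pressure + mesh.b1[i_row] * (
            np.sqrt(recA[inlet_row]) - math.sqrt(mesh.a0[i_row])
        )
        if prev_inlet is not None:
            # reference scale: the pulse pressure, floored at 1% of the mean
            # level so constant-flow runs are not held to a roundoff-level bar
            pulse = max(p_in.max() - p_in.min(), 0.01 * abs(p_in.mean()), 1.0)
            delta = np.sqrt(np.mean((p_in - prev_inlet) ** 2)) / pulse
            if delta < cfg.periodicity_tol:
                converged = True
                prev_inlet = p_in
                break
        prev_inlet = p_in
        # Aitken extrapolation of the slowly charging mean pressure: jump the
        # whole network by the projected remaining offset (uniform pressure
        # shift of the tube law and the windkessel capacitors)
        mean_hist.append(float(p_in.mean()))
        if len(mean_hist) >= 3 and jumps < 2:
            d1 = mean_hist[-1] - mean_hist[-2]
            d2 = mean_hist[-2] - mean_hist[-3]
            if d2 != 0.0:
                ratio = d1 / d2
                if 0.05 < ratio < 0.95 and abs(d1) > 0.2 * cfg.periodicity_tol * pulse:
                    dp_jump = d1 * ratio / (1.0 - ratio)
                    for i in range(len(mesh.ids)):
                        sl = slice(mesh.goff[i], mesh.goff[i] + mesh.ncell[i] + 2)
                        A[sl] = (np.sqrt(A[sl]) + dp_jump / mesh.b1[i]) ** 2
                    tPc += dp_jump * mesh.tR2 / (mesh.tR1 + mesh.tR2)
                    jumps += 1
                    mean_hist.clear()
                    prev_inlet = None  # do not compare across the jump
    if not converged:
        raise SolverError(
            f"no periodic state within {cfg.max_cycles} cycles "
            f"(last relative change {delta:.2e})" if prev_inlet is not None else
            f"no periodic state within {cfg.max_cycles} cycles"
        )

    # downsample the recorded cycle to the output grid
    n_out = min(cfg.samples_per_cycle, nsteps)
    pick = np.linspace(0, nsteps - 1, n_out).round().astype(int)
    t_out = pick * dt
    waves: dict[str, WaveformSet] = {}
    for row, rid in enumerate(rec_ids):
        vi = mesh.index[rid.split(":")[0]]
        a_series = recA[row, pick]
        q_series = recQ[row, pick]
        p_series = cfg.ref_pressure + mesh.b1[vi] * (np.sqrt(a_series) - math.sqrt(mesh.a0[vi]))
        c_series = mesh.ccv[vi] * a_series**0.25
        waves[rid] = WaveformSet(
            location=rid,
            time=t_out,
            pressure=p_series,
            flow=q_series,
            area=a_series,
            wave_speed=c_series,
        )
    if return_state:
        return waves, SolverState(A=A, Q=Q, tPc=tPc, a0=mesh.a0.copy())
    return waves
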