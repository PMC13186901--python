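"""Lumped-parameter (0D) model of the renal microcirculation.

Downstream of each arcuate artery sits a microvascular bed: 650 interlobular
arterioles in parallel, each feeding 60 nephrons in parallel.  A single
nephron is a fixed bridge-topology resistor network:

    inlet --[afferent]--> G
    G --[glomerular capillary]--> X --[efferent]--> PT
    G --[glomerular filter]--> F --[renal tubule]--> T
    T --[ureter]--> outlet
    T --[reabsorption]--> PT
    PT --[peritubular capillary]--> outlet

The filter/tubule branch carries the glomerular filtrate; most of it returns
to the blood side through the reabsorption resistor, the remainder leaves as
urine through the ureter resistor.  The ratio of filter-branch flow to
glomerular inflow is the (blood-side) filtration fraction; the absolute
filter-branch flow summed over all beds is the GFR.

Arteriolar resistances follow Hagen-Poiseuille, R = 8*mu*L/(pi*r^4), so a
lumen-diameter rescaling by s multiplies the resistance by s**-4.  All
resistances are in Pa*s/m^3, pressures in Pa, flows in m^3/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "NEPHRON_COMPONENTS",
    "TABLE_DEFAULTS",
    "NephronCircuit",
    "MicrovascularBed",
    "BedSolution",
    "poiseuille_resistance",
    "solve_nephron",
    "bed_equivalent_resistance",
    "solve_bed",
    "compute_gfr",
    "apply_dkd_arterioles",
    "apply_nephron_loss",
    "solve_hkd_interlobular_scale",
    "default_bed",
]

ML_PER_M3 = 1.0e6
S_PER_MIN = 60.0

#: the eight single-nephron components, in circuit order
NEPHRON_COMPONENTS = (
    "afferent",
    "glomerular_capillary",
    "glomerular_filter",
    "renal_tubule",
    "reabsorption",
    "efferent",
    "peritubular_capillary",
    "ureter",
)

#: reference component resistances [Pa*s/m^3].  The four arteriolar/tubular
#: values are Hagen-Poiseuille evaluations of the reference geometry below;
#: the remainder are literature ratio-derived constants.
TABLE_DEFAULTS: dict[str, float] = {
    "interlobular": 1.37e13,
    "afferent": 8.71e13,
    "glomerular_capillary": 3.92e12,
    "glomerular_filter": 3.35e14,
    "renal_tubule": 1.27e15,
    "reabsorption": 3.31e14,
    "efferent": 1.52e14,
    "peritubular_capillary": 3.60e13,
    "ureter": 7.96e15,
}

#: (viscosity Pa*s, length m, radius m) for the Poiseuille-derived components
POISEUILLE_GEOMETRY: dict[str, tuple[float, float, float]] = {
    "interlobular": (4.00e-3, 370e-6, 22.9e-6),
    "afferent": (4.00e-3, 112e-6, 10.7e-6),
    "renal_tubule": (2.00e-3, 18_000e-6, 16.4e-6),
    "efferent": (2.00e-3, 120e-6, 7.97e-6),
}


def poiseuille_resistance(viscosity: float, length: float, radius: float) -> float:
    """Hagen-Poiseuille resistance 8*mu*L/(pi*r^4) of a cylindrical vessel."""
    if viscosity <= 0:
        raise ValueError(f"viscosity must be positive, got {viscosity}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if length < 0:
        raise ValueError(f"length must be non-negative, got {length}")
    return 8.0 * viscosity * length / (math.pi * radius**4)


@dataclass(frozen=True)
class NephronCircuit:
    """Resistances of the eight single-nephron components [Pa*s/m^3].

    ``math.inf`` is allowed (open branch, e.g. a blocked filter); zero or
    negative resistances are rejected because they short the nodal system.
    """

    resistances: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(NEPHRON_COMPONENTS) - set(self.resistances)
        if missing:
            raise ValueError(f"missing nephron components: {sorted(missing)}")
        for name, r in self.resistances.items():
            if name not in NEPHRON_COMPONENTS:
                raise ValueError(f"unknown nephron component {name!r}")
            if not r > 0:
                raise ValueError(f"non-positive resistance for component {name!r}: {r}")

    def __getitem__(self, name: str) -> float:
        return self.resistances[name]

    def with_resistances(self, **updates: float) -> "NephronCircuit":
        return NephronCircuit({**self.resistances, **updates})

    @classmethod
    def from_table_defaults(cls) -> "NephronCircuit":
        return cls({k: v for k, v in TABLE_DEFAULTS.items() if k != "interlobular"})


@dataclass(frozen=True)
class MicrovascularBed:
    """The microvascular bed downstream of one arcuate artery."""

    interlobular_resistance: float = TABLE_DEFAULTS["interlobular"]
    nephron: NephronCircuit = field(default_factory=NephronCircuit.from_table_defaults)
    n_interlobular_per_arcuate: int = 650
    n_nephrons_per_interlobular: int = 60
    surviving_fraction: float = 1.0
    compliance: float = 2.53e-11  # m^3/Pa, enters only the 1D outlet coupling

    def __post_init__(self) -> None:
        if self.interlobular_resistance <= 0:
            raise ValueError("interlobular_resistance must be positive")
        if self.n_interlobular_per_arcuate < 1 or self.n_nephrons_per_interlobular < 1:
            raise ValueError("component counts must be >= 1")
        if not (0.0 < self.surviving_fraction <= 1.0):
            raise ValueError(
                f"surviving_fraction must be in (0, 1], got {self.surviving_fraction}"
            )


def default_bed() -> MicrovascularBed:
    """The reference-geometry bed (650 x 60 hierarchy, all nephrons intact)."""
    return MicrovascularBed()


# --- nodal analysis ---------------------------------------------------------

# node indices for the bridge circuit; the outlet is the ground reference
_NODES = {"glomerular": 0, "capillary_exit": 1, "filtrate": 2, "tubular": 3, "peritubular": 4}
# component -> (from node, to node); -1 encodes a terminal (inlet or ground)
_EDGES = {
    "afferent": (-1, 0),  # driven from the inlet
    "glomerular_capillary": (0, 1),
    "efferent": (1, 4),
    "glomerular_filter": (0, 2),
    "renal_tubule": (2, 3),
    "ureter": (3, -1),
    "reabsorption": (3, 4),
    "peritubular_capillary": (4, -1),
}


@dataclass(frozen=True)
class BedSolution:
    """Solved pressures/flows for one nephron or one whole bed."""

    node_pressures: dict[str, float]  # Pa, absolute
    branch_flows: dict[str, float]  # m^3/s, positive in the edge direction
    equivalent_resistance: float  # Pa*s/m^3
    filtration_flow: float  # m^3/s through the glomerular filter
    filtration_fraction: float  # filter flow / glomerular inflow
    gfr: float = float("nan")  # ml/min, only set by whole-bed solves


def solve_nephron(
    circuit: NephronCircuit, inlet_pressure: float, outlet_pressure: float
) -> BedSolution:
    """Solve the single-nephron bridge circuit by nodal analysis.

    Returns absolute node pressures, branch flows, the nephron equivalent
    resistance (pressure drop over inlet flow) and the filter-branch flow.
    """
    if not inlet_pressure > outlet_pressure:
        raise ValueError("inlet_pressure must exceed outlet_pressure")
    n = len(_NODES)
    G = np.zeros((n, n))
    rhs = np.zeros(n)
    dp = inlet_pressure - outlet_pressure
    for name, (i, j) in _EDGES.items():
        r = circuit[name]
        g = 0.0 if math.isinf(r) else 1.0 / r
        if i >= 0:
            G[i, i] += g
        if j >= 0:
            G[j, j] += g
        if i >= 0 and j >= 0:
            G[i, j] -= g
            G[j, i] -= g
        elif name == "afferent":
            rhs[j] += g * dp  # inlet drives node G through the afferent
    # nodes isolated by open (infinite-resistance) branches have no path to
    # the inlet or outlet: pin them at outlet pressure instead of letting the
    # nodal system go singular
    anchored: set[int] = set()
    for name, (i, j) in _EDGES.items():
        if math.isinf(circuit[name]):
            continue
        if i < 0 or j < 0 or name == "afferent":
            anchored.add(j if i < 0 else i)
            anchored.add(j if j >= 0 else i)
    anchored.discard(-1)
    adj = {i: set() for i in range(n)}
    for name, (i, j) in _EDGES.items():
        if not math.isinf(circuit[name]) and i >= 0 and j >= 0:
            adj[i].add(j)
            adj[j].add(i)
    reachable = set()
    stack = [a for a in anchored if a >= 0]
    while stack:
        node = stack.pop()
        if node in reachable:
            continue
        reachable.add(node)
        stack.extend(adj[node])
    for i in range(n):
        if i not in reachable:
            G[i, :] = 0.0
            G[:, i] = 0.0
            G[i, i] = 1.0
            rhs[i] = 0.0
    try:
        v = np.linalg.solve(G, rhs)  # node pressures relative to the outlet
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular nephron system: {exc}") from exc

    def _edge_flow(name: str) -> float:
        r = circuit[name]
        if math.isinf(r):
            return 0.0
        i, j = _EDGES[name]
        vi = dp if name == "afferent" else v[i]
        vj = 0.0 if j < 0 else v[j]
        return (vi - vj) / r

    flows = {name: _edge_flow(name) for name in _EDGES}
    inflow = flows["afferent"]
    if inflow <= 0:
        raise ValueError("nephron carries no inlet flow; check component resistances")
    pressures = {name: outlet_pressure + v[idx] for name, idx in _NODES.items()}
    return BedSolution(
        node_pressures=pressures,
        branch_flows=flows,
        equivalent_resistance=dp / inflow,
        filtration_flow=flows["glomerular_filter"],
        filtration_fraction=flows["glomerular_filter"] / inflow,
    )


def nephron_equivalent_resistance(circuit: NephronCircuit) -> float:
    """Equivalent resistance of one nephron (afferent inlet to outlet)."""
    return solve_nephron(circuit, 1.0, 0.0).equivalent_resistance


def nephron_block_resistance(bed: MicrovascularBed) -> float:
    """Equivalent resistance of the parallel nephron block of one
    interlobular unit, including any nephron loss."""
    r_n = nephron_equivalent_resistance(bed.nephron)
    n_eff = bed.n_nephrons_per_interlobular * bed.surviving_fraction
    return r_n / n_eff


def bed_equivalent_resistance(bed: MicrovascularBed) -> float:
    """Total resistance downstream of one arcuate artery.

    Two-level parallel hierarchy: each interlobular artery is in series with
    its nephron block; ``n_interlobular_per_arcuate`` such units in parallel.
    """
    unit = bed.interlobular_resistance + nephron_block_resistance(bed)
    return unit / bed.n_interlobular_per_arcuate


def solve_bed(bed: MicrovascularBed, inlet_pressure: float, outlet_pressure: float) -> BedSolution:
    """Steady whole-bed solve at a given (cycle-mean) perfusion pressure."""
    r_bed = bed_equivalent_resistance(bed)
    dp = inlet_pressure - outlet_pressure
    if dp <= 0:
        raise ValueError("inlet_pressure must exceed outlet_pressure")
    q_bed = dp / r_bed
    q_unit = q_bed / bed.n_interlobular_per_arcuate
    p_glom_in = inlet_pressure - q_unit * bed.interlobular_resistance
    neph = solve_nephron(bed.nephron, p_glom_in, outlet_pressure)
    filt = neph.filtration_fraction * q_bed
    return BedSolution(
        node_pressures=neph.node_pressures,
        branch_flows={"bed_inflow": q_bed, **neph.branch_flows},
        equivalent_resistance=r_bed,
        filtration_flow=filt,
        filtration_fraction=neph.filtration_fraction,
        gfr=filt * ML_PER_M3 * S_PER_MIN,
    )


def compute_gfr(
    bed: MicrovascularBed,
    inlet_pressure: float,
    outlet_pressure: float = 5.0 * 133.322,
    n_beds: int = 40,
) -> tuple[float, float]:
    """GFR [ml/min] summed over ``n_beds`` identical beds, and the blood-side
    filtration fraction (filter-branch flow over glomerular inflow)."""
    sol = solve_bed(bed, inlet_pressure, outlet_pressure)
    return sol.gfr * n_beds, sol.filtration_fraction


# --- disease edits ----------------------------------------------------------


def apply_dkd_arterioles(
    bed: MicrovascularBed,
    afferent_radius_scale: float = 1.10,
    efferent_radius_scale: float = 0.93,
) -> MicrovascularBed:
    """Diabetic arteriolar remodelling: afferent dilation and efferent
    constriction, as lumen-diameter scale factors (Poiseuille, R x s**-4)."""
    if afferent_radius_scale <= 0 or efferent_radius_scale <= 0:
        raise ValueError("radius scales must be positive")
    circuit = bed.nephron.with_resistances(
        afferent=bed.nephron["afferent"] * afferent_radius_scale**-4,
        efferent=bed.nephron["efferent"] * efferent_radius_scale**-4,
    )
    return replace(bed, nephron=circuit)


def apply_nephron_loss(bed: MicrovascularBed, surviving_fraction: float) -> MicrovascularBed:
    """Glomerular loss: only ``surviving_fraction`` of nephrons per
    interlobular unit remain conducting (parallel-conductance scaling)."""
    if not 0.0 < surviving_fraction <= 1.0:
        raise ValueError(f"surviving_fraction must be in (0, 1], got {surviving_fraction}")
    return replace(bed, surviving_fraction=bed.surviving_fraction * surviving_fraction)


def solve_hkd_interlobular_scale(
    bed: MicrovascularBed, target_pvr_ratio: float = 1.10, bracket: tuple[float, float] = (0.3, 1.0)
) -> float:
    """Interlobular lumen-radius multiplier s (< 1 constricts) such that the
    bed equivalent resistance becomes ``target_pvr_ratio`` times its current
    value, with the interlobular resistance rescaled by s**-4."""
    if target_pvr_ratio < 1.0:
        raise ValueError("target_pvr_ratio must be >= 1")
    if target_pvr_ratio == 1.0:
        return 1.0
    baseline = bed_equivalent_resistance(bed)

    def _mismatch(s: float) -> float:
        scaled = replace(bed, interlobular_resistance=bed.interlobular_resistance * s**-4)
        return bed_equivalent_resistance(scaled) - target_pvr_ratio * baseline

    lo, hi = bracket
    if _mismatch(lo) < 0:
        raise ValueError(
            f"target PVR ratio {target_pvr_ratio} unreachable within radius-scale "
            f"bracket {bracket}"
        )
    return brentq(_mismatch, lo, hi, rtol=1e-10)
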