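import math

import numpy as np
import pytest

from renaltwin import microcirculation as mc
from renaltwin.network import ArterialNetwork, VesselSegment, WindkesselTerminal
from renaltwin.solver import characteristic_impedance, vessel_beta


@pytest.fixture(scope="session")
def default_bed() -> mc.MicrovascularBed:
    return mc.MicrovascularBed()


def make_single_vessel(
    length=0.4,
    radius=0.005,
    wall=0.0008,
    youngs=4.0e5,
    distal_resistance=1.5e8,
    compliance=5.0e-9,
    proximal_resistance=None,
) -> ArterialNetwork:
    v = VesselSegment(
        id="tube", length=length, lumen_radius_ref=radius,
        wall_thickness=wall, youngs_modulus=youngs,
    )
    beta = vessel_beta(youngs, wall)
    zc = characteristic_impedance(beta, v.reference_area)
    term = WindkesselTerminal(
        id="tube",
        proximal_resistance=proximal_resistance if proximal_resistance else zc,
        distal_resistance=distal_resistance,
        compliance=compliance,
    )
    return ArterialNetwork(vessels={"tube": v}, terminals={"tube": term}, inlet_vessel="tube")


@pytest.fixture(scope="session")
def single_vessel() -> ArterialNetwork:
    return make_single_vessel()


def expanded_bed_resistance(bed: mc.MicrovascularBed) -> float:
    """Brute-force oracle: nodal solve of the fully expanded bed circuit
    (every interlobular unit and every nephron as explicit components),
    independent of the hierarchical reduction under test."""
    n_int = bed.n_interlobular_per_arcuate
    n_nep = bed.n_nephrons_per_interlobular
    # node numbering: for each interlobular unit u: its distal node; for each
    # nephron (u, k): nodes G, X, F, T, PT.  Inlet held at 1, outlet at 0.
    n_nodes = n_int * (1 + 5 * n_nep)
    G = np.zeros((n_nodes, n_nodes))
    rhs = np.zeros(n_nodes)
    r = bed.nephron.resistances

    def add(i, j, res):
        g = 1.0 / res
        if i >= 0:
            G[i, i] += g
        if j >= 0:
            G[j, j] += g
        if i >= 0 and j >= 0:
            G[i, j] -= g
            G[j, i] -= g

    def drive(node, res):  # edge from the unit-pressure inlet
        add(node, -1, res)
        rhs[node] += 1.0 / res

    for u in range(n_int):
        d = u * (1 + 5 * n_nep)
        drive(d, bed.interlobular_resistance)
        for k in range(n_nep):
            g0 = d + 1 + 5 * k
            gG, gX, gF, gT, gPT = g0, g0 + 1, g0 + 2, g0 + 3, g0 + 4
            add(d, gG, r["afferent"])
            add(gG, gX, r["glomerular_capillary"])
            add(gX, gPT, r["efferent"])
            add(gG, gF, r["glomerular_filter"])
            add(gF, gT, r["renal_tubule"])
            add(gT, -1, r["ureter"])
            add(gT, gPT, r["reabsorption"])
            add(gPT, -1, r["peritubular_capillary"])
    v = np.linalg.solve(G, rhs)
    inflow = sum(
        (1.0 - v[u * (1 + 5 * n_nep)]) / bed.interlobular_resistance
        for u in range(n_int)
    )
    return 1.0 / inflow
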