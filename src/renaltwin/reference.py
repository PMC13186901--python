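"""Construction of the packaged reference arterial tree.

A 75-segment adult systemic arterial tree with 29 outlets, assembled from
standard published segment tables (aorta, supra-aortic, upper/lower limb and
visceral branches).  It is a documented substitute for bespoke dimensional
tables that are not publicly available, and is calibrated so that the non-sex-specific reference
subject reproduces textbook haemodynamics: mean aortic pressure ~93 mmHg and
brachial pressure ~118/78 mmHg at a cardiac output of 5.6 l/min, with about
17% of cardiac output perfusing the kidneys (set by the renal microvascular
bed resistance, 2.80e10 Pa s/m^3 per arcuate bed).

Wall stiffness is assigned by vessel class, giving reference pulse-wave
speeds of ~4.3 m/s (aorta) to ~10 m/s (distal muscular arteries).
"""

from __future__ import annotations

import math

from .microcirculation import MicrovascularBed, bed_equivalent_resistance
from .network import MM, ArterialNetwork, VesselSegment, WindkesselTerminal, attach_renal_trees
from .solver import MMHG, characteristic_impedance, vessel_beta

__all__ = ["build_systemic_reference", "build_full_reference", "REFERENCE_CO"]

#: reference (non-sex-specific, 20-29 yo) cardiac output [m^3/s] (5.6 l/min)
REFERENCE_CO = 5.6e-3 / 60.0

_MAP = 93.0 * MMHG
_VENOUS = 5.0 * MMHG

# vessel classes -> (Young's modulus kPa, wall thickness / radius)
_CLASSES = {
    "aorta": (350.0, 0.10),
    "elastic": (420.0, 0.12),
    "muscular": (650.0, 0.15),
    "distal": (850.0, 0.18),
}

# (id, parent, length_mm, radius_mm, class); order is definition order
_SEGMENTS: list[tuple[str, str | None, float, float, str]] = [
    # aorta
    ("ascending_aorta", None, 40, 14.0, "aorta"),
    ("aortic_arch_a", "ascending_aorta", 20, 13.0, "aorta"),
    ("aortic_arch_b", "aortic_arch_a", 39, 12.0, "aorta"),
    ("thoracic_aorta_a", "aortic_arch_b", 52, 11.0, "aorta"),
    ("thoracic_aorta_b", "thoracic_aorta_a", 52, 10.2, "aorta"),
    ("thoracic_aorta_c", "thoracic_aorta_b", 52, 9.6, "aorta"),
    ("abdominal_aorta_a", "thoracic_aorta_c", 53, 9.0, "aorta"),
    ("abdominal_aorta_b", "abdominal_aorta_a", 20, 8.7, "aorta"),
    ("abdominal_aorta_c", "abdominal_aorta_b", 20, 8.4, "aorta"),
    ("abdominal_aorta_d", "abdominal_aorta_c", 96, 8.0, "aorta"),
    ("abdominal_aorta_e", "abdominal_aorta_d", 20, 7.5, "aorta"),
    # supra-aortic
    ("brachiocephalic", "aortic_arch_a", 34, 6.2, "elastic"),
    ("r_common_carotid_a", "brachiocephalic", 47, 3.7, "elastic"),
    ("r_common_carotid_b", "r_common_carotid_a", 47, 3.6, "elastic"),
    ("l_common_carotid_a", "aortic_arch_b", 70, 3.7, "elastic"),
    ("l_common_carotid_b", "l_common_carotid_a", 69, 3.6, "elastic"),
    ("r_internal_carotid_a", "r_common_carotid_b", 89, 2.0, "distal"),
    ("r_internal_carotid_b", "r_internal_carotid_a", 89, 1.9, "distal"),
    ("r_external_carotid", "r_common_carotid_b", 118, 1.8, "distal"),
    ("l_internal_carotid_a", "l_common_carotid_b", 89, 2.0, "distal"),
    ("l_internal_carotid_b", "l_internal_carotid_a", 89, 1.9, "distal"),
    ("l_external_carotid", "l_common_carotid_b", 118, 1.8, "distal"),
    # arms
    ("r_subclavian", "brachiocephalic", 34, 4.2, "elastic"),
    ("l_subclavian", "aortic_arch_b", 34, 4.2, "elastic"),
    ("r_vertebral", "r_subclavian", 149, 1.9, "distal"),
    ("l_vertebral", "l_subclavian", 148, 1.9, "distal"),
    ("r_brachial_a", "r_subclavian", 211, 4.0, "muscular"),
    ("r_brachial_b", "r_brachial_a", 211, 3.7, "muscular"),
    ("l_brachial_a", "l_subclavian", 211, 4.0, "muscular"),
    ("l_brachial_b", "l_brachial_a", 211, 3.7, "muscular"),
    ("r_radial_a", "r_brachial_b", 118, 1.6, "distal"),
    ("r_radial_b", "r_radial_a", 117, 1.6, "distal"),
    ("l_radial_a", "l_brachial_b", 118, 1.6, "distal"),
    ("l_radial_b", "l_radial_a", 117, 1.6, "distal"),
    ("r_ulnar_a", "r_brachial_b", 67, 2.2, "distal"),
    ("l_ulnar_a", "l_brachial_b", 67, 2.2, "distal"),
    ("r_interosseous", "r_ulnar_a", 79, 0.9, "distal"),
    ("l_interosseous", "l_ulnar_a", 79, 0.9, "distal"),
    ("r_ulnar_b", "r_ulnar_a", 86, 1.9, "distal"),
    ("r_ulnar_c", "r_ulnar_b", 85, 1.9, "distal"),
    ("l_ulnar_b", "l_ulnar_a", 86, 1.9, "distal"),
    ("l_ulnar_c", "l_ulnar_b", 85, 1.9, "distal"),
    # trunk branches
    ("r_intercostal", "thoracic_aorta_a", 80, 2.0, "distal"),
    ("l_intercostal", "thoracic_aorta_b", 80, 2.0, "distal"),
    ("celiac_a", "abdominal_aorta_a", 15, 3.9, "muscular"),
    ("celiac_b", "celiac_a", 15, 3.9, "muscular"),
    ("gastric", "celiac_b", 71, 1.8, "distal"),
    ("splenic", "celiac_b", 63, 2.8, "muscular"),
    ("hepatic", "celiac_b", 66, 2.2, "muscular"),
    ("superior_mesenteric", "abdominal_aorta_b", 59, 4.4, "muscular"),
    ("r_renal", "abdominal_aorta_c", 32, 2.6, "muscular"),
    ("l_renal", "abdominal_aorta_c", 32, 2.6, "muscular"),
    ("inferior_mesenteric", "abdominal_aorta_d", 50, 1.6, "distal"),
    # legs
    ("r_common_iliac", "abdominal_aorta_e", 58, 3.7, "elastic"),
    ("l_common_iliac", "abdominal_aorta_e", 58, 3.7, "elastic"),
    ("r_internal_iliac", "r_common_iliac", 50, 2.0, "muscular"),
    ("l_internal_iliac", "l_common_iliac", 50, 2.0, "muscular"),
    ("r_external_iliac", "r_common_iliac", 144, 2.9, "elastic"),
    ("l_external_iliac", "l_common_iliac", 144, 2.9, "elastic"),
    ("r_femoral_a", "r_external_iliac", 221, 2.4, "muscular"),
    ("r_deep_femoral", "r_femoral_a", 126, 2.0, "muscular"),
    ("r_femoral_b", "r_femoral_a", 222, 2.4, "muscular"),
    ("l_femoral_a", "l_external_iliac", 221, 2.4, "muscular"),
    ("l_deep_femoral", "l_femoral_a", 126, 2.0, "muscular"),
    ("l_femoral_b", "l_femoral_a", 222, 2.4, "muscular"),
    ("r_popliteal_a", "r_femoral_b", 94, 2.1, "muscular"),
    ("r_popliteal_b", "r_popliteal_a", 94, 2.0, "muscular"),
    ("l_popliteal_a", "l_femoral_b", 94, 2.1, "muscular"),
    ("l_popliteal_b", "l_popliteal_a", 94, 2.0, "muscular"),
    ("r_anterior_tibial", "r_popliteal_b", 343, 1.3, "distal"),
    ("l_anterior_tibial", "l_popliteal_b", 343, 1.3, "distal"),
    ("r_posterior_tibial_a", "r_popliteal_b", 161, 1.4, "distal"),
    ("r_posterior_tibial_b", "r_posterior_tibial_a", 160, 1.4, "distal"),
    ("l_posterior_tibial_a", "l_popliteal_b", 161, 1.4, "distal"),
    ("l_posterior_tibial_b", "l_posterior_tibial_a", 160, 1.4, "distal"),
]

# non-renal outlet flow shares (arbitrary units, normalised); territory splits
# follow textbook distributions (cerebral 12%, splanchnic ~30%, legs ~22%).
_OUTLET_SHARES = {
    "r_external_carotid": 2.5, "l_external_carotid": 2.5,
    "r_internal_carotid_b": 6.0, "l_internal_carotid_b": 6.0,
    "r_vertebral": 2.0, "l_vertebral": 2.0,
    "r_radial_b": 1.5, "l_radial_b": 1.5,
    "r_ulnar_c": 1.5, "l_ulnar_c": 1.5,
    "r_interosseous": 0.5, "l_interosseous": 0.5,
    "r_intercostal": 3.0, "l_intercostal": 3.0,
    "gastric": 2.0, "splenic": 6.0, "hepatic": 6.5,
    "superior_mesenteric": 13.0, "inferior_mesenteric": 3.5,
    "r_internal_iliac": 3.0, "l_internal_iliac": 3.0,
    "r_deep_femoral": 3.0, "l_deep_femoral": 3.0,
    "r_anterior_tibial": 2.0, "l_anterior_tibial": 2.0,
    "r_posterior_tibial_b": 3.0, "l_posterior_tibial_b": 3.0,
}

#: total terminal compliance [m^3/Pa] across the non-renal outlets (~0.67
#: ml/mmHg; the distensible vessels themselves contribute the remainder of
#: total arterial compliance)
_TERMINAL_COMPLIANCE_TOTAL = 7.5e-9

#: windkessel design derating: the outlets see less than the full MAP-venous
#: drop because of distributed viscous losses along the tree; calibrated so
#: the reference subject's simulated mean aortic pressure is ~93 mmHg.
_R_CALIBRATION = 0.84

#: stand-in terminal values for the renal stubs in the systemic-only file:
#: total resistance of one kidney (20 beds in parallel) and its compliance.
_RENAL_STUB_R = bed_equivalent_resistance(MicrovascularBed()) / 20.0
_RENAL_STUB_C = 20 * 2.53e-11


def build_systemic_reference() -> ArterialNetwork:
    """The 75-vessel systemic tree with 29 R-C-R outlets (renal outlets are
    single lumped stubs; use :func:`build_full_reference` for renal trees)."""
    vessels: dict[str, VesselSegment] = {}
    for vid, parent, length, radius, cls in _SEGMENTS:
        e_kpa, h_ratio = _CLASSES[cls]
        vessels[vid] = VesselSegment(
            id=vid,
            parent=parent,
            name=vid.replace("_", " "),
            length=length * MM,
            lumen_radius_ref=radius * MM,
            wall_thickness=h_ratio * radius * MM,
            youngs_modulus=e_kpa * 1e3,
        )
    # renal flow set by the bed chain; the rest distributed by territory share
    q_renal = (_MAP - _VENOUS) / (_RENAL_STUB_R / 2.0)
    q_rest = REFERENCE_CO - q_renal
    share_sum = sum(_OUTLET_SHARES.values())
    terminals: dict[str, WindkesselTerminal | MicrovascularBed] = {}
    for vid, share in _OUTLET_SHARES.items():
        frac = share / share_sum
        r_total = _R_CALIBRATION * (_MAP - _VENOUS) / (frac * q_rest)
        v = vessels[vid]
        beta = vessel_beta(v.youngs_modulus, v.wall_thickness)
        r1 = min(characteristic_impedance(beta, v.reference_area), 0.2 * r_total)
        terminals[vid] = WindkesselTerminal(
            id=vid,
            proximal_resistance=r1,
            distal_resistance=r_total - r1,
            compliance=_TERMINAL_COMPLIANCE_TOTAL * frac,
        )
    for vid in ("r_renal", "l_renal"):
        v = vessels[vid]
        beta = vessel_beta(v.youngs_modulus, v.wall_thickness)
        r1 = min(characteristic_impedance(beta, v.reference_area), 0.2 * _RENAL_STUB_R)
        terminals[vid] = WindkesselTerminal(
            id=vid,
            proximal_resistance=r1,
            distal_resistance=_RENAL_STUB_R - r1,
            compliance=_RENAL_STUB_C,
        )
    return ArterialNetwork(vessels=vessels, terminals=terminals, inlet_vessel="ascending_aorta")


def build_full_reference(bed: MicrovascularBed | None = None) -> ArterialNetwork:
    """Systemic tree with both renal fragments attached (147 vessels,
    27 windkessel outlets, 40 microvascular beds)."""
    return attach_renal_trees(build_systemic_reference(), bed=bed)
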