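"""Unit and property tests for the 0D renal microcirculation model."""

import math
from dataclasses import replace

import numpy as np
import pytest

from renaltwin import microcirculation as mc
from conftest import expanded_bed_resistance


def poiseuille_oracle(mu, length, radius):
    return 8.0 * mu * length / (math.pi * radius**4)


class TestPoiseuille:
    @pytest.mark.parametrize(
        "mu,length,radius",
        [
            (4.00e-3, 370e-6, 22.9e-6),  # interlobular geometry
            (4.00e-3, 112e-6, 10.7e-6),  # afferent arteriole
            (2.00e-3, 18_000e-6, 16.4e-6),  # renal tubule
            (2.00e-3, 120e-6, 7.97e-6),  # efferent arteriole
        ],
    )
    def test_matches_direct_evaluation(self, mu, length, radius):
        assert mc.poiseuille_resistance(mu, length, radius) == pytest.approx(
            poiseuille_oracle(mu, length, radius), rel=1e-12
        )

    def test_reference_geometry_reproduces_tabulated_values(self):
        """The packaged component resistances are Hagen-Poiseuille
        evaluations of the reference geometry (to printed precision)."""
        for name, (mu, length, radius) in mc.POISEUILLE_GEOMETRY.items():
            assert mc.poiseuille_resistance(mu, length, radius) == pytest.approx(
                mc.TABLE_DEFAULTS[name], rel=5e-3
            )

    def test_zero_length_and_radius_scaling(self):
        assert mc.poiseuille_resistance(1e-3, 0.0, 1e-5) == 0.0
        r = 1.3e-5
        assert mc.poiseuille_resistance(2e-3, 1e-4, r / 2) == pytest.approx(
            16.0 * mc.poiseuille_resistance(2e-3, 1e-4, r), rel=1e-12
        )

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            mc.poiseuille_resistance(0.0, 1e-4, 1e-5)
        with pytest.raises(ValueError):
            mc.poiseuille_resistance(1e-3, 1e-4, 0.0)


class TestNephronCircuit:
    def test_two_resistor_series_ohms_law(self):
        """With every branch but afferent->capillary->efferent->peritubular
        open, the circuit degenerates to resistors in series."""
        circ = mc.NephronCircuit({
            "afferent": 1e12, "glomerular_capillary": 1e12,
            "glomerular_filter": math.inf, "renal_tubule": 1e12,
            "reabsorption": math.inf, "efferent": 1.0,
            "peritubular_capillary": 1.0, "ureter": math.inf,
        })
        sol = mc.solve_nephron(circ, 1.0, 0.0)
        assert sol.branch_flows["afferent"] == pytest.approx(5e-13, rel=1e-9)

    def test_blocked_filter_gives_zero_filtration_and_series_resistance(self):
        circ = mc.NephronCircuit.from_table_defaults().with_resistances(
            glomerular_filter=math.inf
        )
        sol = mc.solve_nephron(circ, 1.0e4, 0.0)
        assert sol.filtration_flow == 0.0
        assert sol.filtration_fraction == 0.0
        r = circ.resistances
        # blood path in series; the peritubular capillary is shunted by the
        # (high-resistance) reabsorption + ureter leak to the outlet
        shunt = 1.0 / (
            1.0 / r["peritubular_capillary"]
            + 1.0 / (r["reabsorption"] + r["ureter"])
        )
        series = r["afferent"] + r["glomerular_capillary"] + r["efferent"] + shunt
        assert sol.equivalent_resistance == pytest.approx(series, rel=1e-9)

    def test_flow_conservation_at_every_node(self):
        circ = mc.NephronCircuit.from_table_defaults()
        sol = mc.solve_nephron(circ, 1.2e4, 600.0)
        f = sol.branch_flows
        balances = {
            "glomerular": f["afferent"] - f["glomerular_capillary"] - f["glomerular_filter"],
            "capillary_exit": f["glomerular_capillary"] - f["efferent"],
            "filtrate": f["glomerular_filter"] - f["renal_tubule"],
            "tubular": f["renal_tubule"] - f["ureter"] - f["reabsorption"],
            "peritubular": f["efferent"] + f["reabsorption"] - f["peritubular_capillary"],
        }
        for node, imbalance in balances.items():
            assert abs(imbalance) / f["afferent"] < 1e-10, node

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError, match="efferent"):
            mc.NephronCircuit.from_table_defaults().with_resistances(efferent=0.0)


class TestBedReduction:
    def test_reduction_equals_brute_force_expanded_solve(self, default_bed):
        """Hierarchical two-level parallel reduction against a full nodal
        solve of the expanded circuit, on small instances."""
        for n_int, n_nep in [(1, 1), (2, 3), (5, 3)]:
            bed = replace(
                default_bed,
                n_interlobular_per_arcuate=n_int,
                n_nephrons_per_interlobular=n_nep,
            )
            assert mc.bed_equivalent_resistance(bed) == pytest.approx(
                expanded_bed_resistance(bed), rel=1e-9
            )

    def test_degenerate_counts(self, default_bed):
        bed = replace(default_bed, n_interlobular_per_arcuate=1, n_nephrons_per_interlobular=1)
        expected = bed.interlobular_resistance + mc.nephron_equivalent_resistance(bed.nephron)
        assert mc.bed_equivalent_resistance(bed) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_component_resistances(self, default_bed):
        """Equivalent resistance never decreases when any single component
        resistance is increased (checked on randomised circuits)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            scales = {
                k: float(rng.uniform(0.5, 2.0)) * v
                for k, v in default_bed.nephron.resistances.items()
            }
            bed = replace(default_bed, nephron=mc.NephronCircuit(scales))
            base = mc.bed_equivalent_resistance(bed)
            comp = rng.choice(list(scales))
            bumped = replace(
                bed,
                nephron=bed.nephron.with_resistances(**{comp: scales[comp] * 1.05}),
            )
            assert mc.bed_equivalent_resistance(bumped) >= base * (1 - 1e-12)


class TestDiseaseEdits:
    def test_identity_scales(self, default_bed):
        same = mc.apply_dkd_arterioles(default_bed, 1.0, 1.0)
        assert mc.bed_equivalent_resistance(same) == pytest.approx(
            mc.bed_equivalent_resistance(default_bed), rel=1e-12
        )
        assert mc.apply_nephron_loss(default_bed, 1.0).surviving_fraction == 1.0

    def test_afferent_dilation_alone_lowers_resistance(self, default_bed):
        dilated = mc.apply_dkd_arterioles(default_bed, 1.10, 1.0)
        assert mc.bed_equivalent_resistance(dilated) < mc.bed_equivalent_resistance(
            default_bed
        )

    def test_halved_nephron_count_doubles_block_resistance(self, default_bed):
        half = mc.apply_nephron_loss(default_bed, 0.5)
        assert mc.nephron_block_resistance(half) == pytest.approx(
            2.0 * mc.nephron_block_resistance(default_bed), rel=1e-12
        )

    def test_nephron_loss_is_reciprocal_conductance(self, default_bed):
        lost = mc.apply_nephron_loss(default_bed, 0.43)
        assert mc.nephron_block_resistance(lost) == pytest.approx(
            mc.nephron_block_resistance(default_bed) / 0.43, rel=1e-12
        )

    def test_arteriole_edit_and_nephron_loss_commute(self, default_bed):
        a = mc.apply_nephron_loss(mc.apply_dkd_arterioles(default_bed), 0.43)
        b = mc.apply_dkd_arterioles(mc.apply_nephron_loss(default_bed, 0.43))
        assert mc.bed_equivalent_resistance(a) == pytest.approx(
            mc.bed_equivalent_resistance(b), rel=1e-12
        )

    def test_full_diabetic_edit_reproduces_renal_pvr_factor(self, default_bed):
        """Arteriolar remodelling plus 57% nephron loss raises the bed PVR
        by ~35% over baseline, matching the tabulated disease factor."""
        dkd = mc.apply_nephron_loss(mc.apply_dkd_arterioles(default_bed), 0.43)
        factor = mc.bed_equivalent_resistance(dkd) / mc.bed_equivalent_resistance(
            default_bed
        )
        assert factor == pytest.approx(1.35, rel=0.01)


class TestHkdInterlobularScale:
    def test_unit_target_is_fixed_point(self, default_bed):
        assert mc.solve_hkd_interlobular_scale(default_bed, 1.0) == 1.0

    def test_self_consistency_at_ten_percent(self, default_bed):
        s = mc.solve_hkd_interlobular_scale(default_bed, 1.10)
        assert 0.3 < s < 1.0
        scaled = replace(
            default_bed,
            interlobular_resistance=default_bed.interlobular_resistance * s**-4,
        )
        assert mc.bed_equivalent_resistance(scaled) == pytest.approx(
            1.10 * mc.bed_equivalent_resistance(default_bed), rel=1e-6
        )

    def test_unreachable_target_raises(self, default_bed):
        tiny_share = replace(default_bed, interlobular_resistance=1e10)
        with pytest.raises(ValueError, match="unreachable"):
            mc.solve_hkd_interlobular_scale(tiny_share, 2.0)


class TestGfr:
    def test_blocked_filter_gives_zero_gfr(self, default_bed):
        bed = replace(
            default_bed,
            nephron=default_bed.nephron.with_resistances(glomerular_filter=math.inf),
        )
        gfr, ff = mc.compute_gfr(bed, 1.2e4)
        assert gfr == 0.0 and ff == 0.0

    def test_symmetric_branch_split(self):
        """Equal branch resistances from the glomerular node split the inflow
        evenly, so the filtration fraction is one half."""
        circ = mc.NephronCircuit({
            "afferent": 1e12,
            "glomerular_capillary": 5e11, "efferent": 5e11,
            "glomerular_filter": 4e11, "renal_tubule": 6e11,
            "reabsorption": math.inf,
            "peritubular_capillary": 1e12, "ureter": 1e12,
        })
        sol = mc.solve_nephron(circ, 1e4, 0.0)
        # both branches: 1e12 to ground through symmetric chains
        assert sol.filtration_fraction == pytest.approx(0.5, rel=1e-9)

    def test_gfr_scales_with_bed_count_and_pressure_invariant_fraction(self, default_bed):
        g40, ff40 = mc.compute_gfr(default_bed, 1.2e4, n_beds=40)
        g20, ff20 = mc.compute_gfr(default_bed, 1.2e4, n_beds=20)
        assert g40 == pytest.approx(2 * g20, rel=1e-12)
        _, ff_hi = mc.compute_gfr(default_bed, 1.5e4)
        assert ff40 == ff20 == pytest.approx(ff_hi, rel=1e-12)
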