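"""Virtual-subject generation: sex, age and disease parameterisation.

A subject is a set of multiplicative factors on the reference network's
mechanical parameters (lumen radius, Young's modulus, wall thickness, length,
terminal PVR/PVC) plus cardiac output and blood viscosity.  Factors compose
as

    factor = sex(param) * age(param) * disease(param) * N(1, cv_subject) *
             N(1, cv_vessel)   [the last drawn independently per vessel]

The subject-level draw models coherent inter-individual variability (a
person's vasculature is globally stiffer or more constricted), the
per-vessel draw local heterogeneity.  Cohort-level dispersion is dominated
by the subject-level component because independent per-vessel noise averages
out over the many parallel renal pathways; the default CVs are chosen to
reproduce reported population dispersions of renal indices (RI SD ~ 0.04,
GFR SD ~ 10 ml/min).

Only the two renal PVR sex ratios (0.85 male / 1.15 female) are fixed by
reported values; the remaining sex/age factor tables are editable substitutes built
from standard aging-model literature (stiffening ~12%/decade, cardiac output
-4%/decade, renal PVR +9%/decade).

Disease states compose multiplicatively and transitions are restricted to
healthy -> dm_htn -> {dm_htn_dkd, dm_htn_hkd}.  Terminal PVR factors follow
the printed disease columns; blood viscosity enters only the 1D friction
term (the printed PVR columns already summarise the microvascular effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .network import (
    ArterialNetwork,
    NetworkError,
    VesselSegment,
    WindkesselTerminal,
    scale_network,
)
from .microcirculation import MicrovascularBed, NephronCircuit

__all__ = [
    "SEXES",
    "AGE_GROUPS",
    "DISEASE_STATES",
    "VESSEL_PARAMS",
    "TERMINAL_PARAMS",
    "NormalizationTables",
    "SamplingSDs",
    "FilterCriteria",
    "SubjectParameters",
    "build_reference_subject",
    "sample_virtual_subject",
    "apply_disease",
    "physiological_filter",
    "generate_cohort",
    "materialize_subject",
    "subject_seed",
]

SEXES = ("male", "female")
AGE_GROUPS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
DISEASE_STATES = ("healthy", "dm_htn", "dm_htn_dkd", "dm_htn_hkd")

VESSEL_PARAMS = ("length", "lumen_radius", "youngs_modulus", "wall_thickness")
TERMINAL_PARAMS = ("pvr", "pvc")
_SCOPED = VESSEL_PARAMS + TERMINAL_PARAMS

#: reference cardiac output [m^3/s] and blood viscosity [Pa s]
REFERENCE_CO = 5.6e-3 / 60.0
REFERENCE_VISCOSITY = 4.0e-3

_ALLOWED_TRANSITIONS = {
    ("healthy", "dm_htn"),
    ("dm_htn", "dm_htn_dkd"),
    ("dm_htn", "dm_htn_hkd"),
}


def _scoped(global_, systemic, renal):
    return {"global": dict(global_), "systemic": dict(systemic), "renal": dict(renal)}


#: sex factor tables; only the renal PVR ratios (0.85/1.15) are fixed by
#: reported values, the rest are literature-informed substitutes.
DEFAULT_SEX_FACTORS = {
    "male": _scoped(
        {"cardiac_output": 1.07, "viscosity": 1.02},
        {"length": 1.02, "lumen_radius": 1.03, "youngs_modulus": 1.05,
         "wall_thickness": 1.05, "pvr": 0.97, "pvc": 1.05},
        {"length": 1.02, "lumen_radius": 1.03, "youngs_modulus": 1.05,
         "wall_thickness": 1.05, "pvr": 0.85, "pvc": 1.05},
    ),
    "female": _scoped(
        {"cardiac_output": 0.93, "viscosity": 0.98},
        {"length": 0.98, "lumen_radius": 0.97, "youngs_modulus": 0.95,
         "wall_thickness": 0.95, "pvr": 1.03, "pvc": 0.95},
        {"length": 0.98, "lumen_radius": 0.97, "youngs_modulus": 0.95,
         "wall_thickness": 0.95, "pvr": 1.15, "pvc": 0.95},
    ),
}


def _age_factors(decade: int) -> dict:
    d = float(decade)
    sysf = {"length": 1.0, "lumen_radius": 1.0 + 0.01 * d,
            "youngs_modulus": 1.0 + 0.12 * d, "wall_thickness": 1.0 + 0.03 * d,
            "pvr": 1.0 + 0.05 * d, "pvc": 1.0 - 0.06 * d}
    renf = dict(sysf)
    renf["pvr"] = 1.0 + 0.09 * d
    return _scoped(
        {"cardiac_output": 1.0 - 0.04 * d, "viscosity": 1.0 + 0.01 * d}, sysf, renf
    )


DEFAULT_AGE_FACTORS = {g: _age_factors(i) for i, g in enumerate(AGE_GROUPS)}

#: Table-2 disease columns (normalised to the healthy model)
DEFAULT_DISEASE_FACTORS = {
    "dm_htn": _scoped(
        {"cardiac_output": 0.83, "viscosity": 1.20},
        {"length": 1.0, "lumen_radius": 0.97, "youngs_modulus": 1.25,
         "wall_thickness": 1.12, "pvr": 1.17, "pvc": 0.77},
        {"length": 1.0, "lumen_radius": 0.97, "youngs_modulus": 1.25,
         "wall_thickness": 1.12, "pvr": 1.17, "pvc": 0.77},
    ),
    "dm_htn_dkd": _scoped(
        {"cardiac_output": 0.83, "viscosity": 1.20},
        {"length": 1.0, "lumen_radius": 0.97, "youngs_modulus": 1.25,
         "wall_thickness": 1.12, "pvr": 1.17, "pvc": 0.77},
        {"length": 1.0, "lumen_radius": 0.97, "youngs_modulus": 1.25,
         "wall_thickness": 1.12, "pvr": 1.35, "pvc": 0.77},
    ),
    "dm_htn_hkd": _scoped(
        {"cardiac_output": 0.83, "viscosity": 1.20},
        {"length": 1.0, "lumen_radius": 0.97, "youngs_modulus": 1.25,
         "wall_thickness": 1.12, "pvr": 1.17, "pvc": 0.77},
        {"length": 1.0, "lumen_radius": 0.95, "youngs_modulus": 1.40,
         "wall_thickness": 1.23, "pvr": 1.29, "pvc": 0.77},
    ),
}


@dataclass(frozen=True)
class NormalizationTables:
    sex: dict = field(default_factory=lambda: DEFAULT_SEX_FACTORS)
    age: dict = field(default_factory=lambda: DEFAULT_AGE_FACTORS)
    disease: dict = field(default_factory=lambda: DEFAULT_DISEASE_FACTORS)


@dataclass(frozen=True)
class SamplingSDs:
    """Coefficients of variation for the Gaussian factor draws."""

    cardiac_output: float = 0.08
    viscosity: float = 0.03
    subject: dict = field(default_factory=lambda: {
        "length": 0.02, "lumen_radius": 0.03, "youngs_modulus": 0.08,
        "wall_thickness": 0.05, "pvr": 0.11, "pvc": 0.10,
    })
    per_vessel: dict = field(default_factory=lambda: {
        "length": 0.05, "lumen_radius": 0.05, "youngs_modulus": 0.05,
        "wall_thickness": 0.05, "pvr": 0.05, "pvc": 0.05,
    })
    truncation: float = 0.2  # lower truncation, as a fraction of the mean


@dataclass(frozen=True)
class FilterCriteria:
    """Physiological inclusion filter for virtual healthy controls.

    A subject is retained when brachial SBP and DBP lie within ``z_threshold``
    reference standard deviations of the sex/age reference mean and the
    segmental resistive index lies inside ``ri_interval``.  The reference
    SDs are calibration constants of the packaged substitute filter tables.
    """

    sbp_mean: float  # mmHg
    dbp_mean: float  # mmHg
    sbp_sd: float = 4.0  # mmHg
    dbp_sd: float = 3.0  # mmHg
    z_threshold: float = 2.575
    ri_interval: tuple[float, float] = (0.47, 0.80)

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if not self.ri_interval[0] < self.ri_interval[1]:
            raise ValueError("empty RI interval")


@dataclass
class SubjectParameters:
    """One virtual individual, as factors on the reference network."""

    subject_id: str
    sex: str
    age_group: str
    disease_state: str = "healthy"
    cardiac_output: float = REFERENCE_CO  # m^3/s
    viscosity: float = REFERENCE_VISCOSITY  # Pa s
    # scope -> param -> subject-level factor (sex * age * disease * draw)
    factors: dict = field(default_factory=dict)
    # param -> {vessel_id: jitter} (multiplicative, mean 1)
    vessel_jitter: dict = field(default_factory=dict)
    # param -> {vessel_id: jitter} for terminal parameters
    terminal_jitter: dict = field(default_factory=dict)
    seed: int | None = None

    def factor(self, scope: str, param: str) -> float:
        return self.factors.get(scope, {}).get(param, 1.0)


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed derived from the cohort master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _unit_factors() -> dict:
    return {
        "systemic": {p: 1.0 for p in _SCOPED},
        "renal": {p: 1.0 for p in _SCOPED},
    }


def build_reference_subject(
    sex: str, age_group: str, tables: NormalizationTables | None = None
) -> SubjectParameters:
    """Deterministic sex- and age-specific reference subject (no sampling)."""
    tables = tables or NormalizationTables()
    if sex not in tables.sex:
        raise KeyError(f"no sex factor table for {sex!r}")
    if age_group not in tables.age:
        raise KeyError(f"no age factor table for {age_group!r}")
    sx, ag = tables.sex[sex], tables.age[age_group]
    factors = _unit_factors()
    for scope in ("systemic", "renal"):
        for p in _SCOPED:
            factors[scope][p] = sx[scope][p] * ag[scope][p]
    co = REFERENCE_CO * sx["global"]["cardiac_output"] * ag["global"]["cardiac_output"]
    visc = REFERENCE_VISCOSITY * sx["global"]["viscosity"] * ag["global"]["viscosity"]
    return SubjectParameters(
        subject_id=f"ref_{sex}_{age_group}",
        sex=sex,
        age_group=age_group,
        cardiac_output=co,
        viscosity=visc,
        factors=factors,
    )


def sample_virtual_subject(
    reference: SubjectParameters,
    network: ArterialNetwork,
    sds: SamplingSDs | None = None,
    seed: int = 0,
    subject_id: str | None = None,
) -> SubjectParameters:
    """Draw one virtual subject around a reference subject.

    Subject-level factors are drawn per parameter, per-vessel jitters per
    vessel; identical seeds give bit-identical subjects.  Draws are truncated
    below at ``sds.truncation`` times the mean.
    """
    sds = sds or SamplingSDs()
    rng = np.random.default_rng(seed)

    def draw(mean: float, cv: float) -> float:
        return max(rng.normal(mean, cv * abs(mean)), sds.truncation * abs(mean))

    factors = {scope: dict(pf) for scope, pf in reference.factors.items()}
    for scope in ("systemic", "renal"):
        for p in _SCOPED:
            factors[scope][p] = draw(factors[scope][p], sds.subject.get(p, 0.0))
    co = draw(reference.cardiac_output, sds.cardiac_output)
    visc = draw(reference.viscosity, sds.viscosity)

    vessel_jitter: dict = {p: {} for p in VESSEL_PARAMS}
    terminal_jitter: dict = {p: {} for p in TERMINAL_PARAMS}
    for vid in network.vessels:
        for p in VESSEL_PARAMS:
            vessel_jitter[p][vid] = draw(1.0, sds.per_vessel.get(p, 0.0))
    for tid in network.terminals:
        for p in TERMINAL_PARAMS:
            terminal_jitter[p][tid] = draw(1.0, sds.per_vessel.get(p, 0.0))

    return SubjectParameters(
        subject_id=subject_id or f"{reference.subject_id}_s{seed}",
        sex=reference.sex,
        age_group=reference.age_group,
        disease_state=reference.disease_state,
        cardiac_output=co,
        viscosity=visc,
        factors=factors,
        vessel_jitter=vessel_jitter,
        terminal_jitter=terminal_jitter,
        seed=seed,
    )


def apply_disease(
    subject: SubjectParameters, disease: str, tables: NormalizationTables | None = None
) -> SubjectParameters:
    """Scale a subject into a disease state (paired counterpart: the sampled
    draws are reused, only the disease columns change)."""
    tables = tables or NormalizationTables()
    target = disease if disease in DISEASE_STATES else f"dm_htn_{disease}"
    if target not in DISEASE_STATES:
        raise ValueError(f"unknown disease state {disease!r}")
    if (subject.disease_state, target) not in _ALLOWED_TRANSITIONS:
        raise ValueError(
            f"illegal disease transition {subject.disease_state!r} -> {target!r}"
        )
    col = tables.disease[target]
    base = tables.disease.get(subject.disease_state)
    factors = {scope: dict(pf) for scope, pf in subject.factors.items()}
    co, visc = subject.cardiac_output, subject.viscosity
    for scope in ("systemic", "renal"):
        for p in _SCOPED:
            inc = col[scope][p] / (base[scope][p] if base else 1.0)
            factors[scope][p] *= inc
    co *= col["global"]["cardiac_output"] / (base["global"]["cardiac_output"] if base else 1.0)
    visc *= col["global"]["viscosity"] / (base["global"]["viscosity"] if base else 1.0)
    return dc_replace(
        subject,
        subject_id=f"{subject.subject_id}_{target}",
        disease_state=target,
        cardiac_output=co,
        viscosity=visc,
        factors=factors,
    )


def physiological_filter(
    summary: dict, criteria: FilterCriteria
) -> tuple[bool, list[str]]:
    """Apply the inclusion filter to a subject summary {SBP, DBP, RI} (mmHg,
    mmHg, dimensionless); returns (keep, violated criteria)."""
    reasons = []
    if abs(summary["SBP"] - criteria.sbp_mean) > criteria.z_threshold * criteria.sbp_sd:
        reasons.append("SBP")
    if abs(summary["DBP"] - criteria.dbp_mean) > criteria.z_threshold * criteria.dbp_sd:
        reasons.append("DBP")
    lo, hi = criteria.ri_interval
    if not (lo <= summary["RI"] <= hi):
        reasons.append("RI")
    return (not reasons, reasons)


def generate_cohort(
    network: ArterialNetwork,
    n_per_group: int,
    seed: int,
    sexes=SEXES,
    age_groups=AGE_GROUPS,
    tables: NormalizationTables | None = None,
    sds: SamplingSDs | None = None,
) -> list[SubjectParameters]:
    """Deterministically generate the healthy candidate cohort
    (``n_per_group`` subjects per sex/age cell)."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    tables = tables or NormalizationTables()
    sds = sds or SamplingSDs()
    cohort = []
    idx = 0
    for sex in sexes:
        for age in age_groups:
            ref = build_reference_subject(sex, age, tables)
            for k in range(n_per_group):
                sid = f"{sex}_{age}_{k:04d}"
                cohort.append(
                    sample_virtual_subject(
                        ref, network, sds,
                        seed=subject_seed(seed, idx), subject_id=sid,
                    )
                )
                idx += 1
    return cohort


# --- materialisation ---------------------------------------------------------


def _bed_with_pvr(bed: MicrovascularBed, pvr: float, pvc: float) -> MicrovascularBed:
    nephron = NephronCircuit({k: v * pvr for k, v in bed.nephron.resistances.items()})
    return dc_replace(
        bed,
        interlobular_resistance=bed.interlobular_resistance * pvr,
        nephron=nephron,
        compliance=bed.compliance * pvc,
    )


def materialize_subject(
    network: ArterialNetwork, subject: SubjectParameters
) -> ArterialNetwork:
    """Apply a subject's factors to the reference network, returning the
    personalised network handed to the 1D solver."""
    vessels = {}
    for vid, v in network.vessels.items():
        scope = "renal" if v.group.startswith("renal") else "systemic"
        f = subject.factors.get(scope, {})

        def vf(p):
            return f.get(p, 1.0) * subject.vessel_jitter.get(p, {}).get(vid, 1.0)

        vessels[vid] = VesselSegment(
            id=v.id,
            parent=v.parent,
            name=v.name,
            length=v.length * vf("length"),
            lumen_radius_ref=v.lumen_radius_ref * vf("lumen_radius"),
            wall_thickness=v.wall_thickness * vf("wall_thickness"),
            youngs_modulus=v.youngs_modulus * vf("youngs_modulus"),
            group=v.group,
            generation=v.generation,
        )
    terminals = {}
    for tid, t in network.terminals.items():
        scope = "renal" if network.vessels[tid].group.startswith("renal") else "systemic"
        f = subject.factors.get(scope, {})
        pvr = f.get("pvr", 1.0) * subject.terminal_jitter.get("pvr", {}).get(tid, 1.0)
        pvc = f.get("pvc", 1.0) * subject.terminal_jitter.get("pvc", {}).get(tid, 1.0)
        if isinstance(t, MicrovascularBed):
            terminals[tid] = _bed_with_pvr(t, pvr, pvc)
        else:
            terminals[tid] = WindkesselTerminal(
                id=t.id,
                proximal_resistance=t.proximal_resistance * pvr,
                distal_resistance=t.distal_resistance * pvr,
                compliance=t.compliance * pvc,
            )
    return ArterialNetwork(
        vessels=vessels,
        terminals=terminals,
        inlet_vessel=network.inlet_vessel,
        waveform_ref=network.waveform_ref,
    )
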