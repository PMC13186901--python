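"""Synthetic class-conditional waveform cohorts with known ground truth.

A stand-in for the 1D solver when testing the biomarker and trial stages:
each subject's renal waveforms are built from a closed-form template — a
diastolic baseline plus two Gaussian lobes (sharp systolic, slow diastolic)
— whose parameters are drawn from class-conditional Gaussian distributions.
A standardised mean shift delta on a template parameter therefore induces a
known separability: a linear feature of that parameter has binormal AUC
Phi(delta / sqrt(2)), which the trial pipeline must recover.

The templates mimic renal-artery waveform morphology well enough to
exercise upstroke-foot detection and all phase/slope features; they make no
claim to physiological realism beyond morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import biomarker_panel, panel_row
from .network import build_renal_tree
from .solver import MMHG, WaveformSet
from .trial import TrialDataset

__all__ = ["SurrogateSpec", "SurrogateCohort", "generate_surrogate", "surrogate_to_panel"]

LOCATIONS = ("main", "segmental", "interlobar", "arcuate")

#: one representative vessel id per renal generation in the template network
_LOCATION_VESSELS = {
    "main": "L_renal_main",
    "segmental": "L_renal_seg1",
    "interlobar": "L_renal_int11",
    "arcuate": "L_renal_arc111",
}

#: template parameter means: waveform = baseline + amp1*G(c1,w1) + amp2*G(c2,w2)
#: (times as fractions of the period); scale parameters for the derived
#: pressure/area/wave-speed series
DEFAULT_PARAMS = {
    "baseline": 0.20,  # m/s, diastolic velocity floor
    "amp1": 0.60,  # m/s, systolic lobe
    "c1": 0.22, "w1": 0.055,
    "amp2": 0.12,  # m/s, late-systolic lobe
    "c2": 0.42, "w2": 0.10,
    "p_dia": 75.0,  # mmHg
    "p_pulse": 40.0,  # mmHg
    "radius": 2.0e-3,  # m, reference lumen radius
    "area_mod": 0.05,  # fractional systolic area dilation
    "pwv0": 8.0,  # m/s
    "pwv_mod": 0.04,
}

#: default parameter coefficients of variation for the class-conditional draws
DEFAULT_CVS = {
    "baseline": 0.10, "amp1": 0.10, "c1": 0.03, "w1": 0.08,
    "amp2": 0.15, "c2": 0.03, "w2": 0.08,
    "p_dia": 0.05, "p_pulse": 0.10, "radius": 0.05,
    "area_mod": 0.10, "pwv0": 0.08, "pwv_mod": 0.10,
}


@dataclass(frozen=True)
class SurrogateSpec:
    """Specification of a two-class surrogate cohort (class 1 vs class 0)."""

    n_per_class: int = 100
    period: float = 0.8  # s
    n_samples: int = 200
    #: standardised mean shifts of class 1 relative to class 0, in units of
    #: each parameter's SD: {param: delta} applied at every location
    shifts: dict = field(default_factory=dict)
    #: optional per-location shifts {location: {param: delta}}
    location_shifts: dict = field(default_factory=dict)
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    cvs: dict = field(default_factory=lambda: dict(DEFAULT_CVS))
    noise_sd: float = 0.0  # additive waveform noise, fraction of the range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        for p in ("w1", "w2"):
            if self.params.get(p, DEFAULT_PARAMS[p]) <= 0:
                raise ValueError(f"template width {p} must be positive")


@dataclass
class SurrogateCohort:
    waves: list[dict[str, WaveformSet]]  # per subject: vessel id -> waveform
    labels: np.ndarray
    truth: pd.DataFrame  # drawn parameter values per subject/location
    network: object  # template renal fragment used for location mapping


def _template(t: np.ndarray, period: float, p: dict) -> np.ndarray:
    tau = t / period
    g1 = np.exp(-0.5 * ((tau - p["c1"]) / p["w1"]) ** 2)
    g2 = np.exp(-0.5 * ((tau - p["c2"]) / p["w2"]) ** 2)
    return p["baseline"] + p["amp1"] * g1 + p["amp2"] * g2


def generate_surrogate(spec: SurrogateSpec) -> SurrogateCohort:
    """Deterministically generate the surrogate cohort (seeded)."""
    rng = np.random.default_rng(spec.seed)
    net = build_renal_tree()
    t = np.arange(spec.n_samples) * spec.period / spec.n_samples
    waves: list[dict[str, WaveformSet]] = []
    labels = np.repeat([1, 0], spec.n_per_class)
    truth_rows = []
    for si, label in enumerate(labels):
        per_vessel: dict[str, WaveformSet] = {}
        for loc in LOCATIONS:
            draws = {}
            for name, mean in spec.params.items():
                sd = spec.cvs.get(name, 0.0) * abs(mean)
                delta = spec.shifts.get(name, 0.0)
                delta += spec.location_shifts.get(loc, {}).get(name, 0.0)
                mu = mean + (delta * sd if label == 1 else 0.0)
                draws[name] = rng.normal(mu, sd) if sd > 0 else mu
            shape = _template(t, spec.period, draws)
            if spec.noise_sd > 0:
                rng_noise = spec.noise_sd * (shape.max() - shape.min())
                shape = shape + rng.normal(0.0, rng_noise, size=shape.size)
            unit = (shape - draws["baseline"]) / max(draws["amp1"], 1e-9)
            velocity = shape
            pressure = (draws["p_dia"] + draws["p_pulse"] * unit) * MMHG
            area0 = np.pi * draws["radius"] ** 2
            area = area0 * (1.0 + draws["area_mod"] * unit)
            pwv = draws["pwv0"] * (1.0 + draws["pwv_mod"] * unit)
            flow = velocity * area
            per_vessel[_LOCATION_VESSELS[loc]] = WaveformSet(
                location=_LOCATION_VESSELS[loc],
                time=t.copy(),
                pressure=pressure,
                flow=flow,
                area=area,
                wave_speed=pwv,
            )
            truth_rows.append({"subject": si, "label": label, "location": loc, **draws})
        waves.append(per_vessel)
    return SurrogateCohort(
        waves=waves, labels=labels, truth=pd.DataFrame(truth_rows), network=net
    )


def surrogate_to_panel(cohort: SurrogateCohort) -> TrialDataset:
    """Run the real biomarker extraction on the surrogate waveforms and
    assemble the trial dataset (columns ``<location>.<name>``)."""
    rows = []
    for si, per_vessel in enumerate(cohort.waves):
        records = biomarker_panel(per_vessel, cohort.network, subject_id=str(si))
        rows.append(panel_row(records))
    X = pd.DataFrame(rows)
    return TrialDataset(X=X, y=cohort.labels)
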