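"""Waveform-derived candidate biomarkers.

From each one-cycle waveform Y(t) (renal blood flow rate, velocity,
pressure, pulse-wave speed or lumen area) five phase/slope features are
extracted:

* peak-systolic value Y_PS (global maximum),
* end-diastolic value Y_ED (value at the systolic-upstroke foot of the next
  cycle, the clinical end-diastole convention; a global-minimum mode is
  available for sensitivity checks),
* cycle mean Y_mean,
* systolic acceleration slope (Y_PS - Y_b) / (t_PS - t_b),
* diastolic deceleration slope (Y_PS - Y_ED) / (t_PS - t_ED),

where the upstroke foot (Y_b, t_b) is located by the intersecting-tangents
rule: the tangent at the steepest upstroke point intersected with the
diastolic baseline.  The velocity waveform additionally yields the Doppler
indices RI = (V_PSV - V_EDV)/V_PSV and PI = (V_PSV - V_EDV)/V_Mean.

Biomarker names follow the "<Phase|Slope> <Quantity>" convention
("Systolic RBF Rate", "Deceleration Pressure", ...), plus "RI" and "PI".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ArterialNetwork, RENAL_GENERATIONS
from .solver import WaveformSet

__all__ = [
    "PhaseFeatures",
    "BiomarkerRecord",
    "QUANTITIES",
    "FEATURES",
    "PANEL_NAMES",
    "COMMON_PANEL_NAMES",
    "phase_features",
    "resistive_index",
    "pulsatility_index",
    "systolic_acceleration_slope",
    "diastolic_deceleration_slope",
    "biomarker_panel",
    "panel_row",
]

#: waveform quantities entering the panel, with their WaveformSet accessors
QUANTITIES = {
    "RBF Rate": "flow",
    "Velocity": "velocity",
    "Pressure": "pressure",
    "PWV": "wave_speed",
    "Area": "area",
}
FEATURES = ("Systolic", "Diastolic", "Mean", "Acceleration", "Deceleration")

#: the full per-location vocabulary (5 x 5 + RI + PI = 27 names)
PANEL_NAMES = tuple(
    f"{feat} {qty}" for qty in QUANTITIES for feat in FEATURES
) + ("RI", "PI")

#: the clinically accessible subset: pressure- and PWV-derived markers
#: excluded (area retained)
COMMON_PANEL_NAMES = tuple(
    n for n in PANEL_NAMES if "Pressure" not in n and "PWV" not in n
)


@dataclass(frozen=True)
class PhaseFeatures:
    """Phase landmarks of a one-cycle waveform (times in seconds from the
    cycle start; t_ED may exceed the period: it marks the next upstroke)."""

    Y_PS: float
    Y_ED: float
    Y_b: float
    Y_mean: float
    t_PS: float
    t_ED: float
    t_b: float

    @property
    def has_upstroke(self) -> bool:
        return math.isfinite(self.t_b)


def phase_features(
    series: np.ndarray,
    period: float,
    ed_mode: str = "foot",
) -> PhaseFeatures:
    """Extract phase features from a uniformly sampled one-cycle series.

    ``ed_mode`` selects the end-diastole convention: ``"foot"`` (value at the
    upstroke foot of the next cycle) or ``"min"`` (global minimum).
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 50:
        raise ValueError(f"need >= 50 samples per cycle, got {n}")
    dt = period / n
    t = np.arange(n) * dt

    ip = int(np.argmax(y))
    y_ps = float(y[ip])
    t_ps = float(t[ip])
    y_mean = float(y.mean())  # uniform periodic sampling: trapezoidal mean
    y_min = float(y.min())

    if y_ps - y_min <= 1e-12 * max(abs(y_ps), 1.0):
        # flat series: no identifiable upstroke
        return PhaseFeatures(y_ps, y_ps, y_ps, y_mean, t_ps, math.nan, math.nan)

    # roll the cycle so the peak sits at one quarter: the upstroke then lies
    # in the first quarter and the preceding diastole at the left edge
    shift = (n // 4) - ip
    yr = np.roll(y, shift)
    dy = (np.roll(yr, -1) - np.roll(yr, 1)) / (2.0 * dt)  # periodic derivative
    up = slice(0, n // 4 + 1)
    i_d = int(np.argmax(dy[up]))
    slope = float(dy[i_d])
    if slope <= 0:
        return PhaseFeatures(y_ps, y_ps, y_ps, y_mean, t_ps, math.nan, math.nan)

    baseline = float(yr[: n // 4 + 1].min()) if ed_mode == "foot" else y_min
    baseline = min(baseline, float(yr[i_d]))
    # intersecting tangents: steepest-ascent tangent meets the baseline
    t_b_roll = i_d * dt - (float(yr[i_d]) - baseline) / slope
    t_b = (t_b_roll - shift * dt) % period
    y_b = baseline

    if ed_mode == "min":
        i_min = int(np.argmin(y))
        y_ed, t_ed = y_min, float(t[i_min])
    else:
        # end-diastole: the waveform value at the next cycle's upstroke foot
        y_ed = float(np.interp(t_b, t, y, period=period))
        t_ed = t_b
    if t_ed <= t_ps:
        t_ed += period
    if t_b > t_ps:
        t_b -= period
    return PhaseFeatures(y_ps, y_ed, y_b, y_mean, t_ps, t_ed, t_b)


def resistive_index(v_psv: float, v_edv: float) -> float:
    """Doppler resistive index (V_PSV - V_EDV) / V_PSV."""
    if v_psv <= 0:
        raise ValueError("peak systolic velocity must be positive")
    return (v_psv - v_edv) / v_psv


def pulsatility_index(v_psv: float, v_edv: float, v_mean: float) -> float:
    """Doppler pulsatility index (V_PSV - V_EDV) / V_Mean."""
    if v_mean <= 0:
        raise ValueError("mean velocity must be positive")
    return (v_psv - v_edv) / v_mean


def systolic_acceleration_slope(f: PhaseFeatures) -> float:
    """(Y_PS - Y_b) / (t_PS - t_b); undefined (nan) without an upstroke."""
    if not f.has_upstroke:
        return math.nan
    if f.t_PS == f.t_b:
        raise ValueError("t_PS equals t_b; slope undefined")
    return (f.Y_PS - f.Y_b) / (f.t_PS - f.t_b)


def diastolic_deceleration_slope(f: PhaseFeatures) -> float:
    """(Y_PS - Y_ED) / (t_PS - t_ED); negative for a decaying waveform."""
    if not math.isfinite(f.t_ED):
        return math.nan
    if f.t_ED == f.t_PS:
        raise ValueError("t_ED equals t_PS; slope undefined")
    return (f.Y_PS - f.Y_ED) / (f.t_PS - f.t_ED)


@dataclass(frozen=True)
class BiomarkerRecord:
    subject_id: str
    side: str  # left | right
    location: str  # main | segmental | interlobar | arcuate
    name: str  # from PANEL_NAMES
    value: float


def _features_for(series: np.ndarray, period: float, ed_mode: str) -> dict[str, float]:
    f = phase_features(series, period, ed_mode=ed_mode)
    return {
        "Systolic": f.Y_PS,
        "Diastolic": f.Y_ED,
        "Mean": f.Y_mean,
        "Acceleration": systolic_acceleration_slope(f) if f.has_upstroke else 0.0,
        "Deceleration": diastolic_deceleration_slope(f) if f.has_upstroke else 0.0,
        "_V_PSV": f.Y_PS,
        "_V_EDV": f.Y_ED,
        "_V_Mean": f.Y_mean,
    }


def biomarker_panel(
    waves: dict[str, WaveformSet],
    network: ArterialNetwork,
    subject_id: str = "",
    ed_mode: str = "foot",
) -> list[BiomarkerRecord]:
    """Extract the full candidate-biomarker panel from per-vessel waveforms.

    Waveforms are averaged across the vessels of each renal generation and
    side before feature extraction (the clinical per-location convention,
    e.g. the resistive index averaged across segmental arteries); one record
    per (side, location, name).
    """
    groups: dict[tuple[str, str], list[WaveformSet]] = {}
    for vid, w in waves.items():
        v = network.vessels.get(vid)
        if v is None or not v.group.startswith("renal") or v.generation is None:
            continue
        side = v.group.removeprefix("renal_")
        groups.setdefault((side, v.generation), []).append(w)
    sides = {side for side, _ in groups}
    for side in sides:
        missing = [g for g in RENAL_GENERATIONS if (side, g) not in groups]
        if missing:
            raise ValueError(f"missing renal generations on side {side!r}: {missing}")

    records: list[BiomarkerRecord] = []
    for (side, gen), wlist in sorted(groups.items()):
        period = wlist[0].period
        mean_of = {
            qty: np.mean([getattr(w, attr) for w in wlist], axis=0)
            for qty, attr in QUANTITIES.items()
        }
        feats = {
            qty: _features_for(series, period, ed_mode)
            for qty, series in mean_of.items()
        }
        for qty in QUANTITIES:
            for feat in FEATURES:
                records.append(
                    BiomarkerRecord(subject_id, side, gen, f"{feat} {qty}",
                                    float(feats[qty][feat]))
                )
        v = feats["Velocity"]
        records.append(
            BiomarkerRecord(subject_id, side, gen, "RI",
                            resistive_index(v["_V_PSV"], v["_V_EDV"]))
        )
        records.append(
            BiomarkerRecord(subject_id, side, gen, "PI",
                            pulsatility_index(v["_V_PSV"], v["_V_EDV"], v["_V_Mean"]))
        )
    return records


def panel_row(records: list[BiomarkerRecord]) -> dict[str, float]:
    """Collapse per-side records to a per-subject wide row: columns
    ``<location>.<name>`` hold the left/right mean (the default used by the
    trial analyses)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    out: dict[str, float] = {}
    for (loc, name), grp in df.groupby(["location", "name"]):
        out[f"{loc}.{name}"] = float(grp["value"].mean())
    return out
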