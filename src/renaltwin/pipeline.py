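"""End-to-end virtual-trial orchestration.

Stages: healthy candidate generation -> per-subject 1D simulation ->
physiological filtering (brachial SBP/DBP within 2.575 reference SDs,
segmental RI within its normal range) -> deterministic disease scaling of
every retained subject into DM+HTN, DKD and HKD counterparts -> biomarker
panels -> univariate screen, correlation structure and biomarker-combination
evaluation for DKD-vs-HKD classification.

The kidney's glomerular filtration rate is evaluated by one-way coupling:
each converged subject's cycle-mean arcuate pressures drive the 0D
microvascular bed solve (with the disease-specific bed edits: uniform
DM+HTN constriction, diabetic arteriolar dilation/constriction plus 57%
nephron loss, hypertensive interlobular constriction).

Everything is deterministic given (config, seed); the cohort manifest and
result tables are written as CSV under a run directory together with a JSON
manifest recording the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import microcirculation as mc
from . import population as pop
from .network import ArterialNetwork
from .reference import build_full_reference
from .solver import MMHG, NumericsConfig, SolverError, simulate_subject
from .trial import TrialDataset, repeated_holdout, univariate_screen, correlation_matrix

__all__ = [
    "TrialConfig",
    "TrialRun",
    "run_trial",
    "run_subject",
    "percentage_difference",
    "validation_report",
]


def percentage_difference(predicted: float, reference: float) -> float:
    """Absolute difference divided by the mean of the two values, as a
    percentage."""
    mean = 0.5 * (predicted + reference)
    if mean == 0:
        raise ValueError("undefined percentage difference for zero mean")
    return abs(predicted - reference) / abs(mean) * 100.0


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one virtual trial (defaults: the desk-scale study
    cell, 50-59-year-old males)."""

    sexes: tuple[str, ...] = ("male",)
    age_groups: tuple[str, ...] = ("50-59",)
    n_per_group: int = 200
    seed: int = 7
    diseases: tuple[str, ...] = ("dm_htn", "dm_htn_dkd", "dm_htn_hkd")
    # numerics (coarse acceptance grid)
    target_dx: float = 0.013
    cfl: float = 0.9
    min_cells: int = 2
    u_margin: float = 1.2
    heart_rate: float = 75.0
    max_cycles: int = 16
    periodicity_tol: float = 1.0e-3
    # filter
    filter_sbp_sd: float = 1.9  # mmHg
    filter_dbp_sd: float = 1.4  # mmHg
    filter_z: float = 2.575
    ri_interval: tuple[float, float] = (0.47, 0.80)
    # microcirculation / disease
    venous_pressure_mmHg: float = 5.0
    dkd_afferent_scale: float = 1.10
    dkd_efferent_scale: float = 0.93
    dkd_surviving_fraction: float = 0.43
    hkd_interlobular_pvr_ratio: float = 1.10
    # trial statistics
    holdout_iters: int = 50
    train_frac: float = 0.70

    def numerics(self) -> NumericsConfig:
        return NumericsConfig(
            target_dx=self.target_dx,
            cfl=self.cfl,
            min_cells=self.min_cells,
            u_margin=self.u_margin,
            heart_rate=self.heart_rate,
            max_cycles=self.max_cycles,
            periodicity_tol=self.periodicity_tol,
            venous_pressure=self.venous_pressure_mmHg * MMHG,
        )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        """Load a trial configuration from a YAML mapping of field names."""
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown trial config keys: {sorted(unknown)}")
        for key in ("sexes", "age_groups", "diseases", "ri_interval"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _record_locations(network: ArterialNetwork) -> list[str]:
    locs = [v.id for v in network.renal_vessels()]
    locs += ["r_brachial_b", network.inlet_vessel]
    return [l for l in locs if l in network.vessels]


def _segmental_ri(waves, network: ArterialNetwork) -> float:
    """Mean RI across the ten segmental renal arteries (per-vessel RI of the
    velocity waveform, averaged)."""
    ris = []
    for v in network.renal_vessels("segmental"):
        w = waves.get(v.id)
        if w is None:
            continue
        f = bm.phase_features(w.velocity, w.period)
        ris.append(bm.resistive_index(f.Y_PS, f.Y_ED))
    return float(np.mean(ris))


def _disease_bed(
    bed: mc.MicrovascularBed, disease: str, cfg: TrialConfig, pvr_factor_dmhtn: float
) -> mc.MicrovascularBed:
    """Mechanistic microvascular bed for the GFR evaluation of one disease
    state, built from the subject's (jittered) healthy bed."""
    if disease == "healthy":
        return bed
    if disease == "dm_htn":
        return pop._bed_with_pvr(bed, pvr_factor_dmhtn, 1.0)
    if disease == "dm_htn_dkd":
        edited = mc.apply_dkd_arterioles(
            bed, cfg.dkd_afferent_scale, cfg.dkd_efferent_scale
        )
        return mc.apply_nephron_loss(edited, cfg.dkd_surviving_fraction)
    if disease == "dm_htn_hkd":
        base = pop._bed_with_pvr(bed, pvr_factor_dmhtn, 1.0)
        s = mc.solve_hkd_interlobular_scale(base, cfg.hkd_interlobular_pvr_ratio)
        return dataclasses.replace(
            base, interlobular_resistance=base.interlobular_resistance * s**-4
        )
    raise ValueError(f"unknown disease state {disease!r}")


def _subject_gfr(
    waves,
    healthy_net: ArterialNetwork,
    subject: pop.SubjectParameters,
    cfg: TrialConfig,
) -> float:
    """One-way coupled GFR [ml/min]: cycle-mean arcuate pressures drive the
    disease-edited 0D beds."""
    pv = cfg.venous_pressure_mmHg * MMHG
    dmhtn_pvr = pop.DEFAULT_DISEASE_FACTORS["dm_htn"]["renal"]["pvr"]
    total = 0.0
    for tid, bed in healthy_net.beds().items():
        w = waves.get(tid)
        if w is None:
            continue
        jitter = subject.terminal_jitter.get("pvr", {}).get(tid, 1.0)
        bed_j = pop._bed_with_pvr(bed, jitter, 1.0)
        bed_d = _disease_bed(bed_j, subject.disease_state, cfg, dmhtn_pvr)
        p_in = float(w.pressure.mean())
        if p_in <= pv:
            continue
        total += mc.solve_bed(bed_d, p_in, pv).gfr
    return total


def run_subject(
    network: ArterialNetwork,
    subject: pop.SubjectParameters,
    cfg: TrialConfig,
    extract_panel: bool = True,
    init_state=None,
    return_state: bool = False,
):
    """Simulate one subject and summarise it.

    Returns (summary dict, panel row dict or None).  The summary carries the
    quantities the filter and the validation report need (brachial SBP/DBP,
    segmental RI, renal blood flow, GFR, convergence diagnostics).
    """
    net_s = pop.materialize_subject(network, subject)
    numerics = cfg.numerics()
    out = simulate_subject(
        net_s,
        numerics=numerics,
        viscosity=subject.viscosity,
        cardiac_output=subject.cardiac_output,
        record=_record_locations(net_s),
        init_state=init_state,
        return_state=return_state,
    )
    waves, state = out if return_state else (out, None)
    wb = waves["r_brachial_b"]
    mains = [v.id for v in net_s.renal_vessels("main")]
    rbf = sum(float(waves[m].flow.mean()) for m in mains) * 6.0e7  # ml/min
    summary = {
        "subject_id": subject.subject_id,
        "sex": subject.sex,
        "age_group": subject.age_group,
        "disease": subject.disease_state,
        "seed": subject.seed,
        "SBP": float(wb.pressure.max()) / MMHG,
        "DBP": float(wb.pressure.min()) / MMHG,
        "RI": _segmental_ri(waves, net_s),
        "RBF": rbf,
        "GFR": _subject_gfr(waves, net_s, subject, cfg),
    }
    panel = None
    if extract_panel:
        records = bm.biomarker_panel(waves, net_s, subject_id=subject.subject_id)
        panel = bm.panel_row(records)
    if return_state:
        return summary, panel, state
    return summary, panel


@dataclass
class TrialRun:
    """All tables produced by one virtual trial."""

    config: TrialConfig
    manifest: pd.DataFrame  # one row per simulated subject (all states)
    panels: pd.DataFrame  # biomarker rows, indexed like the manifest
    inclusion_rate: float
    dataset: TrialDataset | None  # DKD vs HKD, all locations
    univariate: pd.DataFrame | None
    correlation: pd.DataFrame | None
    evaluations: pd.DataFrame | None  # named biomarker-set performances
    timing: dict = field(default_factory=dict)

    def group_mean(self, disease: str, column: str) -> float:
        sel = self.manifest[(self.manifest["disease"] == disease) & self.manifest["kept"]]
        return float(sel[column].mean())


#: headline biomarker sets evaluated on the DKD/HKD cohort (main renal artery)
NAMED_SETS = {
    "PI": ("main.PI",),
    "PI+RI": ("main.PI", "main.RI"),
    "flow_triplet": (
        "main.Mean RBF Rate", "main.Systolic RBF Rate", "main.Diastolic RBF Rate"
    ),
}


def run_trial(
    config: TrialConfig,
    out_dir: str | Path | None = None,
    network: ArterialNetwork | None = None,
    progress: bool = False,
) -> TrialRun:
    """Run the full virtual trial (see module docstring).  With ``out_dir``
    the manifest, panels and result tables are written as CSV plus a JSON
    run manifest; an existing run with the same config hash is reused."""
    t0 = time.time()
    if out_dir is not None:
        out_dir = Path(out_dir)
        meta_p = out_dir / "run_manifest.json"
        if meta_p.exists():
            meta = json.loads(meta_p.read_text())
            if meta.get("config_hash") == config.config_hash():
                return _load_run(config, out_dir)
    net = network if network is not None else build_full_reference()

    candidates = pop.generate_cohort(
        net, config.n_per_group, config.seed,
        sexes=config.sexes, age_groups=config.age_groups,
    )
    # per-cell filter references: the deterministic reference subject's own
    # simulated brachial pressures
    criteria: dict[tuple[str, str], pop.FilterCriteria] = {}
    for sex in config.sexes:
        for age in config.age_groups:
            ref = pop.build_reference_subject(sex, age)
            summ, _ = run_subject(net, ref, config, extract_panel=False)
            criteria[(sex, age)] = pop.FilterCriteria(
                sbp_mean=summ["SBP"],
                dbp_mean=summ["DBP"],
                sbp_sd=config.filter_sbp_sd,
                dbp_sd=config.filter_dbp_sd,
                z_threshold=config.filter_z,
                ri_interval=config.ri_interval,
            )

    rows, panel_rows = [], []
    n_kept = 0
    for i, subj in enumerate(candidates):
        try:
            summ, _, state = run_subject(
                net, subj, config, extract_panel=False, return_state=True
            )
        except SolverError as exc:
            summ = {
                "subject_id": subj.subject_id, "sex": subj.sex,
                "age_group": subj.age_group, "disease": "healthy",
                "seed": subj.seed, "SBP": np.nan, "DBP": np.nan,
                "RI": np.nan, "RBF": np.nan, "GFR": np.nan,
            }
            summ.update(kept=False, reasons=f"solver: {exc}")
            rows.append(summ)
            continue
        keep, reasons = pop.physiological_filter(
            summ, criteria[(subj.sex, subj.age_group)]
        )
        summ.update(kept=keep, reasons=";".join(reasons))
        rows.append(summ)
        if not keep:
            continue
        n_kept += 1
        for disease in config.diseases:
            counterpart = subj
            if disease != "dm_htn":
                counterpart = pop.apply_disease(subj, "dm_htn")
                counterpart = pop.apply_disease(counterpart, disease)
            else:
                counterpart = pop.apply_disease(subj, "dm_htn")
            dsumm, dpanel = run_subject(net, counterpart, config, extract_panel=True)
            dsumm.update(kept=True, reasons="")
            rows.append(dsumm)
            dpanel["subject_id"] = dsumm["subject_id"]
            dpanel["disease"] = disease
            panel_rows.append(dpanel)
        if progress and (i + 1) % 25 == 0:
            print(f"  {i + 1}/{len(candidates)} candidates, {n_kept} kept", flush=True)

    manifest = pd.DataFrame(rows)
    panels = pd.DataFrame(panel_rows)
    healthy = manifest[manifest["disease"] == "healthy"]
    inclusion = float(healthy["kept"].mean()) if len(healthy) else float("nan")

    dataset = univariate = corr = evals = None
    if n_kept >= 4 and {"dm_htn_dkd", "dm_htn_hkd"} <= set(config.diseases):
        dkd = panels[panels["disease"] == "dm_htn_dkd"]
        hkd = panels[panels["disease"] == "dm_htn_hkd"]
        feat_cols = [c for c in panels.columns if c not in ("subject_id", "disease")]
        X = pd.concat([dkd[feat_cols], hkd[feat_cols]], ignore_index=True)
        y = np.concatenate([np.ones(len(dkd), int), np.zeros(len(hkd), int)])
        dataset = TrialDataset(X=X, y=y)
        univariate = univariate_screen(
            dataset, n_iter=config.holdout_iters, seed=config.seed
        )
        main_cols = [c for c in X.columns if c.startswith("main.")]
        corr, _ = correlation_matrix(TrialDataset(X=dataset.X[main_cols], y=dataset.y))
        ev_rows = []
        for name, cols in NAMED_SETS.items():
            ev = repeated_holdout(
                dataset, cols, n_iter=config.holdout_iters,
                train_frac=config.train_frac, seed=config.seed,
            )
            ev_rows.append(
                {"set": name, "biomarkers": "+".join(cols),
                 "auc": ev.mean_auc, "accuracy": ev.mean_accuracy}
            )
        evals = pd.DataFrame(ev_rows)

    run = TrialRun(
        config=config,
        manifest=manifest,
        panels=panels,
        inclusion_rate=inclusion,
        dataset=dataset,
        univariate=univariate,
        correlation=corr,
        evaluations=evals,
        timing={"total_s": time.time() - t0, "n_candidates": len(candidates),
                "n_kept": n_kept},
    )
    if out_dir is not None:
        _write_run(run, out_dir)
    return run


def _write_run(run: TrialRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    run.manifest.to_csv(out_dir / "cohort_manifest.csv", index=False)
    run.panels.to_csv(out_dir / "biomarker_panels.csv", index=False)
    if run.univariate is not None:
        run.univariate.to_csv(out_dir / "univariate_auc.csv")
    if run.correlation is not None:
        run.correlation.to_csv(out_dir / "correlation_main.csv")
    if run.evaluations is not None:
        run.evaluations.to_csv(out_dir / "named_set_performance.csv", index=False)
    meta = {
        "config_hash": run.config.config_hash(),
        "config": dataclasses.asdict(run.config),
        "inclusion_rate": run.inclusion_rate,
        "timing": run.timing,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(meta, indent=2, default=str))


def _load_run(config: TrialConfig, out_dir: Path) -> TrialRun:
    manifest = pd.read_csv(out_dir / "cohort_manifest.csv", keep_default_na=True)
    manifest["reasons"] = manifest.get("reasons", "").fillna("")
    try:
        panels = pd.read_csv(out_dir / "biomarker_panels.csv")
    except pd.errors.EmptyDataError:
        panels = pd.DataFrame()
    meta = json.loads((out_dir / "run_manifest.json").read_text())
    dataset = univariate = corr = evals = None
    if (out_dir / "univariate_auc.csv").exists():
        univariate = pd.read_csv(out_dir / "univariate_auc.csv", index_col=0)
    if (out_dir / "correlation_main.csv").exists():
        corr = pd.read_csv(out_dir / "correlation_main.csv", index_col=0)
    if (out_dir / "named_set_performance.csv").exists():
        evals = pd.read_csv(out_dir / "named_set_performance.csv")
    if len(panels):
        dkd = panels[panels["disease"] == "dm_htn_dkd"]
        hkd = panels[panels["disease"] == "dm_htn_hkd"]
        feat_cols = [c for c in panels.columns if c not in ("subject_id", "disease")]
        if len(dkd) and len(hkd):
            X = pd.concat([dkd[feat_cols], hkd[feat_cols]], ignore_index=True)
            y = np.concatenate([np.ones(len(dkd), int), np.zeros(len(hkd), int)])
            dataset = TrialDataset(X=X, y=y)
    healthy = manifest[manifest["disease"] == "healthy"]
    return TrialRun(
        config=config,
        manifest=manifest,
        panels=panels,
        inclusion_rate=float(healthy["kept"].mean()) if len(healthy) else float("nan"),
        dataset=dataset,
        univariate=univariate,
        correlation=corr,
        evaluations=evals,
        timing=meta.get("timing", {}),
    )


def validation_report(
    manifest: pd.DataFrame, reference_ranges: dict
) -> pd.DataFrame:
    """Compare cohort-level means against literature reference values.

    ``reference_ranges`` maps (disease, column) -> reference value, e.g.
    ``{("healthy", "RI"): 0.63}``.  The report lists model mean, reference
    and their percentage difference."""
    rows = []
    for (disease, column), ref in reference_ranges.items():
        sel = manifest[(manifest["disease"] == disease) & manifest["kept"]]
        if not len(sel):
            continue
        model = float(sel[column].mean())
        rows.append(
            {"disease": disease, "quantity": column, "model": model,
             "reference": ref, "pct_difference": percentage_difference(model, ref)}
        )
    return pd.DataFrame(rows)
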