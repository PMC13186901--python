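"""Run the scaled-down virtual trial and write every result table.

The acceptance configuration: 256 healthy candidates in the 50-59-year-old
male cell, filtered at the 2.575-SD brachial-pressure / RI window, each
retained subject scaled into its DM+HTN, DKD and HKD counterparts.  Output
under results/trial/: the cohort manifest (pressures, RI, RBF, GFR, filter
outcome per subject), the biomarker panels, the DKD-vs-HKD univariate AUC
screen per renal generation, the main-artery correlation matrix, and the
named headline biomarker sets.

Run as:  python analysis/03_virtual_trial.py [seed]
"""

import sys
from pathlib import Path

from renaltwin.pipeline import TrialConfig, run_trial

OUT = Path(__file__).resolve().parents[1] / "results" / "trial"


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 11
    cfg = TrialConfig(n_per_group=256, seed=seed)
    run = run_trial(cfg, out_dir=OUT, progress=True)
    m = run.manifest
    print(f"\ninclusion rate: {run.inclusion_rate:.3f} "
          f"({int(run.timing.get('n_kept', 0))} kept)")
    for d in ("healthy", "dm_htn", "dm_htn_dkd", "dm_htn_hkd"):
        sel = m[(m["disease"] == d) & m["kept"]]
        if len(sel):
            print(f"{d:11s} RI {sel['RI'].mean():.3f} ({sel['RI'].std():.3f})  "
                  f"RBF {sel['RBF'].mean():6.0f}  GFR {sel['GFR'].mean():5.1f} "
                  f"({sel['GFR'].std():.1f})")
    if run.evaluations is not None:
        print("\nheadline biomarker sets (DKD vs HKD):")
        print(run.evaluations.round(3).to_string(index=False))
    if run.univariate is not None:
        cols = [c for c in ("PI", "RI", "Mean RBF Rate", "Diastolic Velocity",
                            "Diastolic PWV", "Diastolic Pressure", "Diastolic Area")
                if c in run.univariate.columns]
        print("\nunivariate AUC by renal generation:")
        print(run.univariate[cols].round(3).to_string())


if __name__ == "__main__":
    main()
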