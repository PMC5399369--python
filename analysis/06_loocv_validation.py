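"""Validate the three models by leave-one-out cross-validation.

Each subject is predicted from coefficients refit on the other 79 (term
sets fixed); performance is RMSE and the Pearson correlation between
predicted and actual MDS-UPDRS.  Writes loocv_{A,B,C}.tsv,
loocv_summary.tsv and actual-vs-predicted scatter plots (SVG).
"""

import importlib
from pathlib import Path

import pandas as pd

sim = importlib.import_module("01_simulate_cohort")
from pdig.pipeline import run_pipeline

OUT = Path("results/pipeline")

if __name__ == "__main__":
    cfg = sim.config(
        ("simulate", "qc", "connectome", "association", "modeling", "validate")
    )
    cfg.make_plots = True
    run_pipeline(cfg, cache=True)
    summary = pd.read_csv(OUT / "loocv_summary.tsv", sep="\t", index_col=0)
    print("leave-one-out cross-validation (80 folds):")
    print(summary.round(3))
    best = summary.rmse.idxmin()
    print(f"\nlowest prediction error: model {best} "
          f"(RMSE {summary.loc[best, 'rmse']:.2f}, r = {summary.loc[best, 'pearson_r']:.3f})")
    print(f"scatter plots: {OUT}/loocv_A.svg, loocv_B.svg, loocv_C.svg")
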