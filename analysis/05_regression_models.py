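"""Fit the three MDS-UPDRS regression models by backward stepwise search.

Model A uses imaging features (significant-node DC), model B genetic
features (scan-selected SNPs), model C both, each with clinical
covariates and capped two-way interactions.  Reports adjusted R^2 and the
sequential (Type-I) variance decomposition per retained term.  Writes
model_{A,B,C}_{anova,coef,summary} files and model_comparison.tsv.
"""

import importlib
import json
from pathlib import Path

import pandas as pd

sim = importlib.import_module("01_simulate_cohort")
from pdig.pipeline import run_pipeline

OUT = Path("results/pipeline")

if __name__ == "__main__":
    run_pipeline(
        sim.config(("simulate", "qc", "connectome", "association", "modeling")),
        cache=True,
    )
    comparison = pd.read_csv(OUT / "model_comparison.tsv", sep="\t", index_col=0)
    print("model comparison (adjusted R^2, total percent explained):")
    print(comparison[["n_terms", "adj_r2", "pct_explained_total"]].round(3))
    best = comparison.adj_r2.idxmax()
    print(f"\nbest model: {best} (adj R^2 = {comparison.loc[best, 'adj_r2']:.3f})")
    anova = pd.read_csv(OUT / f"model_{best}_anova.tsv", sep="\t", index_col=0)
    print(f"\nmodel {best} sequential ANOVA (term, SS, F, p, pct explained):")
    print(anova.round(4).to_string())
    summary = json.loads((OUT / f"model_{best}_summary.json").read_text())
    print(f"\nstepwise removed {len(summary['stepwise_trace'])} terms from the initial set")
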