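"""Generate the synthetic imaging-genetics cohort.

Simulates 40 healthy controls and 40 Parkinson's disease patients:
demographics/clinical covariates, the 12-SNP candidate panel, streamline
tables realizing the CBGT degree-centrality group contrasts, and
MDS-UPDRS scores from the declared ground-truth model.  Writes
subjects.tsv, streamlines.tsv, genotypes.{ped,map}, truth.json under
results/pipeline/.
"""

import sys
from pathlib import Path

import pandas as pd

from pdig.pipeline import PipelineConfig, run_pipeline

OUT = Path("results/pipeline")


def config(stages_on: tuple[str, ...]) -> PipelineConfig:
    cfg = PipelineConfig(out_dir=str(OUT), seed=int(sys.argv[1]) if len(sys.argv) > 1 else 0)
    cfg.stages = {name: name in stages_on for name in cfg.stages}
    return cfg


if __name__ == "__main__":
    run_pipeline(config(("simulate",)), cache=True)
    subjects = pd.read_csv(OUT / "subjects.tsv", sep="\t", index_col=0)
    print(f"cohort: {len(subjects)} subjects "
          f"({(subjects.group == 'HC').sum()} HC / {(subjects.group == 'PD').sum()} PD)")
    print(f"age: HC {subjects[subjects.group == 'HC'].age.mean():.1f} vs "
          f"PD {subjects[subjects.group == 'PD'].age.mean():.1f} years (matched)")
    print(f"MDS-UPDRS mean {subjects.MDS_UPDRS.mean():.1f}, sd {subjects.MDS_UPDRS.std():.1f}")
    print(f"outputs in {OUT}/")
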