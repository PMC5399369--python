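"""Genotype quality control and population-structure check.

Applies the MAF < 1% / exact-HWE p < 1e-6 / missingness > 5% filters to
the simulated panel and embeds subjects by classical MDS of the
identity-by-state distance matrix.  Writes qc_report.json, qc_excluded.tsv
and mds_coordinates.tsv under results/pipeline/.
"""

import importlib
import json
from pathlib import Path

sim = importlib.import_module("01_simulate_cohort")
from pdig.pipeline import run_pipeline

OUT = Path("results/pipeline")

if __name__ == "__main__":
    run_pipeline(sim.config(("simulate", "qc")), cache=True)
    report = json.loads((OUT / "qc_report.json").read_text())
    c = report["counts"]
    print(f"QC thresholds: MAF >= {report['thresholds']['maf_min']}, "
          f"HWE p >= {report['thresholds']['hwe_min_p']}, "
          f"missing <= {report['thresholds']['miss_max']}")
    print(f"removed {c['removed']} of {c['removed'] + c['retained']} SNPs "
          f"(maf {c['maf']}, hwe {c['hwe']}, missing {c['missing']}; "
          "marginal counts, union removed once)")
    print(f"retained {c['retained']} SNPs; MDS coordinates in mds_coordinates.tsv")
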