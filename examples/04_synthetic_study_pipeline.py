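"""Full pipeline on a small synthetic study.

Generates a study-shaped fixture (3 treatments, mixture of neutral and
niche-assembled samples), runs fits, exact tests and group statistics, and
prints the verdict table and the confusion of verdicts against ground truth.
"""

import tempfile
from pathlib import Path

import pandas as pd

from hubbell import FixtureSpec, Treatment
from hubbell.pipeline import RunConfig, run_pipeline
from hubbell.synthetic import write_fixture

workdir = Path(tempfile.mkdtemp(prefix="hubbell_demo_"))
spec = FixtureSpec(
    n_per_treatment={Treatment.HEALTHY: 5, Treatment.BOP: 5, Treatment.NON_BOP: 5},
    J_range=(300, 1200),
    neutral_fraction=0.4,
    seed=11,
)
shared, tmap, truth_path = write_fixture(spec, workdir / "fixture")
result = run_pipeline(RunConfig(
    otu_path=str(shared), treatment_path=str(tmap), otu_format="shared",
    formula="etienne", n_sims=50, seed=9, outdir=str(workdir / "out"),
))

verdicts = pd.read_csv(result.files["verdicts_etienne_50"], sep="\t")
truth = pd.read_csv(truth_path, sep="\t")
merged = verdicts.merge(truth[["sample_id", "generator"]], on="sample_id")
print(merged[["sample_id", "J", "S", "theta", "m", "p_value",
              "p_value_adjusted", "passes", "generator"]].to_string(index=False))

xtab = pd.crosstab(merged["generator"], merged["passes"])
print("\nverdict vs ground truth (rows: generating model):")
print(xtab.to_string())
print("\nNeutral samples should mostly pass (p_adj > 0.05); lognormal niche "
      "samples are rejected when their abundance distribution is more regular "
      "than neutral demographic noise allows (power grows with read depth).")
print(f"\nreports written under {workdir / 'out'}")
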