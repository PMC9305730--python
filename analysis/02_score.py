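"""Score the cohort: complete-case filter, standardised dimension scores,
utility index and per-dimension internal consistency (Cronbach's alpha).

Reads results/cohort/, writes results/scores.csv and results/alpha.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from _util import add_src_to_path  # noqa: F401

from qolclasses.metadata import DIMENSIONS, aqol_metadata
from qolclasses.responses import complete_case_filter, read_items_csv
from qolclasses.scoring import cronbach_alpha, score_cohort
from qolclasses.synthetic import load_profile

parser = argparse.ArgumentParser()
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

items = read_items_csv(args.cohort_dir / "items.csv", aqol_metadata())
complete, report = complete_case_filter(items)
print(f"complete cases: {report.n_retained}/{report.n_input} "
      f"(dropped {report.n_dropped})")

spec = load_profile("aqol_paper_profile").utility
scores = score_cohort(complete, spec)
out = scores.standardised.copy()
out["utility"] = scores.utility
out.to_csv(args.out_dir / "scores.csv")

alpha = pd.Series(
    {d: cronbach_alpha(complete, d) for d in DIMENSIONS}, name="cronbach_alpha"
)
alpha.to_csv(args.out_dir / "alpha.csv")
print("mean standardised dimension scores (0 worst .. 100 best):")
print(scores.standardised.mean().round(1).to_string())
print(f"mean utility: {scores.utility.mean():.3f}")
print("Cronbach's alpha by dimension:")
print(alpha.round(2).to_string())
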