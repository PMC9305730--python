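"""Choose the number of latent classes by three cross-validation schemes.

Runs 10-fold, leave-one-site-out and split-half CV over K = 1..6, writes
the CV table and per-scheme selections under results/selection/, and runs
the k-means-on-principal-components sensitivity check against the selected
model's classes.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from _util import add_src_to_path  # noqa: F401

from qolclasses.lca import classify_modal, fit_em
from qolclasses.metadata import aqol_metadata
from qolclasses.responses import complete_case_filter, read_items_csv
from qolclasses.selection import (
    cross_validate,
    kmeans_pca_sensitivity,
    make_folds,
    select_k,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results/selection"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

items_full = read_items_csv(args.cohort_dir / "items.csv", aqol_metadata())
items, _ = complete_case_filter(items_full)
truth = pd.read_csv(args.cohort_dir / "true_classes.csv", index_col=0)
sites = truth["site"].to_numpy()[items_full.complete_rows()]

frames, picks = [], {}
for scheme in ("kfold", "loso", "splithalf"):
    folds = make_folds(items.n_persons, scheme, sites=sites, n_folds=10, seed=args.seed)
    cv = cross_validate(items, range(1, 7), folds=folds, n_restarts=20, seed=args.seed)
    frames.append(cv)
    res = select_k(cv)
    picks[scheme] = {"selected_k": res.selected_k, "elbow_k": res.elbow_k}
    print(f"{scheme}: selected K = {res.selected_k} (elbow at {res.elbow_k})")
    print(res.summary[["mean", "std"]].round(1).to_string())

pd.concat(frames, ignore_index=True).to_csv(args.out_dir / "cv_table.csv", index=False)

K = picks["kfold"]["selected_k"]
fit = fit_em(items, K, n_restarts=20, seed=args.seed)
_, ari, info = kmeans_pca_sensitivity(
    items, K, seed=args.seed, lca_labels=classify_modal(fit.posteriors)
)
picks["kmeans_sensitivity"] = {"ari": ari, **info}
print(f"k-means/PCA sensitivity: ARI vs LCA classes = {ari:.2f} "
      f"({info['n_components']} components, {info['explained']:.0%} variance)")
with open(args.out_dir / "selection.json", "w") as fh:
    json.dump(picks, fh, indent=1)
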