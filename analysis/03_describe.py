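"""Item structure: polychoric correlation matrix and MDS network layout.

Reads results/cohort/, writes the correlation matrix, 2-D layout and edge
list under results/descriptives/ and reports the correlation range and how
well items cluster by dimension in the layout.
"""

import argparse
from pathlib import Path

import numpy as np

from _util import add_src_to_path  # noqa: F401

from qolclasses.metadata import aqol_metadata, dimension_indices
from qolclasses.descriptives import mds_layout, polychoric_matrix
from qolclasses.responses import complete_case_filter, read_items_csv

parser = argparse.ArgumentParser()
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results/descriptives"))
args = parser.parse_args()
args.out_dir.mkdir(parents=True, exist_ok=True)

meta = aqol_metadata()
items, _ = complete_case_filter(read_items_csv(args.cohort_dir / "items.csv", meta))
pm = polychoric_matrix(items)
layout = mds_layout(pm)

pm.to_frame().to_csv(args.out_dir / "polychoric.csv")
layout.to_frame().to_csv(args.out_dir / "mds_layout.csv")
layout.edges.to_csv(args.out_dir / "mds_edges.csv", index=False)

off = pm.r[~np.eye(20, dtype=bool)]
print(f"polychoric correlations range {off.min():.2f} .. {off.max():.2f}")
d = np.linalg.norm(layout.coordinates[:, None] - layout.coordinates[None, :], axis=2)
dims = dimension_indices(meta)
within = np.mean([d[np.ix_(ix, ix)][np.triu_indices(len(ix), 1)].mean() for ix in dims.values()])
print(f"mean within-dimension layout distance: {within:.3f}")
print(f"mean overall pairwise distance:        {d[np.triu_indices(20, 1)].mean():.3f}")
print(f"edges above display threshold: {len(layout.edges)}")
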