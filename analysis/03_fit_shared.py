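#!/usr/bin/env python
"""Fit the shared (conserved) parameterization across treatments.

From the per-treatment estimates: fits the linear nitrogen relations
(Vcmax25 and Jmax25 through the base content Nb, the others with free
intercepts) and the pooled stomatal slopes a1/b1, both per water level and
across all treatments, with g0 fixed per record from its nitrogen relation.
F-tests compare the pooled stomatal fits against the treatment-specific ones.
Writes the nitrogen-relation table and the pooled stomatal table.
"""

import argparse
import sys
import warnings
from pathlib import Path

import pandas as pd

from leafphys.estimation import f_test_nested
from leafphys.io import read_curves, read_table, write_table
from leafphys.pipeline import run_shared_fit


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dataset", type=Path,
                        default=Path("results/synthetic_experiment.csv"))
    parser.add_argument("--params", type=Path,
                        default=Path("results/treatment_parameters.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    warnings.filterwarnings("ignore")
    dataset = read_curves(args.dataset)
    param_table = read_table(args.params)

    rows = []
    shared_all = run_shared_fit(dataset, param_table, sharing="all")
    shared_water = run_shared_fit(dataset, param_table, sharing="per_water")

    rel_rows = []
    for name, fit in shared_all["relation_fits"].items():
        rel_rows.append({
            "parameter": name, "slope": fit["slope"],
            "slope_se": fit.standard_errors["slope"],
            "intercept": fit["intercept"],
            "intercept_se": fit.standard_errors["intercept"],
            "rss": fit.rss, "n": fit.n_obs,
        })
    rel_table = pd.DataFrame(rel_rows)
    out_rel = args.out_dir / "nitrogen_relations.csv"
    write_table(rel_table, out_rel, metadata={"dataset": str(args.dataset)})

    for scope, fits in [("all", shared_all["pooled_stomatal"]),
                        ("per_water", shared_water["pooled_stomatal"])]:
        for group, fit in fits.items():
            rows.append({
                "sharing": scope, "group": group,
                "a1": fit["a1"], "a1_se": fit.standard_errors["a1"],
                "b1": fit["b1"], "b1_se": fit.standard_errors["b1"],
                "rss": fit.rss, "df": fit.df, "n": fit.n_obs,
            })
    pooled_table = pd.DataFrame(rows)
    out_pooled = args.out_dir / "pooled_stomatal.csv"
    write_table(pooled_table, out_pooled, metadata={"dataset": str(args.dataset)})

    # Does pooling a1/b1 across water levels significantly worsen the fit?
    per_water = shared_water["pooled_stomatal"]
    rss_full = sum(f.rss for f in per_water.values())
    df_full = sum(f.df for f in per_water.values())
    f_all = shared_all["pooled_stomatal"]["all"]
    fstat, p = f_test_nested(rss_full, df_full, f_all.rss, f_all.df)
    print(f"nitrogen relations -> {out_rel}")
    print(rel_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\npooled stomatal fits -> {out_pooled}")
    print(pooled_table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nF-test, one shared (a1,b1) vs per-water pairs: "
          f"F = {fstat:.1f}, p = {p:.3g}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
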