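#!/usr/bin/env python
"""Between-sample diversity: average-rarefied standardized tables,
Jaccard / Bray-Curtis / unweighted and weighted UniFrac distance matrices,
PCoA ordinations, and ANOSIM with pairwise post hoc tests, per set.
Writes distance matrices, ordinations and a consolidated ANOSIM table
(Metric, Set, Org R, Pond R, Org-Pond R + p-values) under results/beta/."""

import argparse
from pathlib import Path

import pandas as pd

from concord16s import io as cio
from concord16s.beta import beta_pipeline

import _common

ROOT = Path(__file__).resolve().parents[1]
METRICS = ["jaccard", "braycurtis", "unweighted_unifrac", "weighted_unifrac"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", type=Path, default=ROOT / "results" / "fixtures")
    ap.add_argument("--filtered", type=Path, default=ROOT / "results" / "filtered")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "beta")
    ap.add_argument("--draws", type=int, default=100)
    ap.add_argument("--permutations", type=int, default=999)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    metadata = cio.read_metadata(args.fixtures / "metadata.tsv")
    sets = _common.load_filtered_sets(args.fixtures, args.filtered)

    anosim_rows = []
    for sid, cset in sets.items():
        tree = cio.read_newick(args.fixtures / sid / "tree.nwk").sheared(list(cset.table.feature_ids))
        results = beta_pipeline(
            cset.table, metadata, metrics=METRICS, tree=tree,
            n_draws=args.draws, n_permutations=args.permutations, seed=args.seed,
        )
        for metric, res in results.items():
            dm = res["distance_matrix"]
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                args.out / f"{sid}_{metric}.tsv", sep="\t"
            )
            ordn = res["pcoa"]
            pd.DataFrame(
                ordn.coordinates, index=ordn.sample_ids,
                columns=[f"PC{k + 1}" for k in range(ordn.coordinates.shape[1])],
            ).to_csv(args.out / f"{sid}_{metric}_pcoa.tsv", sep="\t")
            t = res["anosim"]
            anosim_rows.append(
                {"Metric": metric, "Set": sid,
                 "Org R": round(t["organ"].r, 3), "Pond R": round(t["pond"].r, 3),
                 "Org-Pond R": round(t["organ_pond"].r, 3),
                 "Org Pval": round(t["organ"].p_value, 4),
                 "Pond Pval": round(t["pond"].p_value, 4),
                 "Org-Pond Pval": round(t["organ_pond"].p_value, 4)}
            )
        bc = results["braycurtis"]["anosim"]
        print(
            f"{sid}: Bray-Curtis ANOSIM R organ={bc['organ'].r:.3f} "
            f"pond={bc['pond'].r:.3f} organ-pond={bc['organ_pond'].r:.3f} "
            f"(p={bc['organ_pond'].p_value:.4f})"
        )
    pd.DataFrame(anosim_rows).to_csv(args.out / "anosim.tsv", sep="\t", index=False)
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
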