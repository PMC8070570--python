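#!/usr/bin/env python
"""Within-sample diversity: observed features, Shannon entropy (nats) and
bias-corrected Chao1, each averaged over rarefied draws at the smallest
sample's depth, with nonparametric organ/pond/organ-pond comparisons.
Writes per-set estimate and test tables under results/alpha/."""

import argparse
import json
from pathlib import Path

import pandas as pd

from concord16s import io as cio
from concord16s.alpha import alpha_pipeline

import _common

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", type=Path, default=ROOT / "results" / "fixtures")
    ap.add_argument("--filtered", type=Path, default=ROOT / "results" / "filtered")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "alpha")
    ap.add_argument("--iterations", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    metadata = cio.read_metadata(args.fixtures / "metadata.tsv")
    sets = _common.load_filtered_sets(args.fixtures, args.filtered)

    for sid, cset in sets.items():
        estimates, comparisons = alpha_pipeline(
            cset.table, metadata, iterations=args.iterations, seed=args.seed
        )
        pd.DataFrame(
            [{"sample": e.sample_id, "depth": e.depth,
              **{m: round(e.point_estimate(m), 4) for m in e.values}} for e in estimates]
        ).to_csv(args.out / f"{sid}_estimates.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"grouping": c.grouping, "metric": c.metric, "test": c.test,
              "statistic": round(c.statistic, 4), "p_value": round(c.p_value, 5),
              "significant_at_05": c.significant_at_05,
              "medians": json.dumps(c.group_medians, sort_keys=True)} for c in comparisons]
        ).to_csv(args.out / f"{sid}_tests.tsv", sep="\t", index=False)
        sig = [f"{c.grouping}/{c.metric} (p={c.p_value:.4f})" for c in comparisons if c.significant_at_05]
        print(f"{sid}: significant at 0.05 -> {', '.join(sig) or 'none'}")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
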