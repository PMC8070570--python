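#!/usr/bin/env python
"""Taxonomy concordance: informative-tag resolution per rank, taxa Venn
overlaps, cross-set Spearman correlations of informative-taxa abundances,
and the <33%-ratio differential-species screen against the 97%-OTU set.
Writes TSVs under results/taxcompare/."""

import argparse
import itertools
from pathlib import Path

import pandas as pd

from concord16s.taxcompare import (
    cross_set_correlation,
    differential_taxa,
    resolution_profile,
    taxa_overlap,
)
from concord16s.types import N_RANKS, RANK_NAMES

import _common

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixtures", type=Path, default=ROOT / "results" / "fixtures")
    ap.add_argument("--filtered", type=Path, default=ROOT / "results" / "filtered")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "taxcompare")
    ap.add_argument("--reference", default="01_OTU_97")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sets = _common.load_filtered_sets(args.fixtures, args.filtered)

    res_rows = []
    for sid, cset in sets.items():
        prof = resolution_profile(cset)
        for lv in range(1, N_RANKS + 1):
            res_rows.append(
                {"set": sid, "level": RANK_NAMES[lv - 1],
                 "n_informative_taxa": prof.n_informative_taxa[lv],
                 "pct_reads_informative": round(prof.pct_reads_informative[lv], 3)}
            )
        print(
            f"{sid}: reads informative at family {prof.pct_reads_informative[5]:.1f}%, "
            f"genus {prof.pct_reads_informative[6]:.1f}%, species {prof.pct_reads_informative[7]:.1f}%"
        )
    pd.DataFrame(res_rows).to_csv(args.out / "resolution.tsv", sep="\t", index=False)

    venn_rows, corr_rows = [], []
    set_list = list(sets.values())
    for lv in range(2, N_RANKS + 1):
        part = taxa_overlap(set_list, lv)
        for comp in sorted(part.n_sequences, key=lambda c: sorted(c)):
            venn_rows.append(
                {"level": RANK_NAMES[lv - 1], "compartment": "&".join(sorted(comp)),
                 "n_taxa": part.n_sequences[comp], "pct_reads": round(part.pct_reads(comp), 3)}
            )
        for a, b in itertools.combinations(set_list, 2):
            c = cross_set_correlation(a, b, lv)
            corr_rows.append(
                {"level": c.level_name, "set_a": c.set_pair[0], "set_b": c.set_pair[1],
                 "rho": round(c.rho, 4) if c.rho == c.rho else "NA", "n_taxa": c.n_taxa}
            )
    pd.DataFrame(venn_rows).to_csv(args.out / "venn.tsv", sep="\t", index=False)
    pd.DataFrame(corr_rows).to_csv(args.out / "correlations.tsv", sep="\t", index=False)
    species = [r for r in corr_rows if r["level"] == "species"]
    print("species-level Spearman rho:", {f"{r['set_a']}~{r['set_b']}": r["rho"] for r in species})

    others = [c for s, c in sets.items() if s != args.reference]
    diff = differential_taxa(sets[args.reference], others, level=N_RANKS)
    diff_rows = [
        {"taxon": e.key, "list": name, "ref_abundance": round(e.ref_abundance, 5), "flag": e.flag,
         **{f"abund_{s}": round(v, 5) for s, v in e.other_abundances.items()}}
        for name, entries in [("reference_predominant", diff.reference_predominant),
                              ("shared_or_other", diff.shared_or_other_predominant)]
        for e in entries
    ]
    pd.DataFrame(diff_rows).to_csv(args.out / "differential.tsv", sep="\t", index=False)
    print(
        f"species predominant in {args.reference} (others < 33% of its abundance): "
        f"{len(diff.reference_predominant)}"
    )


if __name__ == "__main__":
    main()
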