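"""Full concordance run: filter -> sequence comparison -> taxonomy
comparison -> alpha diversity -> beta diversity, from a single config.

Stages run in a fixed order; every stage writes its TSV outputs under its
own subdirectory, a MANIFEST.tsv records what was produced (and marks an
aborted run incomplete), and ``summary.json`` collates the
machine-readable results. The summary is written with sorted keys so two
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .alpha import alpha_pipeline
from .beta import METRIC_CHOICES, beta_pipeline
from .filtering import standard_filter_pipeline
from .seqcompare import (
    difference_profile,
    exact_overlap,
    origin_breakdown,
    resilience_curve,
    threshold_grid,
)
from .taxcompare import (
    cross_set_correlation,
    differential_taxa,
    resolution_profile,
    taxa_overlap,
)
from .types import N_RANKS, RANK_NAMES, ClusterSet, FormatError

log = logging.getLogger("concord16s")

SUMMARY_SCHEMA_VERSION = 1
STAGES = ("filter", "seqcompare", "taxcompare", "alpha", "beta")


@dataclass
class RunConfig:
    """Validated configuration for one end-to-end run."""

    set_paths: dict[str, str]
    metadata_path: str
    out_dir: str
    tree_paths: dict[str, str] = field(default_factory=dict)
    min_frac: float = 0.001
    singleton_mode: str = "per_cell"
    max_changes: int = 20
    min_identity: float = 0.75
    threshold_start: float = 1.0
    threshold_stop: float = 0.9
    threshold_step: float = 0.005
    reference_set: str | None = None
    alpha_iterations: int = 10_000
    beta_draws: int = 100
    beta_permutations: int = 999
    beta_metrics: tuple = ("jaccard", "braycurtis")
    alpha_level: float = 0.05
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(
            set_paths=raw["sets"],
            metadata_path=raw["metadata"],
            out_dir=raw["out_dir"],
            tree_paths=raw.get("trees", {}),
            reference_set=raw.get("reference_set"),
            seed=raw.get("seed", 0),
        )
        for section in ("filter", "seqcompare", "alpha", "beta"):
            for key, val in raw.get(section, {}).items():
                attr = {
                    ("filter", "min_frac"): "min_frac",
                    ("filter", "singleton_mode"): "singleton_mode",
                    ("seqcompare", "max_changes"): "max_changes",
                    ("seqcompare", "min_identity"): "min_identity",
                    ("seqcompare", "threshold_start"): "threshold_start",
                    ("seqcompare", "threshold_stop"): "threshold_stop",
                    ("seqcompare", "threshold_step"): "threshold_step",
                    ("alpha", "iterations"): "alpha_iterations",
                    ("beta", "draws"): "beta_draws",
                    ("beta", "permutations"): "beta_permutations",
                    ("beta", "metrics"): "beta_metrics",
                }.get((section, key))
                if attr is None:
                    raise FormatError(f"unknown config key {section}.{key}")
                setattr(cfg, attr, tuple(val) if attr == "beta_metrics" else val)
        cfg.validate_static()
        return cfg

    def validate_static(self) -> None:
        for sid, path in self.set_paths.items():
            if not Path(path).is_dir():
                raise FormatError(f"set directory for {sid} not found: {path}")
        if not Path(self.metadata_path).is_file():
            raise FormatError(f"metadata file not found: {self.metadata_path}")
        for metric in self.beta_metrics:
            if metric not in METRIC_CHOICES:
                raise FormatError(f"unknown beta metric {metric!r}")
        needs_tree = any("unifrac" in m for m in self.beta_metrics)
        for sid in self.set_paths:
            tree = self.tree_paths.get(sid, str(Path(self.set_paths[sid]) / "tree.nwk"))
            if needs_tree and not Path(tree).is_file():
                raise FormatError(f"UniFrac requested but no tree for set {sid}: {tree}")


def _stage_seeds(master: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(n)]


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the collated summary (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str]] = []
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": config.seed}
    alpha_seed, beta_seed = _stage_seeds(config.seed, 2)
    log.info("derived stage seeds: alpha=%d beta=%d", alpha_seed, beta_seed)

    try:
        sets = {sid: cio.read_cluster_set(path, sid) for sid, path in config.set_paths.items()}
        metadata = cio.read_metadata(config.metadata_path)
        for cset in sets.values():
            metadata.groups("organ_pond", cset.table.sample_ids)  # fail fast on missing samples
        trees = {}
        if any("unifrac" in m for m in config.beta_metrics):
            for sid in sets:
                path = config.tree_paths.get(sid, str(Path(config.set_paths[sid]) / "tree.nwk"))
                trees[sid] = cio.read_newick(path)

        # --- stage 1: filtering -------------------------------------------
        stage_dir = out / "filter"
        stage_dir.mkdir(exist_ok=True)
        filtered: dict[str, ClusterSet] = {}
        summary["filter"] = {}
        for sid, cset in sets.items():
            table, reports = standard_filter_pipeline(
                cset.table, threshold=config.min_frac, singleton_mode=config.singleton_mode
            )
            filtered[sid] = ClusterSet(
                sid,
                table,
                {f: cset.centroids[f] for f in table.feature_ids},
                taxonomy={f: cset.taxonomy[f] for f in table.feature_ids} if cset.taxonomy else {},
                origin={f: cset.origin[f] for f in table.feature_ids},
            )
            cio.write_feature_table(table, stage_dir / f"{sid}_filtered.tsv")
            manifest.append(("filter", f"{sid}_filtered.tsv"))
            summary["filter"][sid] = {k: r.to_dict() for k, r in reports.items()}
            for rep in summary["filter"][sid].values():
                rep["removed_feature_ids"] = len(rep["removed_feature_ids"])

        # --- stage 2: sequence concordance --------------------------------
        stage_dir = out / "seqcompare"
        stage_dir.mkdir(exist_ok=True)
        part = exact_overlap(list(filtered.values()))
        overlap_rows = []
        for comp in sorted(part.n_sequences, key=lambda c: sorted(c)):
            overlap_rows.append(
                {
                    "compartment": "&".join(sorted(comp)),
                    "n_sequences": part.n_sequences[comp],
                    "n_reads": part.n_reads[comp],
                    "pct_sequences": round(part.pct_sequences(comp), 4),
                    "pct_reads": round(part.pct_reads(comp), 4),
                }
            )
        pd.DataFrame(overlap_rows).to_csv(stage_dir / "overlap_partition.tsv", sep="\t", index=False)
        manifest.append(("seqcompare", "overlap_partition.tsv"))
        summary["seqcompare"] = {"overlap": overlap_rows}

        profile_rows, resilience_rows, origin_rows = [], [], []
        grid = threshold_grid(config.threshold_start, config.threshold_stop, config.threshold_step)
        for sid, cset in filtered.items():
            prof = difference_profile(cset, config.max_changes, config.min_identity)
            for n, frac in prof.curve():
                profile_rows.append({"set": sid, "n_changes": n, "cum_fraction": round(frac, 6)})
            res = resilience_curve(cset, grid)
            for t, frac in zip(res.thresholds, res.remaining_fraction):
                resilience_rows.append({"set": sid, "threshold": t, "remaining_fraction": round(frac, 6)})
            brk = origin_breakdown(cset)
            for o in sorted(brk.n_sequences):
                origin_rows.append(
                    {
                        "set": sid,
                        "origin": o,
                        "n_sequences": brk.n_sequences[o],
                        "n_reads": brk.n_reads[o],
                        "pct_reads": round(brk.pct_reads(o), 4),
                    }
                )
        for name, rows in [
            ("difference_profile.tsv", profile_rows),
            ("resilience.tsv", resilience_rows),
            ("origin_breakdown.tsv", origin_rows),
        ]:
            pd.DataFrame(rows).to_csv(stage_dir / name, sep="\t", index=False)
            manifest.append(("seqcompare", name))
        summary["seqcompare"]["origin"] = origin_rows

        # --- stage 3: taxonomy concordance --------------------------------
        stage_dir = out / "taxcompare"
        stage_dir.mkdir(exist_ok=True)
        res_rows, corr_rows, venn_rows = [], [], []
        for sid, cset in filtered.items():
            prof = resolution_profile(cset)
            for level in range(1, N_RANKS + 1):
                res_rows.append(
                    {
                        "set": sid,
                        "level": RANK_NAMES[level - 1],
                        "n_informative_taxa": prof.n_informative_taxa[level],
                        "pct_reads_informative": round(prof.pct_reads_informative[level], 4),
                    }
                )
        set_list = list(filtered.values())
        for level in range(2, N_RANKS + 1):
            part = taxa_overlap(set_list, level)
            for comp in sorted(part.n_sequences, key=lambda c: sorted(c)):
                venn_rows.append(
                    {
                        "level": RANK_NAMES[level - 1],
                        "compartment": "&".join(sorted(comp)),
                        "n_taxa": part.n_sequences[comp],
                        "pct_reads": round(part.pct_reads(comp), 4),
                    }
                )
            for i in range(len(set_list)):
                for j in range(i + 1, len(set_list)):
                    c = cross_set_correlation(set_list[i], set_list[j], level)
                    corr_rows.append(
                        {
                            "level": c.level_name,
                            "set_a": c.set_pair[0],
                            "set_b": c.set_pair[1],
                            "rho": round(c.rho, 6) if c.rho == c.rho else "NA",
                            "n_taxa": c.n_taxa,
                        }
                    )
        for name, rows in [
            ("resolution.tsv", res_rows),
            ("venn.tsv", venn_rows),
            ("correlations.tsv", corr_rows),
        ]:
            pd.DataFrame(rows).to_csv(stage_dir / name, sep="\t", index=False)
            manifest.append(("taxcompare", name))
        summary["taxcompare"] = {"resolution": res_rows, "correlations": corr_rows}

        reference = config.reference_set or sorted(filtered)[0]
        others = [c for s, c in filtered.items() if s != reference]
        diff = differential_taxa(filtered[reference], others, level=N_RANKS)
        diff_rows = [
            {
                "taxon": e.key,
                "list": name,
                "ref_abundance": round(e.ref_abundance, 6),
                "flag": e.flag,
                **{f"abund_{s}": round(v, 6) for s, v in e.other_abundances.items()},
            }
            for name, entries in [
                ("reference_predominant", diff.reference_predominant),
                ("shared_or_other", diff.shared_or_other_predominant),
            ]
            for e in entries
        ]
        pd.DataFrame(diff_rows).to_csv(stage_dir / "differential.tsv", sep="\t", index=False)
        manifest.append(("taxcompare", "differential.tsv"))

        # --- stage 4: alpha diversity --------------------------------------
        stage_dir = out / "alpha"
        stage_dir.mkdir(exist_ok=True)
        summary["alpha"] = {}
        for sid, cset in filtered.items():
            estimates, comparisons = alpha_pipeline(
                cset.table, metadata, iterations=config.alpha_iterations, seed=alpha_seed
            )
            est_rows = [
                {
                    "sample": e.sample_id,
                    "depth": e.depth,
                    **{m: round(e.point_estimate(m), 6) for m in e.values},
                }
                for e in estimates
            ]
            test_rows = [
                {
                    "grouping": c.grouping,
                    "metric": c.metric,
                    "test": c.test,
                    "statistic": round(c.statistic, 6),
                    "p_value": round(c.p_value, 6),
                    "significant_at_05": c.significant_at_05,
                    "medians": json.dumps(c.group_medians, sort_keys=True),
                }
                for c in comparisons
            ]
            pd.DataFrame(est_rows).to_csv(stage_dir / f"{sid}_estimates.tsv", sep="\t", index=False)
            pd.DataFrame(test_rows).to_csv(stage_dir / f"{sid}_tests.tsv", sep="\t", index=False)
            manifest.extend([("alpha", f"{sid}_estimates.tsv"), ("alpha", f"{sid}_tests.tsv")])
            summary["alpha"][sid] = test_rows

        # --- stage 5: beta diversity ---------------------------------------
        stage_dir = out / "beta"
        stage_dir.mkdir(exist_ok=True)
        anosim_rows = []
        for sid, cset in filtered.items():
            tree = trees.get(sid)
            if tree is not None:
                tree = tree.sheared(list(cset.table.feature_ids))
            results = beta_pipeline(
                cset.table,
                metadata,
                metrics=list(config.beta_metrics),
                tree=tree,
                n_draws=config.beta_draws,
                n_permutations=config.beta_permutations,
                seed=beta_seed,
            )
            for metric, res in results.items():
                dm = res["distance_matrix"]
                pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                    stage_dir / f"{sid}_{metric}.tsv", sep="\t"
                )
                ord_ = res["pcoa"]
                pd.DataFrame(
                    ord_.coordinates,
                    index=ord_.sample_ids,
                    columns=[f"PC{k + 1}" for k in range(ord_.coordinates.shape[1])],
                ).to_csv(stage_dir / f"{sid}_{metric}_pcoa.tsv", sep="\t")
                manifest.extend([("beta", f"{sid}_{metric}.tsv"), ("beta", f"{sid}_{metric}_pcoa.tsv")])
                tests = res["anosim"]
                anosim_rows.append(
                    {
                        "Metric": metric,
                        "Set": sid,
                        "Org R": round(tests["organ"].r, 6),
                        "Pond R": round(tests["pond"].r, 6),
                        "Org-Pond R": round(tests["organ_pond"].r, 6),
                        "Org Pval": round(tests["organ"].p_value, 6),
                        "Pond Pval": round(tests["pond"].p_value, 6),
                        "Org-Pond Pval": round(tests["organ_pond"].p_value, 6),
                    }
                )
        pd.DataFrame(anosim_rows).to_csv(stage_dir / "anosim.tsv", sep="\t", index=False)
        manifest.append(("beta", "anosim.tsv"))
        summary["beta"] = {"anosim": anosim_rows}
    except Exception as exc:
        _write_manifest(out, manifest, complete=False)
        log.error("pipeline aborted: %s", exc)
        raise

    _write_manifest(out, manifest, complete=True)
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1) + "\n")
    return summary


def _write_manifest(out: Path, manifest: list[tuple[str, str]], complete: bool) -> None:
    with open(out / "MANIFEST.tsv", "w") as fh:
        fh.write("stage\tfile\n")
        for stage, name in manifest:
            fh.write(f"{stage}\t{name}\n")
        fh.write(f"#complete\t{str(complete).lower()}\n")
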