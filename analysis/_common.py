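"""Shared loader for the analysis drivers: fixture sets restricted to the
features that survived filtering (script 02)."""

from pathlib import Path

from concord16s import io as cio
from concord16s.types import ClusterSet

SET_IDS = ("01_OTU_97", "02_OTU_99", "03_ASV")


def load_filtered_sets(fixtures: Path, filtered: Path) -> dict[str, ClusterSet]:
    out = {}
    for sid in SET_IDS:
        cset = cio.read_cluster_set(fixtures / sid, sid)
        table = cio.read_feature_table(filtered / f"{sid}_filtered.tsv")
        out[sid] = ClusterSet(
            sid,
            table,
            {f: cset.centroids[f] for f in table.feature_ids},
            taxonomy={f: cset.taxonomy[f] for f in table.feature_ids},
            origin={f: cset.origin[f] for f in table.feature_ids},
        )
    return out
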