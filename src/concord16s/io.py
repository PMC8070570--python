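"""Readers and writers for the pipeline's external artifacts.

Formats are deliberately plain: tab-separated feature tables (features in
rows, first column the feature id), FASTA centroids, two-column Greengenes
style taxonomy TSVs, Newick trees and a sample-metadata TSV with ``organ``
and ``pond`` columns. Writers emit deterministic row/column order so that a
write-then-read round trip is exact.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .types import (
    N_RANKS,
    RANK_PREFIXES,
    FeatureTable,
    FormatError,
    PhyloTree,
    SampleMetadata,
    TaxonomyString,
    normalize_sequence,
)

log = logging.getLogger("concord16s")


def read_feature_table(path, dialect: str = "tsv_features_in_rows") -> FeatureTable:
    """Read a TSV count table: header row = sample ids, first column = feature ids."""
    if dialect != "tsv_features_in_rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise FormatError(f"empty or degenerate feature table in {path}")
    feature_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                val = int(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {cell!r} at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
            counts[i, j] = val
    return FeatureTable(feature_ids, sample_ids, counts)


def write_feature_table(table: FeatureTable, path) -> None:
    df = pd.DataFrame(table.counts, index=table.feature_ids, columns=table.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_fasta(path) -> dict[str, str]:
    """Read centroid sequences; ids are the header token up to first whitespace."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"duplicate sequence id {record.id!r}")
        out[record.id] = normalize_sequence(str(record.seq), context=f"sequence {record.id!r}")
    if not out:
        raise FormatError(f"no sequences in {path}")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=f, description="") for f, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def parse_lineage(lineage: str) -> TaxonomyString:
    """Parse a Greengenes-style semicolon lineage ``k__X; p__Y; ...``."""
    parts = [p.strip() for p in lineage.split(";")] if lineage.strip() else []
    if len(parts) > N_RANKS:
        raise FormatError(f"more than {N_RANKS} ranks in {lineage!r}")
    labels = []
    for i, part in enumerate(parts):
        if part[:3] in RANK_PREFIXES:
            if part[:3] != RANK_PREFIXES[i]:
                raise FormatError(
                    f"rank prefix {part[:3]!r} out of order at position {i + 1} in {lineage!r}"
                )
            labels.append(part[3:].strip())
        elif "__" in part[:4]:
            raise FormatError(f"unknown rank prefix in {part!r}")
        else:
            labels.append(part)
    return TaxonomyString.canonicalize(labels)


def format_lineage(t: TaxonomyString) -> str:
    return "; ".join(p + l for p, l in zip(RANK_PREFIXES, t.ranks))


def read_taxonomy(path) -> dict[str, TaxonomyString]:
    """Two-column TSV: feature id, semicolon-separated rank-prefixed lineage."""
    out: dict[str, TaxonomyString] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{line_no}: expected 2 tab-separated columns")
            fid, lineage = fields[0], fields[1]
            if fid in out:
                raise FormatError(f"duplicate taxonomy for feature {fid!r}")
            out[fid] = parse_lineage(lineage)
    return out


def write_taxonomy(taxonomy: dict[str, TaxonomyString], path) -> None:
    with open(path, "w") as fh:
        for fid, t in taxonomy.items():
            fh.write(f"{fid}\t{format_lineage(t)}\n")


def read_newick(path_or_str) -> PhyloTree:
    """Read a rooted Newick tree; every non-root branch must carry a length."""
    if isinstance(path_or_str, str) and path_or_str.strip().startswith("("):
        tree = TreeNode.read(_io.StringIO(path_or_str))
    else:
        tree = TreeNode.read(str(path_or_str))
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path))


def read_metadata(path) -> SampleMetadata:
    """Sample-metadata TSV; required columns: sample id (first), organ, pond."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("organ", "pond"):
        if required not in cols:
            raise FormatError(f"metadata missing column {required!r}")
    sample_ids = df.iloc[:, 0].tolist()
    return SampleMetadata(
        sample_ids,
        organ=dict(zip(sample_ids, df[cols["organ"]])),
        pond=dict(zip(sample_ids, df[cols["pond"]])),
    )


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": metadata.sample_ids,
            "organ": [metadata.organ[s] for s in metadata.sample_ids],
            "pond": [metadata.pond[s] for s in metadata.sample_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_origin(path) -> dict[str, str]:
    """Optional two-column TSV: feature id, origin in {reference, de_novo, unknown}."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fid, origin = line.split("\t")[:2]
            out[fid] = origin
    return out


def write_origin(origin: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for fid, o in origin.items():
            fh.write(f"{fid}\t{o}\n")


def read_cluster_set(directory, set_id: str | None = None):
    """Assemble a ClusterSet from a directory laid out by ``write_cluster_set``."""
    from .types import ClusterSet

    directory = Path(directory)
    set_id = set_id or directory.name
    table = read_feature_table(directory / "table.tsv")
    centroids = read_fasta(directory / "centroids.fasta")
    taxonomy = read_taxonomy(directory / "taxonomy.tsv") if (directory / "taxonomy.tsv").exists() else {}
    origin = read_origin(directory / "origin.tsv") if (directory / "origin.tsv").exists() else {}
    return ClusterSet(set_id, table, centroids, taxonomy=taxonomy, origin=origin)


def write_cluster_set(cset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_feature_table(cset.table, directory / "table.tsv")
    write_fasta(cset.centroids, directory / "centroids.fasta")
    if cset.taxonomy:
        write_taxonomy(cset.taxonomy, directory / "taxonomy.tsv")
    if cset.origin:
        write_origin(cset.origin, directory / "origin.tsv")
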