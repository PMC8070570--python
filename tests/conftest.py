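import numpy as np
import pytest

from concord16s.filtering import standard_filter_pipeline
from concord16s.synth import generate_bundle
from concord16s.types import ClusterSet, FeatureTable, TaxonomyString


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study: 40 taxa, 2x2x6 samples, 20k reads."""
    return generate_bundle(seed=3)


@pytest.fixture(scope="session")
def filtered_sets(bundle):
    """The three cluster sets after the standard filter pipeline."""
    out = {}
    for sid, cset in bundle.sets.items():
        table, _ = standard_filter_pipeline(cset.table)
        out[sid] = ClusterSet(
            sid,
            table,
            {f: cset.centroids[f] for f in table.feature_ids},
            taxonomy={f: cset.taxonomy[f] for f in table.feature_ids},
            origin={f: cset.origin[f] for f in table.feature_ids},
        )
    return out


def make_table(counts, feature_ids=None, sample_ids=None) -> FeatureTable:
    counts = np.asarray(counts)
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(counts.shape[1])]
    return FeatureTable(feature_ids, sample_ids, counts)


def species_lineage(i: int) -> TaxonomyString:
    return TaxonomyString(
        ("Bacteria", "P1", "C1", "O1", "F1", "G1", f"sp{i:02d}")
    )


def single_sample_set(set_id, counts, lineages=None, sequences=None) -> ClusterSet:
    """One-sample ClusterSet from a count vector, for correlation fixtures."""
    fids = [f"t{i + 1}" for i in range(len(counts))]
    table = make_table(np.asarray(counts)[:, None], feature_ids=fids)
    seqs = sequences or {f: "ACGT" for f in fids}
    tax = lineages or {f: species_lineage(i + 1) for i, f in enumerate(fids)}
    return ClusterSet(set_id, table, seqs, taxonomy=tax)
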