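import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import treedna as td

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_otu_table(rows, samples):
    """Build an OtuTable from terse specs.

    ``rows``: list of (otu_id, taxon, seq_len, insert_len, {sample: count});
    ``samples``: list of (sample_id, role, collection_method, tree, visit,
    ext_batch, pcr_batch, site).
    """
    sample_ids = [s[0] for s in samples]
    features = pd.DataFrame(
        [(r[1], r[2], r[3]) for r in rows],
        columns=["taxon", "sequence_length", "insert_length"],
        index=pd.Index([r[0] for r in rows], name="otu_id"),
    )
    counts = pd.DataFrame(
        [[r[4].get(s, 0) for s in sample_ids] for r in rows],
        columns=sample_ids,
        index=features.index,
    )
    meta = pd.DataFrame(
        samples,
        columns=["sample_id", "role", "collection_method", "tree_id",
                 "visit_index", "extraction_batch", "pcr_batch", "site"],
    ).set_index("sample_id")
    return td.OtuTable(features=features, counts=counts, samples=meta)


def make_history(records, species_meta=None):
    """Build a DetectionHistory from (species, tree, visit, method, y) tuples;
    method 'roller'/'soil'; y may be None for a missing event."""
    rows = [
        {
            "species": sp, "tree": tr, "visit": v, "collection_method": m,
            "molecular_method": "metabarcoding",
            "y": np.nan if y is None else y,
        }
        for sp, tr, v, m, y in records
    ]
    return td.DetectionHistory(obs=pd.DataFrame(rows), species_meta=species_meta)


def make_multimethod_history(sample_records):
    """Build a single-species two-method history from
    (tree, visit, collection_method, y_metabarcoding, y_qpcr) tuples."""
    rows = []
    for tr, v, cm, ym, yq in sample_records:
        for mm, y in (("metabarcoding", ym), ("qpcr", yq)):
            rows.append(
                {"species": "focal", "tree": tr, "visit": v,
                 "collection_method": cm, "molecular_method": mm, "y": y}
            )
    return td.DetectionHistory(obs=pd.DataFrame(rows))


@pytest.fixture
def batch_table():
    """Four true samples in two PCR batches plus one PCR negative per batch,
    an extraction negative and a field negative; used for the
    negative-control subtraction rules."""
    samples = [
        ("S1", "sample", "roller", "t1", 1, "E1", "B", "siteA"),
        ("S2", "sample", "roller", "t1", 2, "E1", "B", "siteA"),
        ("S3", "sample", "soil", "t2", 1, "E1", "C", "siteA"),
        ("S4", "sample", "soil", "t2", 2, "E2", "C", "siteB"),
        ("PN_B", "pcr_negative", "roller", "", 0, "", "B", ""),
        ("PN_C", "pcr_negative", "roller", "", 0, "", "C", ""),
        ("EN1", "extraction_negative", "roller", "", 0, "E1", "", ""),
        ("FN_A", "field_negative", "roller", "", 0, "", "", "siteA"),
    ]
    rows = [
        ("o1", "Glaucomys volans", 100, 120,
         {"S1": 5, "S2": 100, "S3": 40, "S4": 40, "PN_B": 7}),
        ("o2", "Sciurus carolinensis", 100, 120,
         {"S1": 50, "S2": 60, "S3": 70, "S4": 80}),
    ]
    return make_otu_table(rows, samples)
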