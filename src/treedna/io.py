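"""Tabular containers for tree-bark ("roller") and soil eDNA survey data.

Two containers carry the whole pipeline.  :class:`OtuTable` holds
metabarcoding read counts (OTU x sample) together with per-OTU taxon
assignments and length information, and per-sample metadata including the
negative-control roles used for decontamination.  :class:`DetectionHistory`
holds the binary species x tree x sampling-event detection records that the
occupancy models consume.

File formats are deliberately plain: OTU tables and their sample metadata
are tab-separated (UTF-8, first column is the row key); detection histories
are long-format CSV with one row per (species, tree, event) observation.
A missing observation is an empty ``y`` cell, never a 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_ROLES = ("sample", "field_negative", "extraction_negative", "pcr_negative")
NEGATIVE_ROLES = ("field_negative", "extraction_negative", "pcr_negative")
COLLECTION_METHODS = ("roller", "soil")
MOLECULAR_METHODS = ("metabarcoding", "qpcr", "na")

#: columns required in a sample-metadata table, beside the sample_id key
SAMPLE_META_COLUMNS = (
    "role",
    "collection_method",
    "tree_id",
    "visit_index",
    "extraction_batch",
    "pcr_batch",
    "site",
)

_FEATURE_COLUMNS = ("taxon", "sequence_length", "insert_length")


class TableParseError(ValueError):
    """Raised when an input table violates the format contract.

    The message names the offending row and column so the bad cell can be
    located in the source file.
    """


@dataclass
class OtuTable:
    """An OTU x sample read-count table with taxon and sample metadata.

    Parameters
    ----------
    features
        DataFrame indexed by ``otu_id`` with columns ``taxon``,
        ``sequence_length`` and ``insert_length`` (both in bp).
    counts
        DataFrame of non-negative integer read counts, indexed by ``otu_id``
        with one column per ``sample_id``.  Must share its index with
        ``features``.
    samples
        DataFrame indexed by ``sample_id`` with the columns in
        :data:`SAMPLE_META_COLUMNS`.  ``role`` is one of
        :data:`SAMPLE_ROLES`; negative-control rows are linked to true
        samples through ``site`` (+ ``visit_index``), ``extraction_batch``
        and ``pcr_batch``.
    """

    features: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.features.index.equals(self.counts.index):
            raise TableParseError("features and counts must be indexed by the same otu_ids")
        missing = [c for c in _FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise TableParseError(f"feature table missing columns: {missing}")
        unknown = set(self.counts.columns) - set(self.samples.index)
        if unknown:
            raise TableParseError(
                f"count columns absent from sample metadata: {sorted(unknown)}"
            )
        bad_roles = set(self.samples["role"]) - set(SAMPLE_ROLES)
        if bad_roles:
            raise TableParseError(f"unknown sample roles: {sorted(bad_roles)}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise TableParseError(
                f"negative read count at otu {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    # -- convenience views ------------------------------------------------
    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        """Sample columns present in the count matrix (any role)."""
        return list(self.counts.columns)

    def ids_with_role(self, *roles: str) -> list:
        ids = self.samples.index[self.samples["role"].isin(roles)]
        return [s for s in ids if s in self.counts.columns]

    @property
    def true_sample_ids(self) -> list:
        return self.ids_with_role("sample")

    @property
    def negative_ids(self) -> list:
        return self.ids_with_role(*NEGATIVE_ROLES)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def otu_totals(self) -> pd.Series:
        """Total reads per OTU across every column in the count matrix."""
        return self.counts.sum(axis=1)

    def replace(self, *, features=None, counts=None, samples=None) -> "OtuTable":
        return OtuTable(
            features=self.features if features is None else features,
            counts=self.counts if counts is None else counts,
            samples=self.samples if samples is None else samples,
        )

    def equals(self, other: "OtuTable") -> bool:
        return (
            self.features.equals(other.features)
            and self.counts.equals(other.counts)
            and self.samples.equals(other.samples)
        )


@dataclass
class DetectionHistory:
    """Binary detection records for repeat-visit occupancy modelling.

    ``obs`` is a long-format DataFrame with columns ``species``, ``tree``,
    ``visit``, ``collection_method``, ``molecular_method`` and ``y``.
    ``y`` is 1 (detected), 0 (sampled, not detected) or NaN (the event is
    part of the design but was not observed, e.g. a skipped soil visit).
    ``species_meta``, when present, is indexed by species and carries an
    ``arboreal`` boolean and a ``clade`` label.
    """

    obs: pd.DataFrame
    species_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"species", "tree", "visit", "collection_method", "molecular_method", "y"}
        missing = required - set(self.obs.columns)
        if missing:
            raise TableParseError(f"detection history missing columns: {sorted(missing)}")
        y = self.obs["y"]
        ok = y.isna() | y.isin([0, 1])
        if not ok.all():
            bad = self.obs.loc[~ok].iloc[0]
            raise TableParseError(
                f"y must be 0, 1 or missing; got {bad['y']!r} for species "
                f"{bad['species']!r}, tree {bad['tree']!r}"
            )
        bad_cm = set(self.obs["collection_method"]) - set(COLLECTION_METHODS)
        if bad_cm:
            raise TableParseError(f"unknown collection methods: {sorted(bad_cm)}")
        bad_mm = set(self.obs["molecular_method"]) - set(MOLECULAR_METHODS)
        if bad_mm:
            raise TableParseError(f"unknown molecular methods: {sorted(bad_mm)}")
        if self.species_meta is not None and "arboreal" in self.species_meta.columns:
            vals = set(self.species_meta["arboreal"].dropna().unique())
            if not vals <= {True, False}:
                raise TableParseError("arboreal flags must be boolean")

    @property
    def species(self) -> list:
        return sorted(self.obs["species"].unique())

    @property
    def trees(self) -> list:
        return sorted(self.obs["tree"].unique())

    def observed(self) -> pd.DataFrame:
        """Rows with a recorded 0/1 outcome (missing events dropped)."""
        return self.obs.dropna(subset=["y"])

    def equals(self, other: "DetectionHistory") -> bool:
        a = self.obs.reset_index(drop=True)
        b = other.obs.reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, meta_path) -> OtuTable:
    """Read an OTU table TSV plus its sample-metadata TSV.

    The table file has columns ``otu_id``, ``taxon``, ``sequence_length``,
    ``insert_length`` and then one integer column per sample.  Errors name
    the offending cell.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
    for col in ("otu_id", *_FEATURE_COLUMNS):
        if col not in raw.columns:
            raise TableParseError(f"{path}: missing column {col!r}")
    raw = raw.set_index("otu_id")
    features = raw[list(_FEATURE_COLUMNS)].copy()
    sample_cols = [c for c in raw.columns if c not in _FEATURE_COLUMNS]
    counts = raw[sample_cols].copy()
    for col in sample_cols:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            otu = counts.index[vals.isna().to_numpy().nonzero()[0][0]]
            raise TableParseError(
                f"{path}: non-numeric count at otu {otu!r}, sample {col!r}"
            )
        neg = vals < 0
        if neg.any():
            otu = counts.index[neg.to_numpy().nonzero()[0][0]]
            raise TableParseError(
                f"{path}: negative read count at otu {otu!r}, sample {col!r}"
            )
        counts[col] = vals.astype(np.int64)

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise TableParseError(f"{meta_path}: missing column 'sample_id'")
    for col in SAMPLE_META_COLUMNS:
        if col not in meta.columns:
            raise TableParseError(f"{meta_path}: missing column {col!r}")
    meta = meta.set_index("sample_id")
    return OtuTable(features=features, counts=counts, samples=meta)


def write_otu_table(table: OtuTable, path, meta_path) -> None:
    out = pd.concat([table.features, table.counts], axis=1)
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")
    meta = table.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_detection_history(path, species_meta_path=None) -> DetectionHistory:
    obs = pd.read_csv(path)
    meta = None
    if species_meta_path is not None:
        meta = pd.read_csv(species_meta_path).set_index("species")
        if "arboreal" in meta.columns:
            meta["arboreal"] = meta["arboreal"].astype(bool)
    return DetectionHistory(obs=obs, species_meta=meta)


def write_detection_history(history: DetectionHistory, path, species_meta_path=None) -> None:
    history.obs.to_csv(path, index=False)
    if species_meta_path is not None and history.species_meta is not None:
        meta = history.species_meta.copy()
        meta.index.name = "species"
        meta.to_csv(species_meta_path)


# ---------------------------------------------------------------------------
# detection-history construction
# ---------------------------------------------------------------------------

def build_detection_history(
    table: OtuTable,
    min_reads_detect: int = 1,
    molecular_method: str = "metabarcoding",
) -> DetectionHistory:
    """Collapse a (filtered) OTU table to a binary detection history.

    A species counts as detected in a sample when its summed reads across
    OTUs reach ``min_reads_detect`` (default 1, i.e. any surviving read).
    Events are keyed by (tree, visit, collection_method); roller and soil
    samples taken the same day are distinct events.  Negative-control
    columns are excluded; if any still carry reads a warning is logged,
    since the table was expected to be decontaminated first.
    """
    if min_reads_detect < 1:
        raise ValueError("min_reads_detect must be a positive integer")
    neg_ids = table.negative_ids
    if neg_ids:
        leftover = int(table.counts[neg_ids].to_numpy().sum())
        if leftover > 0:
            logger.warning(
                "detection history built from a table with %d reads remaining "
                "in negative controls; negatives are excluded", leftover
            )
    by_taxon = table.counts.groupby(table.features["taxon"]).sum()
    rows = []
    for sid in table.true_sample_ids:
        meta = table.samples.loc[sid]
        detected = by_taxon[sid] >= min_reads_detect
        for taxon, det in detected.items():
            rows.append(
                {
                    "species": taxon,
                    "tree": meta["tree_id"],
                    "visit": meta["visit_index"],
                    "collection_method": meta["collection_method"],
                    "molecular_method": molecular_method,
                    "y": int(det),
                }
            )
    obs = pd.DataFrame(
        rows,
        columns=["species", "tree", "visit", "collection_method", "molecular_method", "y"],
    )
    return DetectionHistory(obs=obs)
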