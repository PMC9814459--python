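"""Post-assignment filtering cascade for metabarcoding OTU tables.

The cascade runs five stages in a fixed order:

1. drop OTUs with total reads below ``min_read_count`` or sequences shorter
   than ``min_length_bp``;
2. drop OTUs with insert length at or above ``max_insert_bp_exclusive``
   (off-target, typically microbial, amplicons);
3. drop OTUs assigned to known contaminant taxa;
4. per-OTU negative-control thresholding: for every true sample, reduce
   each OTU's count by the largest count that OTU shows in any linked
   negative control (field negatives share the sample's site and visit,
   extraction negatives its extraction batch, PCR negatives its PCR
   batch), then zero the negative-control columns;
5. drop OTUs whose remaining total is below ``min_otu_total``.

Stage 4 supports two readings of "remove the counts that appeared in the
negatives": ``subtract`` (default, the stricter reading — the negative
count is deducted from every linked sample, floored at zero) and
``threshold`` (counts at or below the negative count are zeroed, larger
counts kept whole).  Stage 5 likewise supports a per-sample variant of the
total-count rule via ``low_abundance_scope``.

The order is not commutative — e.g. negative thresholding before the taxon
filters would waste effort on contaminant OTUs about to disappear, and the
abundance floor is meant to act on post-threshold residuals — so
:func:`run_filter_pipeline` applies the stages exactly in the order above
and records a read-conserving audit for each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import NEGATIVE_ROLES, OtuTable

logger = logging.getLogger(__name__)

#: taxa commonly associated with laboratory or reagent contamination
DEFAULT_CONTAMINANT_TAXA = (
    "Bos taurus",
    "Homo sapiens",
    "Mus musculus",
    "Sus scrofa",
    "Gallus gallus",
)


@dataclass(frozen=True)
class FilterConfig:
    min_read_count: int = 10
    min_length_bp: int = 80
    max_insert_bp_exclusive: int = 200
    contaminant_taxa: tuple = DEFAULT_CONTAMINANT_TAXA
    min_otu_total: int = 20
    negative_rule: str = "subtract"        # or "threshold"
    low_abundance_scope: str = "total"     # or "per_sample"

    def __post_init__(self) -> None:
        for name in ("min_read_count", "min_length_bp", "max_insert_bp_exclusive",
                     "min_otu_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.negative_rule not in ("subtract", "threshold"):
            raise ValueError("negative_rule must be 'subtract' or 'threshold'")
        if self.low_abundance_scope not in ("total", "per_sample"):
            raise ValueError("low_abundance_scope must be 'total' or 'per_sample'")


@dataclass
class StageAudit:
    stage: str
    reads_in: int
    reads_out: int
    otus_in: int
    otus_out: int
    removed_by_reason: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reads_out > self.reads_in:
            raise ValueError(f"stage {self.stage}: reads_out exceeds reads_in")
        if sum(self.removed_by_reason.values()) != self.reads_in - self.reads_out:
            raise ValueError(f"stage {self.stage}: removal reasons do not sum to loss")


@dataclass
class FilterAudit:
    stages: list

    @property
    def reads_in(self) -> int:
        return self.stages[0].reads_in

    @property
    def reads_out(self) -> int:
        return self.stages[-1].reads_out

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "reads_in": s.reads_in,
                    "reads_out": s.reads_out,
                    "otus_in": s.otus_in,
                    "otus_out": s.otus_out,
                    "removed_by_reason": s.removed_by_reason,
                }
                for s in self.stages
            ]
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _keep_otus(table: OtuTable, keep: pd.Series) -> OtuTable:
    return table.replace(features=table.features.loc[keep], counts=table.counts.loc[keep])


def filter_low_count_short(table: OtuTable, cfg: FilterConfig) -> OtuTable:
    """Drop OTUs with total reads < min_read_count or length < min_length_bp."""
    keep = (table.otu_totals() >= cfg.min_read_count) & (
        table.features["sequence_length"] >= cfg.min_length_bp
    )
    return _keep_otus(table, keep)


def filter_insert_length(table: OtuTable, cfg: FilterConfig) -> OtuTable:
    """Drop OTUs with insert length >= max_insert_bp_exclusive (off-target)."""
    return _keep_otus(table, table.features["insert_length"] < cfg.max_insert_bp_exclusive)


def remove_contaminant_taxa(table: OtuTable, cfg: FilterConfig) -> OtuTable:
    """Drop OTUs assigned to a listed contaminant taxon."""
    return _keep_otus(table, ~table.features["taxon"].isin(set(cfg.contaminant_taxa)))


def _linked_negatives(samples: pd.DataFrame, sid: str, available: list) -> list:
    """Negative-control sample ids linked to a true sample.

    Field negatives match on site (and visit when both record one);
    extraction negatives on extraction_batch; PCR negatives on pcr_batch.
    """
    me = samples.loc[sid]
    linked = []
    for nid in available:
        neg = samples.loc[nid]
        role = neg["role"]
        if role == "field_negative":
            if neg["site"] and neg["site"] == me["site"]:
                nv, sv = neg.get("visit_index"), me.get("visit_index")
                if not nv or not sv or nv == sv:
                    linked.append(nid)
        elif role == "extraction_negative":
            if neg["extraction_batch"] and neg["extraction_batch"] == me["extraction_batch"]:
                linked.append(nid)
        elif role == "pcr_negative":
            if neg["pcr_batch"] and neg["pcr_batch"] == me["pcr_batch"]:
                linked.append(nid)
    return linked


def subtract_negative_controls(table: OtuTable, rule: str = "subtract") -> OtuTable:
    """Apply per-OTU negative-control thresholds, then zero the negatives.

    For each true sample and OTU the threshold ``t`` is the maximum count
    of that OTU across the sample's linked negatives (0, with a warning,
    for samples with no linked negative).  Under ``subtract`` the sample
    count is reduced by ``t`` (floor 0); under ``threshold`` it is zeroed
    when <= ``t`` and kept otherwise.
    """
    counts = table.counts.copy()
    neg_ids = table.ids_with_role(*NEGATIVE_ROLES)
    for sid in table.true_sample_ids:
        linked = _linked_negatives(table.samples, sid, neg_ids)
        if not linked:
            logger.warning("sample %s has no linked negative controls; threshold 0", sid)
            continue
        t = table.counts[linked].max(axis=1)
        col = counts[sid]
        counts[sid] = (col - t).clip(lower=0) if rule == "subtract" else col.where(col > t, 0)
    if neg_ids:
        counts[neg_ids] = 0
    return table.replace(counts=counts)


def drop_low_abundance_otus(table: OtuTable, cfg: FilterConfig) -> OtuTable:
    """Drop OTUs below the residual-abundance floor.

    With ``low_abundance_scope='total'`` (default) an OTU is dropped when
    its summed reads across all samples fall below ``min_otu_total``; with
    ``'per_sample'`` individual cells below the floor are zeroed instead.
    """
    if cfg.low_abundance_scope == "total":
        return _keep_otus(table, table.otu_totals() >= cfg.min_otu_total)
    return table.replace(counts=table.counts.where(table.counts >= cfg.min_otu_total, 0))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_filter_pipeline(
    table: OtuTable, cfg: FilterConfig | None = None
) -> tuple[OtuTable, FilterAudit]:
    """Run the five-stage cascade in its canonical order with an audit."""
    cfg = cfg or FilterConfig()
    stages = []

    def run_stage(tab, fn, stage, reason):
        reads_in, otus_in = tab.total_reads(), len(tab.counts)
        out = fn(tab)
        loss = reads_in - out.total_reads()
        stages.append(
            StageAudit(
                stage=stage, reads_in=reads_in, reads_out=out.total_reads(),
                otus_in=otus_in, otus_out=len(out.counts),
                removed_by_reason={reason: loss} if loss else {},
            )
        )
        return out

    table = run_stage(table, lambda t: filter_low_count_short(t, cfg),
                      "low_count_short", "low_count_or_short")
    table = run_stage(table, lambda t: filter_insert_length(t, cfg),
                      "insert_length", "long_insert")
    table = run_stage(table, lambda t: remove_contaminant_taxa(t, cfg),
                      "contaminant_taxa", "contaminant_taxon")

    # negative stage: split the loss between thresholded sample reads and
    # zeroed negative-control columns
    reads_in, otus_in = table.total_reads(), len(table.counts)
    neg_ids = table.ids_with_role(*NEGATIVE_ROLES)
    neg_reads = int(table.counts[neg_ids].to_numpy().sum()) if neg_ids else 0
    out = subtract_negative_controls(table, rule=cfg.negative_rule)
    loss = reads_in - out.total_reads()
    reasons = {}
    if neg_reads:
        reasons["negative_control_zeroed"] = neg_reads
    if loss - neg_reads:
        reasons["negative_threshold"] = loss - neg_reads
    stages.append(
        StageAudit(
            stage="negative_controls", reads_in=reads_in, reads_out=out.total_reads(),
            otus_in=otus_in, otus_out=len(out.counts), removed_by_reason=reasons,
        )
    )
    table = out

    table = run_stage(table, lambda t: drop_low_abundance_otus(t, cfg),
                      "low_abundance", "low_abundance_otu")
    return table, FilterAudit(stages=stages)
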