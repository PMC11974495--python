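"""Post-clustering filters that turn a raw OTU read-count table into the
composite-sample presence/absence matrix the community models consume.

The pipeline order is fixed: (1) per-sample low-abundance zeroing (tag
jumping and low-level contamination show up as a tiny fraction of a
sample's reads), (2) removal of low-depth samples, (3) merging of the
replicate sampling units per tidal level into composite samples,
(4) taxonomy-based exclusion plus occupancy filtering and binarisation.

Tables are pandas DataFrames: read counts are samples (rows) x OTUs
(columns) of non-negative integers; taxonomy is one row per OTU with its
best-hit identity percentage, assigned group and a meiofauna flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: identity thresholds (strict ">") for taxonomic rank assignment
RANK_THRESHOLDS = (
    (97.0, "species"),
    (95.0, "genus"),
    (90.0, "family"),
    (85.0, "order"),
)


@dataclass
class PresenceAbsenceTable:
    """Binary composite-sample x OTU matrix with per-OTU group labels."""

    matrix: pd.DataFrame  # composites x OTUs, entries in {0, 1}
    groups: pd.Series  # OTU id -> higher-taxon label

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_otus(self) -> int:
        return self.matrix.shape[1]

    def group_tally(self) -> pd.Series:
        return self.groups.value_counts()


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.size == 0:
        raise ValueError("empty read-count table")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("duplicate sample or OTU ids")


def filter_low_abundance(
    counts: pd.DataFrame, min_rel: float = 0.0003, scope: str = "sample"
) -> pd.DataFrame:
    """Zero entries below ``min_rel`` of their sample's total reads.

    scope="sample" (default): each entry with count/row_sum < min_rel is
    set to 0 independently per sample — the reading that matches the
    per-sample artefact (tag jumping) the filter is aimed at.
    scope="table": an OTU is removed outright when it never reaches
    ``min_rel`` relative abundance in any sample.
    """
    _validate_counts(counts)
    if min_rel < 0:
        raise ValueError("min_rel must be non-negative")
    if min_rel == 0:
        return counts.copy()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample(s) with zero reads")
    rel = counts.div(totals, axis=0)
    if scope == "sample":
        return counts.where(rel >= min_rel, 0)
    if scope == "table":
        keep = (rel >= min_rel).any(axis=0)
        return counts.loc[:, keep].copy()
    raise ValueError(f"unknown scope {scope!r}")


def drop_low_depth_samples(
    counts: pd.DataFrame, min_reads: int = 3000
) -> pd.DataFrame:
    """Remove samples whose total read count is strictly below ``min_reads``."""
    _validate_counts(counts)
    totals = counts.sum(axis=1)
    dropped = totals.index[totals < min_reads].tolist()
    if dropped:
        log.info("dropping %d low-depth sample(s): %s", len(dropped), dropped)
    kept = counts.loc[totals >= min_reads]
    if kept.shape[0] == 0:
        raise ValueError("all samples fall below the read-depth threshold")
    return kept.copy()


def merge_replicates(
    counts: pd.DataFrame, grouping: pd.Series | dict, mode: str = "sum"
) -> pd.DataFrame:
    """Merge replicate sampling units into composite samples.

    ``grouping`` maps each sample id to its composite id (e.g.,
    "beach_tidalLevel"). mode="sum" adds the read counts; mode="union"
    takes the per-OTU maximum (the binary consequence is identical).
    A group of size 1 passes through unchanged.
    """
    _validate_counts(counts)
    grouping = pd.Series(grouping)
    missing = counts.index.difference(grouping.index)
    if len(missing) > 0:
        raise ValueError(f"samples missing from grouping: {missing.tolist()}")
    keys = grouping.loc[counts.index]
    if mode == "sum":
        merged = counts.groupby(keys).sum()
    elif mode == "union":
        merged = counts.groupby(keys).max()
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    merged.index.name = "composite_id"
    return merged


def assign_rank(best_identity_pct: float) -> str:
    """Map a best-hit identity percentage to a taxonomic rank.

    Bins are strict: > 97 species, > 95 genus, > 90 family, > 85 order;
    anything at or below 85 is unassigned (excluded downstream).
    """
    if not 0.0 <= best_identity_pct <= 100.0:
        raise ValueError(f"identity {best_identity_pct} outside [0, 100]")
    for threshold, rank in RANK_THRESHOLDS:
        if best_identity_pct > threshold:
            return rank
    return "unassigned"


def build_community_matrix(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    min_occupancy: int = 10,
) -> PresenceAbsenceTable:
    """Binarise a merged count table and apply taxonomy/occupancy filters.

    Drops OTUs that are unassigned (best identity <= 85%) or flagged
    non-meiofauna, then binarises (count > 0), then drops OTUs present in
    fewer than ``min_occupancy`` composites and composites left with no OTU.
    """
    _validate_counts(counts)
    tax = taxonomy.set_index("otu_id") if "otu_id" in taxonomy.columns else taxonomy
    known = counts.columns.intersection(tax.index)
    if len(known) < len(counts.columns):
        unknown = counts.columns.difference(tax.index).tolist()
        log.info("dropping %d OTU(s) without taxonomy: %s", len(unknown), unknown[:5])
    tax = tax.loc[known]
    ranks = tax["best_identity_pct"].map(assign_rank)
    keep = (ranks != "unassigned") & tax["is_meiofauna"].astype(bool)
    binary = (counts.loc[:, keep.index[keep]] > 0).astype(int)
    occupancy = binary.sum(axis=0)
    binary = binary.loc[:, occupancy >= min_occupancy]
    if binary.shape[1] == 0:
        raise ValueError("no OTUs retained after taxonomy/occupancy filters")
    binary = binary.loc[binary.sum(axis=1) > 0]
    assert (binary.sum(axis=0) >= min_occupancy).all()
    return PresenceAbsenceTable(matrix=binary, groups=tax.loc[binary.columns, "group"])


def preprocess_pipeline(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    grouping: pd.Series | dict,
    min_rel: float = 0.0003,
    min_reads: int = 3000,
    min_occupancy: int = 10,
    abundance_scope: str = "sample",
    merge_mode: str = "sum",
) -> PresenceAbsenceTable:
    """Full deterministic filter pipeline.

    Order: low-abundance zeroing -> low-depth sample removal -> replicate
    merging -> taxonomy exclusion, binarisation and occupancy filter.
    """
    filtered = filter_low_abundance(counts, min_rel=min_rel, scope=abundance_scope)
    filtered = drop_low_depth_samples(filtered, min_reads=min_reads)
    merged = merge_replicates(filtered, grouping, mode=merge_mode)
    return build_community_matrix(merged, taxonomy, min_occupancy=min_occupancy)
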