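"""Marker quality control: per-marker allele statistics, exclusion filters,
and pruning to an unlinked marker set for population-structure inference.

Allele frequencies are computed on a dosage scale: a homozygous call
contributes 1 to its allele, a mixed-base (IUPAC) call contributes 0.5 to
each of its two constituent alleles, and missing calls are excluded from the
denominator. For a fixed-line panel this reduces to plain allele counting
with mixed calls split evenly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AMBIGUITY, MISSING, NUCLEOTIDES, AnnotationTable, MarkerTable

log = logging.getLogger(__name__)

_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class MarkerStats:
    """Summary statistics for one marker."""

    n_nonmissing: int
    missing_fraction: float
    n_states: int      # distinct non-N call characters (ambiguity codes count)
    n_alleles: int     # distinct underlying nucleotides after decomposition
    maf: float         # minor-allele frequency on the dosage scale; NaN if all missing
    is_biallelic: bool


def _dosage_counts(table: MarkerTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker allele dosage counts.

    Returns (counts, n_nonmissing, n_states) where counts is markers x 4
    (A, C, G, T dosages).
    """
    arr = table.calls.to_numpy(dtype="<U1")  # markers x accessions
    m, n = arr.shape
    counts = np.zeros((m, 4))
    for nuc, i in _NUC_INDEX.items():
        counts[:, i] += (arr == nuc).sum(axis=1)
    for code, (a, b) in AMBIGUITY.items():
        hits = (arr == code).sum(axis=1)
        counts[:, _NUC_INDEX[a]] += 0.5 * hits
        counts[:, _NUC_INDEX[b]] += 0.5 * hits
    n_nonmissing = (arr != MISSING).sum(axis=1)
    n_states = np.array([len(set(row) - {MISSING}) for row in arr])
    return counts, n_nonmissing, n_states


def marker_stats_table(table: MarkerTable) -> pd.DataFrame:
    """MarkerStats for every marker, as a DataFrame indexed by marker_id."""
    counts, n_nonmissing, n_states = _dosage_counts(table)
    n = table.n_accessions
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / counts.sum(axis=1, keepdims=True)
    n_alleles = (counts > 0).sum(axis=1)
    # minor allele frequency = second-largest allele frequency (0 if monomorphic)
    sorted_freqs = np.sort(np.nan_to_num(freqs), axis=1)
    maf = sorted_freqs[:, -2]
    maf = np.where(n_nonmissing > 0, maf, np.nan)
    return pd.DataFrame(
        {
            "n_nonmissing": n_nonmissing,
            "missing_fraction": 1.0 - n_nonmissing / n,
            "n_states": n_states,
            "n_alleles": n_alleles,
            "maf": maf,
            "is_biallelic": n_alleles == 2,
        },
        index=table.meta.index,
    )


def compute_marker_stats(table: MarkerTable, marker_id: str) -> MarkerStats:
    """Statistics for a single marker (all-missing markers get maf = NaN, not an error)."""
    if marker_id not in table.meta.index:
        raise KeyError(f"unknown marker {marker_id!r}")
    row = marker_stats_table(table.subset([marker_id])).iloc[0]
    return MarkerStats(
        n_nonmissing=int(row["n_nonmissing"]),
        missing_fraction=float(row["missing_fraction"]),
        n_states=int(row["n_states"]),
        n_alleles=int(row["n_alleles"]),
        maf=float(row["maf"]),
        is_biallelic=bool(row["is_biallelic"]),
    )


def filter_markers(
    table: MarkerTable,
    max_missing: float = 0.25,
    max_states: int = 3,
    min_maf: float | None = None,
    min_depth: float | None = 10.0,
    min_qual: float | None = 20.0,
) -> MarkerTable:
    """Apply the SNP exclusion thresholds; original marker order is preserved.

    Markers are kept when missing_fraction <= max_missing, n_states <=
    max_states, and (when min_maf is given) maf > min_maf. Depth and base
    quality operate on the optional per-marker ``depth`` / ``qual`` metadata
    columns and are only applied when those columns are present.
    """
    stats = marker_stats_table(table)
    keep = (stats["missing_fraction"] <= max_missing) & (stats["n_states"] <= max_states)
    if min_maf is not None:
        keep &= stats["maf"].fillna(0.0) > min_maf
    if min_depth is not None and "depth" in table.meta.columns:
        keep &= table.meta["depth"] >= min_depth
    if min_qual is not None and "qual" in table.meta.columns:
        keep &= table.meta["qual"] >= min_qual
    kept = table.subset(stats.index[keep])
    log.info("filter_markers: %d -> %d markers", table.n_markers, kept.n_markers)
    return kept


def prune_for_structure(
    table: MarkerTable,
    annotation: AnnotationTable | None = None,
    min_maf: float = 0.05,
    min_distance_bp: int = 500,
) -> MarkerTable:
    """Stringent pruning for structure inference: biallelic, MAF above the
    threshold, one marker per gene, and markers at least ``min_distance_bp``
    apart.

    Within each gene the highest-MAF qualifying SNP is kept (tie-break:
    lowest position). When the annotation provides genomic coordinates,
    retained markers are additionally thinned along each chromosome so
    consecutive markers are >= min_distance_bp apart on the genomic scale
    (the higher-MAF marker of a too-close pair wins).
    """
    stats = marker_stats_table(table)
    qualifying = stats[(stats["is_biallelic"]) & (stats["maf"] > min_maf)]
    chosen: list[str] = []
    meta = table.meta
    for gene, grp in meta.loc[qualifying.index].groupby("gene_id", sort=False):
        cand = qualifying.loc[grp.index].copy()
        cand["position"] = grp["position"]
        # highest MAF wins; ties broken by lowest within-CDS position
        cand = cand.sort_values(["maf", "position"], ascending=[False, True], kind="mergesort")
        chosen.append(cand.index[0])
    chosen = [m for m in meta.index if m in set(chosen)]  # original order

    if annotation is not None and "start" in annotation.table.columns:
        chosen = _thin_genomic(table, annotation, chosen, stats, min_distance_bp)

    kept = table.subset(chosen)
    log.info(
        "prune_for_structure: %d -> %d markers (min_maf=%g, min_distance=%d bp)",
        table.n_markers, kept.n_markers, min_maf, min_distance_bp,
    )
    return kept


def _thin_genomic(table, annotation, chosen, stats, min_distance_bp):
    """Greedy thinning on genomic coordinates; higher-MAF marker of a close pair wins."""
    ann = annotation.table
    rows = []
    for mid in chosen:
        gene = table.meta.loc[mid, "gene_id"]
        if gene in ann.index and pd.notna(ann.loc[gene, "start"]):
            gpos = float(ann.loc[gene, "start"]) + float(table.meta.loc[mid, "position"]) - 1
            rows.append((mid, table.meta.loc[mid, "chromosome"], gpos, stats.loc[mid, "maf"]))
        else:
            rows.append((mid, table.meta.loc[mid, "chromosome"], np.nan, stats.loc[mid, "maf"]))
    out: list[str] = []
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "gpos", "maf"])
    for _, grp in df.groupby("chrom", sort=False):
        located = grp.dropna(subset=["gpos"]).sort_values(["gpos", "marker_id"], kind="mergesort")
        kept_rows: list[pd.Series] = []
        for _, row in located.iterrows():
            if kept_rows and row["gpos"] - kept_rows[-1]["gpos"] < min_distance_bp:
                if row["maf"] > kept_rows[-1]["maf"]:
                    kept_rows[-1] = row
            else:
                kept_rows.append(row)
        out.extend(r["marker_id"] for r in kept_rows)
        out.extend(grp[grp["gpos"].isna()]["marker_id"])  # unlocatable: kept as-is
    return [m for m in chosen if m in set(out)]
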