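"""Tabular data model and file I/O for the associative transcriptomics pipeline.

All pipeline tables are tab-separated UTF-8 with a header row. Genotype calls
are single IUPAC characters per accession: A/C/G/T for homozygous calls,
R/Y/S/W/K/M for mixed-base ("hemi-SNP") calls, and N for missing. Mixed-base
calls in transcriptome data from fixed (doubled-haploid or highly inbred)
lines usually reflect co-expressed paralogues rather than true heterozygosity;
the data model is agnostic about their origin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# IUPAC ambiguity codes for two-allele mixtures.
AMBIGUITY = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
NUCLEOTIDES = ("A", "C", "G", "T")
MISSING = "N"
VALID_CALLS = frozenset(NUCLEOTIDES) | frozenset(AMBIGUITY) | {MISSING}

# reverse lookup: unordered nucleotide pair -> ambiguity code
PAIR_TO_CODE = {frozenset(v): k for k, v in AMBIGUITY.items()}

#: canonical chromosome plotting order; unanchored scaffolds ("C00") go last
CHROMOSOMES = tuple(f"C{i:02d}" for i in range(1, 10)) + ("C00",)

_MARKER_ID_RE = re.compile(r"^(?P<gene>[^:]+):(?P<pos>\d+):(?P<state>[A-Z])$")


class ValidationError(ValueError):
    """A table violates one of the data-model invariants."""


def call_alleles(call: str) -> tuple[str, ...]:
    """Underlying nucleotides of a call: () for N, one for homozygous, two for ambiguity."""
    if call == MISSING:
        return ()
    if call in AMBIGUITY:
        return AMBIGUITY[call]
    if call in NUCLEOTIDES:
        return (call,)
    raise ValidationError(f"invalid call character {call!r}")


def parse_marker_id(marker_id: str) -> tuple[str, int, str]:
    """Split ``gene:position:state`` marker names, e.g. ``Bo6g103650.1:2010:T``."""
    m = _MARKER_ID_RE.match(marker_id)
    if m is None:
        raise ValidationError(f"malformed marker_id {marker_id!r}; expected 'gene:pos:state'")
    return m.group("gene"), int(m.group("pos")), m.group("state")


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (CHROMOSOMES.index(chrom), chrom)
    except ValueError:
        return (len(CHROMOSOMES), chrom)


@dataclass
class MarkerTable:
    """Transcriptome-derived SNP calls with per-marker metadata.

    Parameters
    ----------
    meta : DataFrame indexed by marker_id with columns gene_id, chromosome,
        position (1-based within-CDS), allele_states ("/"-joined observed
        states), order_index (plotting rank within chromosome). Optional
        extra columns (e.g. depth, qual) are carried through.
    calls : DataFrame markers x accessions of single-character states.
    """

    meta: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.meta)

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[1]

    def call_matrix(self) -> np.ndarray:
        """accessions x markers array of single-character states."""
        return self.calls.to_numpy(dtype="<U1").T

    def subset(self, marker_ids) -> "MarkerTable":
        """Row subset in original order; order_index is re-ranked within chromosome."""
        idx = [m for m in self.meta.index if m in set(marker_ids)]
        meta = self.meta.loc[idx].copy()
        if len(meta):
            rank = (
                meta.sort_values("order_index", kind="mergesort")
                .groupby("chromosome")
                .cumcount()
                + 1
            )
            meta["order_index"] = rank.reindex(meta.index)
        return MarkerTable(meta, self.calls.loc[idx].copy())

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.meta.index.duplicated().any():
            dup = self.meta.index[self.meta.index.duplicated()][0]
            raise ValidationError(f"duplicate marker_id {dup!r}")
        if not self.meta.index.equals(self.calls.index):
            raise ValidationError("meta and calls indexed by different markers")
        if len(self.meta) == 0:
            return
        for mid in self.meta.index:
            gene, pos, state = parse_marker_id(mid)
            if pos < 1:
                raise ValidationError(f"{mid}: position must be >= 1")
        if (self.meta["position"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based within-CDS)")
        arr = self.calls.to_numpy(dtype="<U1")
        bad = ~np.isin(arr, list(VALID_CALLS))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call {arr[i, j]!r} at marker {self.meta.index[i]!r}, "
                f"accession {self.calls.columns[j]!r}"
            )
        # every non-missing call must appear in the declared allele states
        for mid, states in self.meta["allele_states"].items():
            allowed = set(str(states).split("/")) | {MISSING}
            observed = set(self.calls.loc[mid])
            extra = observed - allowed
            if extra:
                raise ValidationError(f"{mid}: call(s) {sorted(extra)} not in allele_states {states!r}")
        # order_index must be a permutation within each chromosome
        for chrom, grp in self.meta.groupby("chromosome"):
            ranks = sorted(grp["order_index"])
            if ranks != list(range(1, len(grp) + 1)):
                raise ValidationError(f"order_index not a permutation of 1..n on {chrom}")


@dataclass
class ExpressionMatrix:
    """Nonnegative RPKM values, genes x accessions, with optional gene metadata."""

    rpkm: pd.DataFrame
    meta: pd.DataFrame | None = None  # optional: chromosome, order_index per gene

    def __post_init__(self) -> None:
        body = self.rpkm.to_numpy(dtype=float)
        if np.isfinite(body).all() and (body < 0).any():
            i, j = np.argwhere(body < 0)[0]
            raise ValidationError(
                f"negative RPKM {body[i, j]} for gene {self.rpkm.index[i]!r}"
            )
        if self.rpkm.index.duplicated().any():
            raise ValidationError("duplicate gene_id in expression matrix")
        if self.meta is not None:
            self.meta = self.meta.reindex(self.rpkm.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.rpkm.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.rpkm.columns)


@dataclass
class PhenotypeTable:
    """Trait values per accession, in days relative to the end of vernalisation.

    Negative values mean the stage was reached during pre-growth or
    vernalisation; NA means missing or never reached.
    """

    values: pd.DataFrame  # accessions x traits, float with NaN

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate accession row {dup!r}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate trait name")

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"unknown trait {name!r}")
        return self.values[name]


@dataclass
class QMatrix:
    """Per-accession ancestry proportions for K clusters; rows sum to 1."""

    proportions: pd.DataFrame  # accessions x K, columns Q1..QK

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if arr.size and (np.abs(arr.sum(axis=1) - 1.0) > 1e-9).any():
            bad = self.proportions.index[np.abs(arr.sum(axis=1) - 1.0) > 1e-9][0]
            raise ValidationError(f"ancestry row for {bad!r} does not sum to 1")
        if arr.size and ((arr < -1e-12) | (arr > 1 + 1e-12)).any():
            raise ValidationError("ancestry proportions outside [0, 1]")

    @property
    def k(self) -> int:
        return self.proportions.shape[1]

    @property
    def accessions(self) -> list[str]:
        return list(self.proportions.index)

    def to_array(self) -> np.ndarray:
        return self.proportions.to_numpy(dtype=float)


@dataclass
class AnnotationTable:
    """Per-gene chromosome/order plus optional genomic coordinates and orthologue labels."""

    table: pd.DataFrame  # indexed by gene_id

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r} in annotation")


ASSOCIATION_COLUMNS = [
    "unit_id",
    "chromosome",
    "order_index",
    "maf",
    "mean_rpkm",
    "n_used",
    "minus_log10_p",
    "marker_r2",
    "q_value",
    "model_tag",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MARKER_META_COLS = ["marker_id", "gene_id", "chromosome", "position", "allele_states"]


def _normalise_call(c: str) -> str:
    c = str(c).strip().upper()
    if c in ("-", "", "NA", "NAN"):
        return MISSING
    return c


def read_marker_table(path) -> MarkerTable:
    """Read a marker-call TSV.

    Expected columns: marker_id, gene_id, chromosome, position, allele_states,
    optionally order_index / depth / qual, then one column per accession.
    ``allele_states`` may be blank, in which case states are recomputed from
    the observed calls. "-" calls are normalised to N.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ("marker_id", "gene_id", "chromosome", "position") if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"marker table missing column(s) {missing_cols}")
    optional = [c for c in ("order_index", "depth", "qual") if c in df.columns]
    known = set(_MARKER_META_COLS) | set(optional)
    accession_cols = [c for c in df.columns if c not in known]
    if not accession_cols:
        raise ValidationError("marker table has no accession columns")

    for lineno, (mid, gene_col, pos_col) in enumerate(
        zip(df["marker_id"], df["gene_id"], df["position"]), start=2
    ):
        gene, pos, _ = _try_parse(mid, lineno)
        if gene != gene_col or pos != int(pos_col):
            raise ValidationError(
                f"line {lineno}: marker_id {mid!r} disagrees with gene_id/position columns"
            )

    calls = df[accession_cols].map(_normalise_call)
    empty_cell = (df[accession_cols] == "").any(axis=1)
    if empty_cell.any():
        lineno = int(np.argmax(empty_cell.to_numpy())) + 2
        raise ValidationError(f"line {lineno}: missing accession call cell")

    meta = pd.DataFrame(
        {
            "gene_id": df["gene_id"].to_numpy(),
            "chromosome": df["chromosome"].to_numpy(),
            "position": df["position"].astype(int).to_numpy(),
        },
        index=pd.Index(df["marker_id"], name="marker_id"),
    )
    calls.index = meta.index

    if "allele_states" in df.columns and (df["allele_states"] != "").all():
        meta["allele_states"] = df["allele_states"].to_numpy()
    else:
        meta["allele_states"] = [
            "/".join(sorted(set(calls.loc[mid]) - {MISSING})) for mid in meta.index
        ]
    if "order_index" in df.columns:
        meta["order_index"] = df["order_index"].astype(int).to_numpy()
    else:
        meta["order_index"] = (
            meta.groupby("chromosome").cumcount() + 1
        )  # file order within chromosome
    for col in ("depth", "qual"):
        if col in df.columns:
            meta[col] = pd.to_numeric(df[col]).to_numpy()
    return MarkerTable(meta, calls)


def _try_parse(marker_id: str, lineno: int) -> tuple[str, int, str]:
    try:
        return parse_marker_id(marker_id)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def write_marker_table(table: MarkerTable, path) -> None:
    out = table.meta.copy()
    out = out[[c for c in ("gene_id", "chromosome", "position", "allele_states", "order_index", "depth", "qual") if c in out.columns]]
    out = pd.concat([out, table.calls], axis=1)
    out.index.name = "marker_id"
    out.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x accessions RPKM TSV; optional chromosome/order_index meta columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in ("chromosome", "order_index") if c in df.columns]
    meta = df[meta_cols] if meta_cols else None
    body = df.drop(columns=meta_cols)
    body = body.astype(float)
    df.index.name = "gene_id"
    return ExpressionMatrix(body, meta)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.rpkm if expr.meta is None else pd.concat([expr.meta, expr.rpkm], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate accession row {dup!r}")
    return PhenotypeTable(df.astype(float))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    out = pheno.values.copy()
    out.index.name = "accession_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_qmatrix(path) -> QMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return QMatrix(df)


def write_qmatrix(q: QMatrix, path) -> None:
    out = q.proportions.copy()
    out.index.name = "accession_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, na_values=["NA"])
    return AnnotationTable(df)


def write_annotation(ann: AnnotationTable, path) -> None:
    out = ann.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def write_results(table: pd.DataFrame, path) -> None:
    """Write an association table as TSV: fixed column order, rows sorted by
    chromosome (C01..C09 then C00) then order_index, p to 6 significant digits."""
    cols = [c for c in ASSOCIATION_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    out = table[cols].copy()
    if len(out):
        key = out["chromosome"].map(lambda c: chromosome_sort_key(str(c)))
        out = out.iloc[np.lexsort((out["order_index"].to_numpy(), key.to_numpy()))]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in out.iterrows():
            cells = []
            for c in cols:
                v = row[c]
                if c in ("minus_log10_p", "marker_r2", "q_value", "maf", "mean_rpkm") and pd.notna(v):
                    cells.append(f"{float(v):.6g}")
                elif pd.isna(v):
                    cells.append("NA")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# VCF import (biallelic SNPs only)
# ---------------------------------------------------------------------------

def read_vcf(path) -> MarkerTable:
    """Import biallelic SNPs from a (plain-text) VCF as IUPAC-coded calls.

    GT 0/0 -> ref homozygote, 1/1 -> alt homozygote, 0/1 or 1/0 -> the
    ambiguity code for the ref/alt pair, missing -> N. Multi-allelic or
    non-SNP records are skipped. Gene id is taken from the CHROM field and
    the marker id is synthesised as ``CHROM:POS:ALT``.
    """
    rows = []
    samples: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1 or alt == "." or "," in alt:
                continue
            het = PAIR_TO_CODE.get(frozenset((ref, alt)))
            calls = []
            for sample in fields[9:]:
                gt = sample.split(":")[0].replace("|", "/")
                if gt in ("0/0", "0"):
                    calls.append(ref)
                elif gt in ("1/1", "1"):
                    calls.append(alt)
                elif gt in ("0/1", "1/0"):
                    calls.append(het if het else MISSING)
                else:
                    calls.append(MISSING)
            rows.append((chrom, pos, ref, alt, calls))
    if not samples:
        raise ValidationError("VCF has no #CHROM header line")
    meta_rows, call_rows, index = [], [], []
    for chrom, pos, ref, alt, calls in rows:
        mid = f"{chrom}:{pos}:{alt}"
        states = sorted(set(calls) - {MISSING})
        index.append(mid)
        meta_rows.append(
            {"gene_id": chrom, "chromosome": "C00", "position": pos, "allele_states": "/".join(states)}
        )
        call_rows.append(calls)
    meta = pd.DataFrame(meta_rows, index=pd.Index(index, name="marker_id"))
    meta["order_index"] = range(1, len(meta) + 1)
    calls_df = pd.DataFrame(call_rows, index=meta.index, columns=samples)
    return MarkerTable(meta, calls_df)


# ---------------------------------------------------------------------------
# alignment of accession sets
# ---------------------------------------------------------------------------

def align_accessions(geno: MarkerTable, *others):
    """Re-index companion tables to the marker table's accession order.

    The marker table's column order is canonical. Raises if any companion
    covers a different accession *set*.
    """
    ref = geno.accessions
    aligned = []
    for other in others:
        if isinstance(other, ExpressionMatrix):
            have = set(other.accessions)
            if have != set(ref):
                raise ValidationError("expression accession set differs from marker table")
            aligned.append(ExpressionMatrix(other.rpkm[ref], other.meta))
        elif isinstance(other, PhenotypeTable):
            if set(other.accessions) != set(ref):
                raise ValidationError("phenotype accession set differs from marker table")
            aligned.append(PhenotypeTable(other.values.loc[ref]))
        elif isinstance(other, QMatrix):
            if set(other.accessions) != set(ref):
                raise ValidationError("Q matrix accession set differs from marker table")
            aligned.append(QMatrix(other.proportions.loc[ref]))
        else:
            raise TypeError(f"cannot align object of type {type(other).__name__}")
    return aligned[0] if len(aligned) == 1 else tuple(aligned)
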