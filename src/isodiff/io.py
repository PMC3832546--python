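"""File formats: annotation (GTF / refFlat), read-category tables,
junction-count tables, result tables, and an optional SAM/BAM path.

The canonical machine-readable exchange format for reduced read evidence
is a TSV with one row per read category plus one totals row per
gene/condition:

    gene_id  condition  row_type  count  rate_1 ... rate_N

``row_type`` is ``category`` (count = reads in the category, rate_i = the
category rate vector) or ``totals`` (count = total mapped reads, rate_i =
the per-isoform total sampling rates a_i).  Genes with fewer isoforms
than the widest gene in the file pad trailing rate columns with NA.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import Footprint, GeneModel, ReadCategoryTable
from .model_selection import GeneResult
from .ranking import JunctionTriplet

logger = logging.getLogger(__name__)

__all__ = [
    "read_annotation",
    "read_gtf",
    "read_refflat",
    "read_category_table",
    "write_category_table",
    "read_junction_table",
    "results_to_frame",
    "write_results",
    "count_read_types_from_sam",
]

_NA = "NA"


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str, format: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF or refFlat file.

    ``format`` is ``"gtf"`` or ``"refflat"``; by default it is inferred
    from the file extension (``.gtf`` → GTF, anything else → refFlat).
    Genes are returned in deterministic (first-appearance) order.
    """
    if format is None:
        format = "gtf" if str(path).lower().endswith((".gtf", ".gtf.txt")) else "refflat"
    if format == "gtf":
        return read_gtf(path)
    if format == "refflat":
        return read_refflat(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _assemble_genes(
    transcripts: "dict[str, list[tuple[str, str, list[tuple[int, int]]]]]",
) -> list[GeneModel]:
    """Build GeneModels from per-gene lists of (tx_id, strand, exon list)."""
    genes = []
    for gene_id, txs in transcripts.items():
        exon_set: set[tuple[int, int]] = set()
        kept = []
        for tx_id, strand, exons in txs:
            if not exons:
                warnings.warn(
                    f"transcript {tx_id} of gene {gene_id} has no exons; skipped",
                    stacklevel=3,
                )
                continue
            exons = sorted(exons)
            exon_set.update(exons)
            kept.append((tx_id, strand, exons))
        if not kept:
            continue
        ordered = sorted(exon_set)
        index = {e: i for i, e in enumerate(ordered)}
        strand = kept[0][1] if len({s for _, s, _ in kept}) == 1 else "."
        isoforms = tuple(
            (tx_id, tuple(index[e] for e in exons)) for tx_id, _, exons in kept
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                exons=tuple(ordered),
                isoforms=isoforms,
                strand=strand if strand in {"+", "-"} else ".",
            )
        )
    return genes


def read_gtf(path: str) -> list[GeneModel]:
    """Parse exon features of a GTF file, grouped by transcript and gene.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open on read.  A malformed line raises with its line number.
    """
    import gffutils

    with open(path) as fh:
        lines = fh.readlines()
    for ln, line in enumerate(lines, 1):
        if line.startswith("#") or not line.strip():
            continue
        if len(line.rstrip("\n").split("\t")) != 9:
            raise ValueError(f"{path}: malformed GTF line {ln} (expected 9 fields)")
    if not any(ln.strip() and not ln.startswith("#") for ln in lines):
        warnings.warn(f"{path}: empty annotation", stacklevel=2)
        return []
    db = gffutils.create_db(
        "".join(lines),
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts: dict[str, list] = {}
    tx_order: dict[tuple[str, str], list[tuple[int, int]]] = {}
    tx_meta: dict[tuple[str, str], str] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("gene_id", ["?"])[0]
        tx_id = feat.attributes.get("transcript_id", ["?"])[0]
        key = (gene_id, tx_id)
        tx_order.setdefault(key, []).append((feat.start - 1, feat.end))
        tx_meta[key] = feat.strand or "."
    for (gene_id, tx_id), exons in tx_order.items():
        transcripts.setdefault(gene_id, []).append(
            (tx_id, tx_meta[(gene_id, tx_id)], exons)
        )
    return _assemble_genes(transcripts)


_REFFLAT_COLS = [
    "geneName",
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
]


def read_refflat(path: str) -> list[GeneModel]:
    """Read a refFlat-style tab-separated annotation (UCSC convention,
    0-based half-open exon coordinates in comma-terminated lists)."""
    try:
        df = pd.read_csv(
            path, sep="\t", names=_REFFLAT_COLS, comment="#", header=None,
            dtype=str, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty annotation", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty annotation", stacklevel=2)
        return []
    transcripts: dict[str, list] = {}
    for ln, row in enumerate(df.itertuples(index=False), 1):
        try:
            n = int(row.exonCount)
            s_str = str(row.exonStarts).strip(",")
            e_str = str(row.exonEnds).strip(",")
            starts = [int(x) for x in s_str.split(",")] if s_str else []
            ends = [int(x) for x in e_str.split(",")] if e_str else []
            if len(starts) != n or len(ends) != n:
                raise ValueError("exonCount disagrees with exon lists")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed refFlat line {ln}: {exc}") from None
        transcripts.setdefault(row.geneName, []).append(
            (row.name, row.strand, list(zip(starts, ends)))
        )
    return _assemble_genes(transcripts)


# ---------------------------------------------------------------------------
# read-category tables


def write_category_table(
    path: str,
    tables: Mapping[str, Mapping[str, ReadCategoryTable]],
) -> None:
    """Write per-gene, per-condition category tables to the TSV format."""
    width = max(
        (t.n_isoforms for conds in tables.values() for t in conds.values()),
        default=0,
    )
    cols = ["gene_id", "condition", "row_type", "count"] + [
        f"rate_{i + 1}" for i in range(width)
    ]
    rows = []

    def pad(vec):
        out = [f"{v:.6g}" for v in vec]
        return out + [_NA] * (width - len(out))

    for gene_id, conds in tables.items():
        for cond, t in conds.items():
            for c, r in zip(t.counts, t.rates):
                rows.append([gene_id, cond, "category", f"{c:.6g}", *pad(r)])
            rows.append(
                [gene_id, cond, "totals", str(int(t.total_reads_mapped)),
                 *pad(t.isoform_totals)]
            )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_category_table(
    path: str,
    annotation: Sequence[GeneModel] | None = None,
) -> dict[str, dict[str, ReadCategoryTable]]:
    """Read the category TSV back into nested ``{gene: {condition: table}}``.

    Duplicate category rows (identical rate vectors) are merged
    defensively with summed counts.  If ``annotation`` is given, each
    gene's rate-vector length is validated against its isoform count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition": str})
    rate_cols = [c for c in df.columns if c.startswith("rate_")]
    iso_count = {g.gene_id: g.n_isoforms for g in annotation} if annotation else None
    out: dict[str, dict[str, ReadCategoryTable]] = {}
    for (gene_id, cond), grp in df.groupby(["gene_id", "condition"], sort=False):
        rates_full = grp[rate_cols].to_numpy(dtype=float)
        n_iso = int((~np.isnan(rates_full)).all(axis=0).sum())
        if np.isnan(rates_full[:, :n_iso]).any():
            raise ValueError(f"gene {gene_id}: ragged rate columns")
        if iso_count is not None:
            expected = iso_count.get(gene_id)
            if expected is not None and expected != n_iso:
                raise ValueError(
                    f"gene {gene_id}: table has {n_iso} rate columns but the "
                    f"annotation defines {expected} isoforms"
                )
        cats = grp[grp["row_type"] == "category"]
        tot = grp[grp["row_type"] == "totals"]
        if len(tot) != 1:
            raise ValueError(f"gene {gene_id}, condition {cond}: need exactly one totals row")
        counts = cats["count"].to_numpy(dtype=float)
        if np.any(counts < 0):
            raise ValueError(f"gene {gene_id}: negative category count")
        rates = cats[rate_cols].to_numpy(dtype=float)[:, :n_iso]
        # defensive re-grouping: merge duplicate rate vectors
        merged: dict[tuple, float] = {}
        for c, r in zip(counts, rates):
            key = tuple(r)
            merged[key] = merged.get(key, 0.0) + c
        keys = sorted(merged)
        out.setdefault(gene_id, {})[cond] = ReadCategoryTable(
            condition_id=str(cond),
            counts=np.array([merged[k] for k in keys]),
            rates=np.array(keys).reshape(len(keys), n_iso)
            if keys
            else np.zeros((0, n_iso)),
            isoform_totals=tot[rate_cols].to_numpy(dtype=float)[0, :n_iso],
            total_reads_mapped=int(tot["count"].iloc[0]),
        )
    return out


def read_junction_table(path: str) -> pd.DataFrame:
    """Read a junction-count TSV (exon_id, condition, UJC, DJC, SJC)."""
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str, "condition": str})
    required = {"exon_id", "condition", "UJC", "DJC", "SJC"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# results


def _fmt(x) -> str:
    if x is None:
        return _NA
    if isinstance(x, float) and not np.isfinite(x):
        return _NA
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def results_to_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    """Flatten GeneResults into a table: one row per gene with the
    log-likelihoods, hLRT p-values, T, and per-condition isoform
    abundance estimates with CI bounds for the selected model."""
    width = 0
    K = 0
    for r in results:
        if r.estimates is not None:
            K = max(K, r.estimates[2].n_conditions)
            width = max(width, r.estimates[2].n_isoforms)
    rows = []
    for r in results:
        row: dict[str, object] = {
            "gene_id": r.gene_id,
            "status": "ok" if isinstance(r.selected_model, int) else r.selected_model,
            "selected_model": r.selected_model,
            "l0": np.nan,
            "l1": np.nan,
            "l2": np.nan,
            "p01": r.pvalues[0],
            "p02": r.pvalues[1],
            "p12": r.pvalues[2],
            "T": r.T,
            "boundary": r.boundary,
        }
        if r.estimates is not None:
            row["l0"] = r.estimates[0].loglik
            row["l1"] = r.estimates[1].loglik
            row["l2"] = r.estimates[2].loglik
            sel = r.selected_model if isinstance(r.selected_model, int) else 2
            theta = r.estimates[sel].theta
            ci = None
            if r.intervals is not None:
                if "theta" in r.intervals:
                    ci = r.intervals["theta"]
                elif "theta_tilde" in r.intervals:
                    ci = np.tile(r.intervals["theta_tilde"], (theta.shape[0], 1, 1))
            for k in range(theta.shape[0]):
                for i in range(theta.shape[1]):
                    row[f"theta_c{k + 1}_i{i + 1}"] = theta[k, i]
                    if ci is not None:
                        row[f"ci_lo_c{k + 1}_i{i + 1}"] = ci[k, i, 0]
                        row[f"ci_hi_c{k + 1}_i{i + 1}"] = ci[k, i, 1]
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(path: str, results: Sequence[GeneResult]) -> None:
    """Write the result table as TSV (floats at 6 significant digits,
    missing values spelled NA)."""
    df = results_to_frame(results)
    out = df.map(_fmt)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# optional alignment path


def count_read_types_from_sam(
    path: str, gene: GeneModel, read_length: int
) -> dict[Footprint, int]:
    """Count observed read types from primary single-end alignments.

    A read's footprint is the tuple of its aligned reference blocks.
    Soft-clipped or partially mapped reads are skipped; paired-end input
    raises (the paired-end insert-length sampling model is unsupported).
    Footprints are returned verbatim; matching against the gene's
    enumerated read types happens in ``reduce_to_categories``.
    """
    import pysam

    counts: dict[Footprint, int] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                raise ValueError(
                    "unsupported sampling model: paired-end alignments "
                    "(only single-end uniform sampling is implemented)"
                )
            cigar = read.cigartuples or []
            if any(op in (4, 5) for op, _ in cigar):  # soft/hard clip
                continue
            if read.query_length and read.query_length != read_length:
                continue
            fp = tuple((int(s), int(e)) for s, e in read.get_blocks())
            if not fp:
                continue
            counts[fp] = counts.get(fp, 0) + 1
    return counts
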