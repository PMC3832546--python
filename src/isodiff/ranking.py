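"""Ranking of differentially spliced genes and junction-based exon
inclusion levels (ψ).

The ranking statistic for a two-condition comparison is

    T = ½ · ‖ θ₁/‖θ₁‖₁ − θ₂/‖θ₂‖₁ ‖₁  ∈ [0, 1],

half the L1 distance between the L1-normalized isoform abundance vectors;
T = 0 whenever the two vectors are proportional (the model-0/model-1
case), and 1 for disjoint isoform usage.

For a cassette exon with junction read counts UJC (upstream inclusion),
DJC (downstream inclusion) and SJC (skipping), the event is recast as a
two-isoform gene — the inclusion "isoform" made of the two junction
regions, the skipping "isoform" of one — and the inclusion level is the
abundance fraction of the inclusion isoform:

    ψ̂ = (UJC + DJC) / ((UJC + DJC) + 2·SJC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .gene_model import GeneModel
    from .model_selection import GeneResult

__all__ = [
    "JunctionTriplet",
    "t_statistic",
    "rank_genes",
    "psi_from_junctions",
    "junction_category_table",
    "delta_psi",
    "psi_from_isoforms",
]

DEFAULT_JUNCTION_LENGTH = 84


@dataclass(frozen=True)
class JunctionTriplet:
    """Junction read counts for one cassette-exon event.

    ``junction_length`` is the length of each hypothetical junction
    "exon" (84 bp by convention); it cancels in ψ̂ but fixes the scale of
    the recovered abundances.
    """

    exon_id: str
    UJC: int
    DJC: int
    SJC: int
    junction_length: int = DEFAULT_JUNCTION_LENGTH

    def __post_init__(self):
        for name in ("UJC", "DJC", "SJC"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.junction_length < 1:
            raise ValueError("junction_length must be positive")


def t_statistic(theta_1: Sequence[float], theta_2: Sequence[float]) -> float:
    """Half the L1 distance between L1-normalized abundance vectors.

    Returns NaN (with a warning) if either vector is all zero.
    """
    t1 = np.asarray(theta_1, dtype=float)
    t2 = np.asarray(theta_2, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("abundance vectors must have the same length")
    if np.any(t1 < 0) or np.any(t2 < 0):
        raise ValueError("abundances must be non-negative")
    s1, s2 = t1.sum(), t2.sum()
    if s1 == 0 or s2 == 0:
        warnings.warn("T undefined for an all-zero abundance vector", stacklevel=2)
        return float("nan")
    return 0.5 * float(np.abs(t1 / s1 - t2 / s2).sum())


def rank_genes(results: Sequence["GeneResult"], by: str = "T") -> list["GeneResult"]:
    """Order genes by differential-splicing evidence.

    ``by="T"`` sorts descending on the T statistic (two-condition analyses
    only); ``by="pvalue"`` ascending on the model-0-vs-2 p-value.  Model-0
    and filtered genes sink to the bottom, NA values last within their
    block, ties broken by gene_id.
    """
    if by not in {"T", "pvalue"}:
        raise ValueError("by must be 'T' or 'pvalue'")
    results = list(results)
    if by == "T":
        for r in results:
            if r.estimates is not None and r.estimates[2].n_conditions != 2:
                raise ValueError("T-ranking is defined only for two conditions")

    def key(r: "GeneResult"):
        tested = isinstance(r.selected_model, int)
        eligible = tested and r.selected_model in (1, 2)
        if by == "T":
            v = r.T if tested else np.nan
            missing = not np.isfinite(v if v is not None else np.nan)
            return (not eligible, missing, -(0.0 if missing else v), r.gene_id)
        p = r.pvalues[1] if tested else np.nan
        missing = not np.isfinite(p)
        return (not eligible, missing, 0.0 if missing else p, r.gene_id)

    return sorted(results, key=key)


def psi_from_junctions(j: JunctionTriplet) -> tuple[float, float, float]:
    """(θ̂_inclusion, θ̂_skipping, ψ̂) from a junction-count triplet.

    The maximum-likelihood fit of the constructed two-isoform gene has a
    closed form: with unit depth scale and read length equal to the
    junction length, each junction region carries exactly one read type,
    so θ̂_long = (UJC+DJC)/2 (two isoform-specific read types) and
    θ̂_short = SJC.  All-zero counts give ψ = NaN.
    """
    total = j.UJC + j.DJC + j.SJC
    if total == 0:
        return 0.0, 0.0, float("nan")
    theta_long = (j.UJC + j.DJC) / 2.0
    theta_short = float(j.SJC)
    psi = (j.UJC + j.DJC) / ((j.UJC + j.DJC) + 2.0 * j.SJC)
    return theta_long, theta_short, psi


def junction_category_table(j: JunctionTriplet, condition_id: str = "junctions"):
    """Read-category table of the hypothetical two-isoform gene behind
    :func:`psi_from_junctions`.

    The inclusion isoform carries the upstream and downstream junction
    windows (two read types, total sampling rate 2 at unit depth scale);
    the skipping isoform the skipping window (one read type, rate 1).
    The two inclusion read types share the compatibility pattern and merge
    into one category.  Fitting this table under the free model recovers
    θ̂_long = (UJC+DJC)/2 and θ̂_short = SJC.
    """
    from .gene_model import ReadCategoryTable

    counts, rates = [], []
    if j.UJC + j.DJC > 0:
        counts.append(j.UJC + j.DJC)
        rates.append([2.0, 0.0])
    if j.SJC > 0:
        counts.append(j.SJC)
        rates.append([0.0, 1.0])
    return ReadCategoryTable(
        condition_id=condition_id,
        counts=np.array(counts, dtype=float),
        rates=np.array(rates, dtype=float).reshape(len(counts), 2),
        isoform_totals=np.array([2.0, 1.0]),
        total_reads_mapped=j.UJC + j.DJC + j.SJC,
    )


def delta_psi(psi_cond1: float, psi_cond2: float) -> float:
    """Between-condition difference of exon inclusion, ψ₁ − ψ₂ (NaN
    propagates)."""
    return float(psi_cond1) - float(psi_cond2)


def psi_from_isoforms(
    gene: "GeneModel", exon_index: int, theta: Sequence[float]
) -> float:
    """Inclusion level of one exon from full-length isoform abundances.

    ψ is the abundance fraction of the isoforms containing the exon, over
    all isoforms of the gene.  Returns NaN when the exon is in all or in
    none of the isoforms (not an inclusion event) or when all abundances
    are zero.
    """
    th = np.asarray(theta, dtype=float)
    if th.shape != (gene.n_isoforms,):
        raise ValueError("theta length must equal the number of isoforms")
    if np.any(th < 0):
        raise ValueError("abundances must be non-negative")
    if not 0 <= exon_index < len(gene.exons):
        raise ValueError(f"exon index {exon_index} out of range")
    contains = np.array(
        [exon_index in idx for _, idx in gene.isoforms], dtype=bool
    )
    if contains.all() or not contains.any():
        return float("nan")
    total = th.sum()
    if total == 0:
        return float("nan")
    return float(th[contains].sum() / total)
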