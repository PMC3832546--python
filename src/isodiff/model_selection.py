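"""Per-gene classification into the three nested models by a hierarchical
likelihood ratio test (hLRT).

The first round runs two parallel tests at level α/2: model 0 vs model 1
(χ², K−1 df) and model 0 vs model 2 (χ², (K−1)·I df).  If neither is
significant the gene is called model 0; if exactly one is, that model is
selected.  If both are, a second-round test of model 1 vs model 2 at level
α ((K−1)·(I−1) df) decides between differential expression and
differential splicing.

Genes with fewer than ``min_reads`` mapped reads in *every* condition are
filtered out before testing (default 5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .estimation import (
    AbundanceEstimate,
    confidence_intervals,
    fit_model0,
    fit_model1,
    fit_model2,
)
from .gene_model import ReadCategoryTable
from .ranking import t_statistic

logger = logging.getLogger(__name__)

__all__ = [
    "GeneResult",
    "DifferentialSplicingAnalysis",
    "filter_low_count",
    "hlrt",
    "hlrt_degrees_of_freedom",
    "run_all_genes",
]

_CLAMP_WARN = 1e-6


@dataclass
class GeneResult:
    """Outcome of the hLRT for one gene."""

    gene_id: str
    selected_model: int | str  # 0, 1, 2, "filtered" or "NA"
    lrt_stats: tuple[float, float, float]  # Λ01, Λ02, Λ12
    pvalues: tuple[float, float, float]  # p01, p02, p12 (NaN if not reached)
    alpha: float
    estimates: dict[int, AbundanceEstimate] | None = None
    T: float = np.nan
    intervals: dict[str, np.ndarray] | None = None
    boundary: bool = False
    message: str = ""


def hlrt_degrees_of_freedom(K: int, I: int) -> tuple[int, int, int]:
    """Degrees of freedom for the three LRTs: (K−1, (K−1)·I, (K−1)·(I−1))."""
    return K - 1, (K - 1) * I, (K - 1) * (I - 1)


def filter_low_count(
    tables: Sequence[ReadCategoryTable], min_reads: int = 5
) -> bool:
    """True (keep) unless every condition has fewer than ``min_reads``
    mapped reads for the gene."""
    return any(t.total_count >= min_reads for t in tables)


def _clamped(stat: float, label: str) -> float:
    if stat < 0:
        if stat < -_CLAMP_WARN:
            logger.warning(
                "negative LRT statistic %s = %.3g clamped to 0 "
                "(possible non-convergence)",
                label,
                stat,
            )
        return 0.0
    return stat


def hlrt(
    fits: Mapping[int, AbundanceEstimate] | Sequence[AbundanceEstimate],
    alpha: float,
    gene_id: str = "",
) -> GeneResult:
    """Select among the three nested models for one gene.

    ``fits`` supplies the converged estimates for models 0, 1 and 2.
    Negative LRT statistics from numerical noise are clamped to zero.
    When I = 1 models 1 and 2 coincide (second-round df would be 0); the
    second round then resolves to model 1 and p12 is NA.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not isinstance(fits, Mapping):
        fits = {e.model_id: e for e in fits}
    e0, e1, e2 = fits[0], fits[1], fits[2]
    K, I = e2.theta.shape
    if K < 2:
        raise ValueError("the hLRT requires at least two conditions")
    df01, df02, df12 = hlrt_degrees_of_freedom(K, I)
    lam01 = _clamped(-2.0 * (e0.loglik - e1.loglik), "-2(l0-l1)")
    lam02 = _clamped(-2.0 * (e0.loglik - e2.loglik), "-2(l0-l2)")
    lam12 = _clamped(-2.0 * (e1.loglik - e2.loglik), "-2(l1-l2)")
    p01 = float(stats.chi2.sf(lam01, df01))
    p02 = float(stats.chi2.sf(lam02, df02))
    sig01 = lam01 > stats.chi2.ppf(1 - alpha / 2, df01)
    sig02 = lam02 > stats.chi2.ppf(1 - alpha / 2, df02)
    p12 = np.nan
    if not sig01 and not sig02:
        selected = 0
    elif sig01 != sig02:
        selected = 1 if sig01 else 2
    else:  # second round
        if df12 == 0:
            selected = 1  # I == 1: models 1 and 2 are identical
        else:
            p12 = float(stats.chi2.sf(lam12, df12))
            selected = 2 if lam12 > stats.chi2.ppf(1 - alpha, df12) else 1
    return GeneResult(
        gene_id=gene_id,
        selected_model=selected,
        lrt_stats=(lam01, lam02, lam12),
        pvalues=(p01, p02, p12),
        alpha=alpha,
        estimates={0: e0, 1: e1, 2: e2},
        boundary=any(e.boundary for e in (e0, e1, e2)),
    )


class DifferentialSplicingAnalysis(BaseEstimator):
    """Fit all three abundance models per gene and classify by the hLRT.

    Parameters
    ----------
    alpha : float
        Overall significance level of the hierarchical test (default 0.05).
    min_reads : int
        Low-count filter: genes with fewer reads than this in every
        condition are reported as ``"filtered"`` without testing.
    tol, max_iter : EM convergence controls.
    ci_level : float or None
        If set, attach Wald confidence intervals for the selected model.

    Attributes
    ----------
    results_ : list of GeneResult, in input (annotation) order.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        min_reads: int = 5,
        tol: float = 1e-10,
        max_iter: int = 10000,
        ci_level: float | None = 0.95,
    ):
        self.alpha = alpha
        self.min_reads = min_reads
        self.tol = tol
        self.max_iter = max_iter
        self.ci_level = ci_level

    def fit(
        self,
        genes: Iterable[tuple[str, Sequence[ReadCategoryTable]]],
        y=None,
    ) -> "DifferentialSplicingAnalysis":
        genes = list(genes)
        if not genes:
            warnings.warn("empty dataset: no genes to analyse", stacklevel=2)
        seen: set[str] = set()
        results: list[GeneResult] = []
        for gene_id, tables in genes:
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            results.append(self._one_gene(gene_id, list(tables)))
        self.results_ = results
        return self

    def _one_gene(self, gene_id, tables) -> GeneResult:
        nan3 = (np.nan, np.nan, np.nan)
        if not filter_low_count(tables, self.min_reads):
            return GeneResult(
                gene_id, "filtered", nan3, nan3, self.alpha,
                message=f"fewer than {self.min_reads} reads in all conditions",
            )
        try:
            e0 = fit_model0(tables, self.tol, self.max_iter)
            e1 = fit_model1(tables, self.tol, self.max_iter)
            e2 = fit_model2(tables, self.tol, self.max_iter)
            res = hlrt({0: e0, 1: e1, 2: e2}, self.alpha, gene_id)
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("gene %s failed: %s", gene_id, exc)
            return GeneResult(gene_id, "NA", nan3, nan3, self.alpha, message=str(exc))
        # T is identically 0 for model-0/1 calls; meaningful only for K=2
        if res.selected_model == 2:
            if e2.n_conditions == 2:
                res.T = t_statistic(e2.theta[0], e2.theta[1])
        else:
            res.T = 0.0
        if self.ci_level is not None:
            sel = res.selected_model if isinstance(res.selected_model, int) else 2
            res.intervals = confidence_intervals(
                res.estimates[sel], tables, self.ci_level
            )
        return res


def run_all_genes(
    genes: Iterable[tuple[str, Sequence[ReadCategoryTable]]],
    alpha: float = 0.05,
    min_reads: int = 5,
    **kwargs,
) -> list[GeneResult]:
    """Classify every gene; deterministic iteration in the given
    (annotation) order.  Per-gene failures are reported with
    ``selected_model = "NA"`` instead of aborting the run."""
    ana = DifferentialSplicingAnalysis(alpha=alpha, min_reads=min_reads, **kwargs)
    return ana.fit(genes).results_
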