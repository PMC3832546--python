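"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from isodiff import GeneModel, ReadCategoryTable, default_sim_gene
from isodiff.estimation import loglik


@pytest.fixture
def sim_gene() -> GeneModel:
    """The cassette-exon simulation gene: exons 1200/60/600, isoform A
    includes all three, isoform B skips the middle one."""
    return default_sim_gene()


@pytest.fixture
def single_exon_gene() -> GeneModel:
    return GeneModel("g1", exons=((0, 100),), isoforms=(("t1", (0,)),))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_read_types(gene: GeneModel, read_length: int):
    """Independent footprint enumeration: materialize every transcript as
    its list of genomic base coordinates, slice out each read window and
    regroup into runs of consecutive bases."""
    compat: dict[tuple, set[int]] = {}
    for i in range(gene.n_isoforms):
        bases: list[int] = []
        for s, e in gene.isoform_exons(i):
            bases.extend(range(s, e))
        for start in range(len(bases) - read_length + 1):
            window = bases[start : start + read_length]
            runs = []
            run_start = window[0]
            prev = window[0]
            for b in window[1:]:
                if b != prev + 1:
                    runs.append((run_start, prev + 1))
                    run_start = b
                prev = b
            runs.append((run_start, prev + 1))
            compat.setdefault(tuple(runs), set()).add(i)
    return compat


def optimizer_loglik(tables, model: int, n_starts: int = 6, seed: int = 0) -> float:
    """Generic numerical maximization of the model log-likelihood,
    independent of the EM path: L-BFGS-B on log-transformed parameters
    (which handles the non-negativity constraint and the model-1 scale
    ridge), multiple starts, best value kept."""
    I = tables[0].n_isoforms
    K = len(tables)
    rng = np.random.default_rng(seed)
    LOG_LO, LOG_HI = -30.0, 30.0

    def neg(y):
        x = np.exp(y)
        if model == 0:
            th = np.tile(x, (K, 1))
        elif model == 2:
            th = x.reshape(K, I)
        else:  # model 1: x = (theta_tilde, tau)
            th = np.outer(x[I:], x[:I])
        val = sum(loglik(th[k], t) for k, t in enumerate(tables))
        return -val if np.isfinite(val) else 1e300

    dim = {0: I, 1: I + K, 2: K * I}[model]
    scale = max(sum(t.total_count for t in tables), 1.0) / max(
        sum(t.isoform_totals.sum() for t in tables), 1.0
    )
    best = np.inf
    for s in range(n_starts):
        x0 = np.full(dim, scale) if s == 0 else rng.uniform(0.1, 3.0, dim) * scale
        if model == 1:
            x0[I:] = 1.0 if s == 0 else rng.uniform(0.3, 3.0, K)
        res = minimize(
            neg, np.clip(np.log(x0), LOG_LO, LOG_HI), method="L-BFGS-B",
            bounds=[(LOG_LO, LOG_HI)] * dim,
            options={"maxiter": 4000, "ftol": 1e-14, "gtol": 1e-12},
        )
        best = min(best, res.fun)
    return -best


def random_instance(rng: np.random.Generator, K=None, I=None, J=None):
    """A small random multi-condition category-table instance with counts
    drawn from the Poisson model at a random true abundance vector."""
    K = K or rng.integers(2, 4)
    I = I or rng.integers(1, 4)
    J = J or rng.integers(1, 7)
    tables = []
    theta_true = rng.uniform(0.5, 5.0, size=I)
    for k in range(K):
        rates = rng.uniform(0.2, 2.0, size=(J, I))
        # sparsify some entries to create isoform-specific categories
        rates *= rng.random(size=(J, I)) > 0.3
        # every category must touch at least one isoform
        for j in range(J):
            if not rates[j].any():
                rates[j, rng.integers(I)] = rng.uniform(0.2, 2.0)
        totals = rates.sum(axis=0) + rng.uniform(0.0, 1.0, size=I)
        mu = rates @ (theta_true * rng.uniform(0.5, 2.0))
        counts = rng.poisson(mu * 5).astype(float)
        keep = counts > 0
        if not keep.any():
            keep[0] = True
            counts[0] = 1.0
        tables.append(
            ReadCategoryTable(
                condition_id=f"c{k}",
                counts=counts[keep],
                rates=rates[keep].reshape(int(keep.sum()), I),
                isoform_totals=totals,
                total_reads_mapped=int(counts.sum()),
            )
        )
    return tables, theta_true
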