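"""Scikit-learn-style estimators for statistical epistasis networks.

:class:`InformationGainScorer` is the exhaustive scoring engine: ``fit(X, y)``
on an ``n x m`` genotype matrix and a binary phenotype computes the mutual
information I(A;C) of every SNP with the class and the information gain
IG(A;B;C) of every unordered SNP pair. :class:`StatisticalEpistasisNetwork`
wraps the whole pipeline — scoring, phenotype-permutation null, per-pair and
per-property p-values, a threshold sweep, and the topology report — behind a
single ``fit``. Both follow sklearn conventions (``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and compose
with sklearn tooling.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import xlogy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import GenotypeDataset
from .infotheory import PairWeightTable, _log_base

__all__ = ["InformationGainScorer", "StatisticalEpistasisNetwork"]


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d genotype matrix")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match the number of rows of X")
    if not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotypes must be 0/1/2 with no missing values; "
                         "impute first")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")
    return X.astype(np.int8, copy=False), y.astype(np.int8, copy=False)


def _mi_from_cells(cells: np.ndarray, n: int, log_b: float) -> np.ndarray:
    """Plug-in I(X;C) for a batch of (k, g, 2) genotype-by-class counts."""
    rows = cells.sum(axis=2)
    cols = cells.sum(axis=1)
    val = (
        xlogy(cells, cells).sum(axis=(1, 2))
        - xlogy(rows, rows).sum(axis=1)
        - xlogy(cols, cols).sum(axis=1)
        + xlogy(n, n)
    ) / (n * math.log(log_b))
    return np.where((val < 0) & (val > -1e-12), 0.0, val)


class InformationGainScorer(BaseEstimator):
    """Exhaustive entropy-based main-effect and pairwise-interaction scorer.

    Parameters
    ----------
    base : {2, 'e', 'bits', 'nats'}, default=2
        Logarithm base; all weights (and any thresholds applied to them) are
        in the corresponding unit.
    compute_pairs : bool, default=True
        Also score all m(m-1)/2 unordered SNP pairs. Scoring is chunked one
        anchor SNP at a time so memory stays O(pairs) for the weights, never
        O(pairs x individuals).

    Attributes
    ----------
    main_effects_ : pandas.Series
        I(A;C) per SNP, indexed by SNP id.
    pair_weights_ : PairWeightTable or None
        IG(A;B;C) for every unordered pair (condensed storage).
    class_entropy_ : float
        H(C) of the phenotype, an upper bound for every I(·;C).
    n_features_in_ : int
    """

    def __init__(self, base=2, compute_pairs: bool = True) -> None:
        self.base = base
        self.compute_pairs = compute_pairs

    def fit(self, X, y, snp_ids: list[str] | None = None):
        X, y = _validate_xy(X, y)
        n, m = X.shape
        log_b = _log_base(self.base)
        ids = list(snp_ids) if snp_ids is not None else [
            f"snp{k:05d}" for k in range(m)]
        if len(ids) != m:
            raise ValueError("snp_ids length must match number of columns")

        # single-SNP 3x2 tables, all SNPs at once
        flat = (6 * np.arange(m))[None, :] + 2 * X.astype(np.int64) + y[:, None]
        cells = np.bincount(flat.ravel(), minlength=6 * m).reshape(m, 3, 2)
        mains = _mi_from_cells(cells.astype(float), n, log_b)

        n1 = int(y.sum())
        p1 = n1 / n
        self.class_entropy_ = float(
            -(xlogy(p1, p1) + xlogy(1 - p1, 1 - p1)) / math.log(log_b))
        self.main_effects_ = pd.Series(mains, index=ids,
                                       name="mutual_information")
        self.n_features_in_ = m
        self.snp_ids_ = ids

        if self.compute_pairs:
            if m < 2:
                raise ValueError("need at least 2 SNPs to score pairs")
            weights = np.empty(m * (m - 1) // 2)
            pos = 0
            yl = y.astype(np.int64)
            for i in range(m - 1):
                k = m - 1 - i
                # joint 9x2 tables for pairs (i, i+1..m-1) in one bincount
                codes = 3 * X[:, i].astype(np.int64)[:, None] + X[:, i + 1:]
                flat = (18 * np.arange(k))[None, :] + 2 * codes + yl[:, None]
                joint = np.bincount(flat.ravel(),
                                    minlength=18 * k).reshape(k, 9, 2)
                ij = _mi_from_cells(joint.astype(float), n, log_b)
                weights[pos:pos + k] = ij - mains[i] - mains[i + 1:]
                pos += k
            self.pair_weights_ = PairWeightTable(snp_ids=ids, weights=weights)
        else:
            self.pair_weights_ = None
        return self

    def fit_dataset(self, ds: GenotypeDataset):
        """Convenience: fit from a :class:`GenotypeDataset` (must be imputed)."""
        return self.fit(ds.genotypes, ds.phenotype, snp_ids=ds.snp_ids)


class StatisticalEpistasisNetwork(BaseEstimator):
    """End-to-end statistical epistasis network analysis.

    ``fit(X, y)`` scores all SNPs and SNP pairs, builds a phenotype-permutation
    null ensemble, attaches per-pair permutation p-values, sweeps the network
    threshold over a fixed grid on both the observed and the permuted data,
    and assembles a per-threshold topology report flagging thresholds whose
    network structure departs from the permutation null.

    Parameters
    ----------
    t_max, t_min, step : float
        Descending threshold grid (defaults 0.02 -> 0 in steps of 0.001).
    n_permutations : int, default=1000
        Number of phenotype permutations for the null ensemble.
    alpha : float, default=0.01
        Per-edge significance cutoff used to form Ĝ_t and the per-property
        significance flag. No multiple-testing correction is applied across
        pairs: the edge filter is the raw per-pair permutation p-value.
    topology_alpha : float, default=0.05
        Significance level for the degree-distribution goodness-of-fit flags.
    base : {2, 'e'}, default=2
        Logarithm base for all information weights.
    n_boot : int, default=200
        Parametric-bootstrap replicates per Kolmogorov-Smirnov p-value in the
        topology report.
    max_null_weights : int, default=50_000_000
        Storage budget (floats) for per-replicate pair-weight tables; if
        ``n_permutations * n_pairs`` exceeds it the null keeps only
        per-threshold summaries and per-pair p-values are unavailable.
    random_state : int, default=0
        Seed for the permutation null and the bootstrap.

    Attributes
    ----------
    main_effects_, pair_weights_ : as in :class:`InformationGainScorer`,
        with ``pair_weights_.p_values`` filled when the storage budget allows.
    null_ : NullEnsemble
    sweep_ : ThresholdSweep of the observed data.
    property_pvalues_ : DataFrame of per-threshold permutation p-values for
        edge count, vertex count, and largest-component size.
    report_ : DataFrame, the per-threshold topology report.
    """

    def __init__(self, t_max: float = 0.02, t_min: float = 0.0,
                 step: float = 0.001, n_permutations: int = 1000,
                 alpha: float = 0.01, topology_alpha: float = 0.05,
                 base=2, n_boot: int = 200,
                 max_null_weights: int = 50_000_000,
                 random_state: int = 0) -> None:
        self.t_max = t_max
        self.t_min = t_min
        self.step = step
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.topology_alpha = topology_alpha
        self.base = base
        self.n_boot = n_boot
        self.max_null_weights = max_null_weights
        self.random_state = random_state

    def fit(self, X, y, snp_ids: list[str] | None = None):
        from .network import threshold_grid, threshold_sweep
        from .permutation import build_null, pair_pvalues, property_pvalues
        from .topology import topology_report

        X, y = _validate_xy(X, y)
        ds = GenotypeDataset(
            snp_ids=(list(snp_ids) if snp_ids is not None
                     else [f"snp{k:05d}" for k in range(X.shape[1])]),
            genotypes=X, phenotype=y)
        scorer = InformationGainScorer(base=self.base).fit_dataset(ds)
        self.scorer_ = scorer
        self.main_effects_ = scorer.main_effects_
        grid = threshold_grid(self.t_max, self.t_min, self.step)
        self.null_ = build_null(
            ds, n_replicates=self.n_permutations, seed=self.random_state,
            thresholds=grid, base=self.base,
            max_weight_storage=self.max_null_weights)
        if self.null_.pair_weights is not None:
            self.pair_weights_ = pair_pvalues(scorer.pair_weights_, self.null_)
        else:
            self.pair_weights_ = scorer.pair_weights_
        self.sweep_ = threshold_sweep(self.pair_weights_, self.t_max,
                                      self.t_min, self.step)
        self.property_pvalues_ = property_pvalues(self.sweep_, self.null_)
        self.report_ = topology_report(
            self.sweep_, self.property_pvalues_, self.pair_weights_,
            self.main_effects_, m_total=ds.n_snps, alpha=self.topology_alpha,
            property_alpha=self.alpha, n_boot=self.n_boot,
            seed=self.random_state)
        return self

    def fit_dataset(self, ds: GenotypeDataset):
        return self.fit(ds.genotypes, ds.phenotype, snp_ids=ds.snp_ids)

    def graph_at(self, t: float, significant_only: bool = False):
        """The network G_t (or Ĝ_t with ``significant_only``) at threshold t."""
        from .network import build_graph, filter_significant

        check_is_fitted(self, "pair_weights_")
        g = build_graph(self.pair_weights_, self.main_effects_, t)
        if significant_only:
            g = filter_significant(g, self.alpha)
        return g
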