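"""Phenotype-permutation null: per-pair and per-property significance.

Shuffling the case/control labels while leaving the genotype matrix intact
removes every genotype-phenotype association but preserves the class balance
and all between-SNP structure. The ensemble of networks rebuilt from many
such shuffles is the null against which both individual pair weights and
whole-network properties (edge count, vertex count, largest-component size)
are compared.

Per-pair p-values follow the matched-pair permutation estimator: the fraction
of replicates whose weight for the *same pair* exceeds the observed weight
(strict inequality by default; a non-strict and an add-one ``(b+1)/(R+1)``
variant are available, since the strict estimator can only report p = 0 for
pairs that beat every replicate). No multiple-testing correction is applied
across the pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeDataset
from .infotheory import PairWeightTable

__all__ = [
    "NullEnsemble",
    "permute_phenotype",
    "build_null",
    "pair_pvalues",
    "property_pvalues",
]


@dataclass
class NullEnsemble:
    """Per-replicate pair weights and/or network summaries under the null.

    ``pair_weights`` is an ``(n_replicates, n_pairs)`` array when the storage
    budget allows full tables (required for matched-pair p-values), else
    ``None`` with only the reduced summaries retained. ``summaries`` holds
    one row per (replicate, threshold) with the per-threshold edge count,
    vertex count and largest-component size; ``max_weights`` keeps each
    replicate's maximum pair weight.
    """

    n_replicates: int
    seed: int
    snp_ids: list[str]
    pair_weights: np.ndarray | None
    max_weights: np.ndarray
    thresholds: np.ndarray | None
    summaries: pd.DataFrame | None

    def replicate_table(self, r: int) -> PairWeightTable:
        if self.pair_weights is None:
            raise ValueError("full pair weights were not retained "
                             "(summary-only null ensemble)")
        return PairWeightTable(snp_ids=self.snp_ids,
                               weights=self.pair_weights[r])

    def write_summaries(self, path, header_comment: str = "") -> None:
        if self.summaries is None:
            raise ValueError("no per-threshold summaries were computed")
        with open(path, "w") as fh:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
            self.summaries.to_csv(fh, sep="\t", index=False,
                                  float_format="%.12g")


def permute_phenotype(ds: GenotypeDataset,
                      seed: int | np.random.Generator) -> GenotypeDataset:
    """Uniform random permutation of the phenotype labels.

    Genotypes are untouched (shared, not copied) and the case/control counts
    are preserved exactly. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    return ds.with_phenotype(rng.permutation(ds.phenotype))


def build_null(ds: GenotypeDataset, n_replicates: int, seed: int,
               thresholds: np.ndarray | None = None, base=2,
               max_weight_storage: int = 50_000_000) -> NullEnsemble:
    """Build the permutation null ensemble.

    For each replicate the phenotype is independently shuffled (replicate
    ``r`` uses seed ``seed + r``, so replicates are order-independent and may
    be computed concurrently) and all pair weights recomputed. Full
    per-replicate weight tables are retained when
    ``n_replicates * n_pairs <= max_weight_storage`` floats; otherwise only
    the per-threshold network summaries and the per-replicate maximum weight
    are kept.
    """
    from .estimators import InformationGainScorer
    from .network import threshold_sweep

    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    m = ds.n_snps
    n_pairs = m * (m - 1) // 2
    keep_weights = n_replicates * n_pairs <= max_weight_storage
    pw = np.empty((n_replicates, n_pairs)) if keep_weights else None
    max_w = np.empty(n_replicates)
    rows = []
    for r in range(n_replicates):
        shuffled = permute_phenotype(ds, seed + r)
        scorer = InformationGainScorer(base=base).fit_dataset(shuffled)
        w = scorer.pair_weights_.weights
        if pw is not None:
            pw[r] = w
        max_w[r] = w.max()
        if thresholds is not None:
            sweep = threshold_sweep(scorer.pair_weights_,
                                    t_max=float(np.max(thresholds)),
                                    t_min=float(np.min(thresholds)),
                                    step=_grid_step(thresholds))
            df = sweep.to_frame()
            df.insert(0, "replicate", r)
            rows.append(df)
    summaries = pd.concat(rows, ignore_index=True) if rows else None
    return NullEnsemble(
        n_replicates=n_replicates, seed=seed, snp_ids=list(ds.snp_ids),
        pair_weights=pw, max_weights=max_w,
        thresholds=(np.asarray(thresholds, dtype=float)
                    if thresholds is not None else None),
        summaries=summaries)


def _grid_step(thresholds: np.ndarray) -> float:
    t = np.sort(np.asarray(thresholds, dtype=float))
    if t.size < 2:
        return 1.0
    diffs = np.diff(t)
    if not np.allclose(diffs, diffs[0], atol=1e-9):
        raise ValueError("threshold grid must be evenly spaced")
    return float(diffs[0])


def pair_pvalues(obs: PairWeightTable, null: NullEnsemble,
                 mode: str = "strict") -> PairWeightTable:
    """Matched-pair permutation p-values for every observed pair weight.

    ``strict`` (default): p = #{r : w_r > w_obs} / R. ``nonstrict`` uses >=;
    ``add_one`` uses (#{r : w_r >= w_obs} + 1) / (R + 1), which cannot reach
    exactly zero.
    """
    if null.pair_weights is None:
        raise ValueError("matched-pair p-values need the full per-replicate "
                         "weight tables; rebuild the null with a larger "
                         "storage budget")
    if list(obs.snp_ids) != list(null.snp_ids):
        raise ValueError("observed table and null ensemble cover different "
                         "SNP sets")
    R = null.n_replicates
    if mode == "strict":
        p = (null.pair_weights > obs.weights).sum(axis=0) / R
    elif mode == "nonstrict":
        p = (null.pair_weights >= obs.weights).sum(axis=0) / R
    elif mode == "add_one":
        p = ((null.pair_weights >= obs.weights).sum(axis=0) + 1) / (R + 1)
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    return PairWeightTable(snp_ids=list(obs.snp_ids),
                           weights=obs.weights.copy(), p_values=p)


def pooled_pair_pvalues(obs: PairWeightTable, null: NullEnsemble,
                        mode: str = "strict") -> PairWeightTable:
    """Pooled-null variant: each observed weight is compared against the null
    weights of *all* pairs, not just its own. Off by default; provided for
    sensitivity analyses."""
    if null.pair_weights is None:
        raise ValueError("pooled p-values need the full per-replicate tables")
    pool = np.sort(null.pair_weights.ravel())
    if mode == "strict":
        exceed = pool.size - np.searchsorted(pool, obs.weights, side="right")
        p = exceed / pool.size
    elif mode == "nonstrict":
        exceed = pool.size - np.searchsorted(pool, obs.weights, side="left")
        p = exceed / pool.size
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    return PairWeightTable(snp_ids=list(obs.snp_ids),
                           weights=obs.weights.copy(), p_values=p)


def property_pvalues(sweep_real, null: NullEnsemble) -> pd.DataFrame:
    """Per-threshold permutation p-values for the three network properties.

    For each threshold and each of edge count, vertex count and
    largest-component size, p is the fraction of null replicates whose value
    is >= the observed one.
    """
    if null.summaries is None:
        raise ValueError("null ensemble holds no per-threshold summaries")
    grid = np.asarray(sweep_real.thresholds, dtype=float)
    null_grid = np.sort(null.summaries["threshold"].unique())[::-1]
    if grid.size != null_grid.size or not np.allclose(grid, null_grid,
                                                      atol=1e-9):
        raise ValueError("real and null sweeps use different threshold grids")
    R = null.n_replicates
    obs = sweep_real.to_frame().set_index("threshold")
    rows = []
    by_t = null.summaries.groupby("threshold")
    for t in grid:
        nt = by_t.get_group(_nearest(by_t.groups.keys(), t))
        row = {"threshold": t}
        for prop in ("n_edges", "n_vertices", "lcc_size"):
            row[f"p_{prop}"] = float(
                (nt[prop].to_numpy() >= obs.loc[t, prop]).sum() / R)
        rows.append(row)
    return pd.DataFrame(rows)


def _nearest(keys, t: float):
    return min(keys, key=lambda k: abs(k - t))
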