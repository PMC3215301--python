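"""Entropy-based main-effect and pairwise-interaction weights.

The weight of a SNP A is the mutual information I(A;C) = H(C) - H(C|A)
between its genotype and the case/control class C; the weight of an unordered
SNP pair (A, B) is the information gain

    IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C),

the class information carried by the joint two-SNP genotype beyond what each
SNP carries alone. Positive IG is synergy; negative IG is redundancy (the two
genotypes co-vary). All probabilities are empirical plug-in frequencies with
the standard 0·log(1/0) = 0 convention and no pseudocounts.

The logarithm base defaults to 2 (bits) and may be set to e (nats); every
threshold in a run is interpreted in the configured unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .data import GenotypeDataset, ValidationError

__all__ = [
    "entropy",
    "mutual_information",
    "information_gain",
    "all_main_effects",
    "all_pair_weights",
    "PairWeightTable",
    "write_main_effects",
    "read_main_effects",
]

_BASES = {2: 2.0, "2": 2.0, "bits": 2.0, "e": math.e, "nats": math.e}


def _log_base(base) -> float:
    try:
        return _BASES[base]
    except (KeyError, TypeError):
        raise ValueError(f"unsupported log base {base!r}; use 2 or 'e'")


def entropy(dist, base=2) -> float:
    """Shannon entropy H = sum_i p_i log(1/p_i) of a probability vector.

    Zero entries contribute zero. Entries must be non-negative and sum to 1
    within 1e-9.
    """
    p = np.asarray(dist, dtype=float)
    if (p < 0).any():
        raise ValueError("probability vector has a negative entry")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    return float(-xlogy(p, p).sum() / math.log(_log_base(base)))


def _counts_mi(counts: np.ndarray, base) -> float:
    """I(X;C) from a (k, 2) genotype-by-class count table.

    Plug-in mutual information written in count form:
    I = [sum_gc N_gc ln N_gc - sum_g N_g ln N_g - sum_c N_c ln N_c
         + N ln N] / (N ln base).
    """
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    val = (
        xlogy(counts, counts).sum()
        - xlogy(row, row).sum()
        - xlogy(col, col).sum()
        + xlogy(n, n)
    ) / (n * math.log(_log_base(base)))
    if -1e-12 < val < 0:  # clamp negative rounding residue
        val = 0.0
    return float(val)


def mutual_information(counts, base=2) -> float:
    """Mutual information I(A;C) from a genotype-by-class count table.

    ``counts`` is a ``(3, 2)`` (single SNP) or ``(9, 2)`` (joint pair
    genotype) table of non-negative integers with column 0 = controls,
    column 1 = cases. Equals H(C) - H(C|A) with the conditional entropy
    summed over the genotype-class cells (six for a single SNP).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("counts must be a (k, 2) genotype-by-class table")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() < 1:
        raise ValueError("empty contingency table")
    if (c.sum(axis=0) == 0).any():
        raise ValueError("both phenotype classes must be present")
    return _counts_mi(c, base)


def information_gain(pair_counts, a_counts, b_counts, base=2) -> float:
    """Information gain IG(A;B;C) = I(A,B;C) - I(A;C) - I(B;C).

    The three tables must describe the same individuals: identical totals and
    identical class marginals. May be negative (redundant SNPs).
    """
    pc = np.asarray(pair_counts, dtype=float)
    ac = np.asarray(a_counts, dtype=float)
    bc = np.asarray(b_counts, dtype=float)
    for name, t, k in (("pair", pc, 9), ("A", ac, 3), ("B", bc, 3)):
        if t.shape != (k, 2):
            raise ValueError(f"{name} counts must have shape ({k}, 2)")
    cls = pc.sum(axis=0)
    if not (np.array_equal(cls, ac.sum(axis=0))
            and np.array_equal(cls, bc.sum(axis=0))):
        raise ValueError("count tables have inconsistent class marginals")
    return (_counts_mi(pc, base) - _counts_mi(ac, base)
            - _counts_mi(bc, base))


@dataclass
class PairWeightTable:
    """Information gain for every unordered SNP pair, condensed storage.

    Weights (and optional permutation p-values) are stored in scipy-style
    condensed order: pair ``(i, j)`` with ``i < j`` lives at index
    ``i*m - i*(i+1)/2 + (j - i - 1)``. Access is symmetric:
    ``table.weight(i, j) == table.weight(j, i)``.
    """

    snp_ids: list[str]
    weights: np.ndarray
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        m = len(self.snp_ids)
        if self.weights.shape != (m * (m - 1) // 2,):
            raise ValueError(
                f"expected {m * (m - 1) // 2} condensed weights for m={m}, "
                f"got {self.weights.shape}"
            )
        if self.p_values is not None:
            self.p_values = np.asarray(self.p_values, dtype=float)
            if self.p_values.shape != self.weights.shape:
                raise ValueError("p_values must align with weights")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_pairs(self) -> int:
        return self.weights.shape[0]

    def index(self, i: int, j: int) -> int:
        """Condensed index of unordered pair (i, j)."""
        m = self.n_snps
        if i == j:
            raise IndexError("no self-pairs")
        if not (0 <= i < m and 0 <= j < m):
            raise IndexError(f"pair ({i}, {j}) out of range for m={m}")
        if i > j:
            i, j = j, i
        return i * m - i * (i + 1) // 2 + (j - i - 1)

    def weight(self, i: int, j: int) -> float:
        return float(self.weights[self.index(i, j)])

    def p_value(self, i: int, j: int) -> float:
        if self.p_values is None:
            raise ValueError("p-values have not been computed")
        return float(self.p_values[self.index(i, j)])

    def iter_pairs(self) -> Iterator[tuple[int, int]]:
        m = self.n_snps
        for i in range(m - 1):
            for j in range(i + 1, m):
                yield i, j

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized (i, j) arrays aligned with the condensed storage."""
        m = self.n_snps
        i, j = np.triu_indices(m, k=1)
        return i, j

    def to_frame(self) -> pd.DataFrame:
        i, j = self.pair_indices()
        ids = np.asarray(self.snp_ids, dtype=object)
        df = pd.DataFrame({
            "snp_a": ids[i],
            "snp_b": ids[j],
            "information_gain": self.weights,
        })
        if self.p_values is not None:
            df["p_value"] = self.p_values
        return df

    def write(self, path: str | Path, header_comment: str = "") -> None:
        """Write the pair-weight TSV (snp_a, snp_b, information_gain[, p])."""
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False,
                                   float_format="%.12g")

    @classmethod
    def read(cls, path: str | Path) -> "PairWeightTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        ids: list[str] = []
        seen: set[str] = set()
        for s in pd.concat([df["snp_a"], df["snp_b"]]):
            if s not in seen:
                seen.add(s)
                ids.append(s)
        tab = cls(snp_ids=ids,
                  weights=np.zeros(len(ids) * (len(ids) - 1) // 2),
                  p_values=(np.full(len(ids) * (len(ids) - 1) // 2, np.nan)
                            if "p_value" in df.columns else None))
        pos = {s: k for k, s in enumerate(ids)}
        idx = [tab.index(pos[a], pos[b])
               for a, b in zip(df["snp_a"], df["snp_b"])]
        tab.weights[idx] = df["information_gain"].to_numpy()
        if tab.p_values is not None:
            tab.p_values[idx] = df["p_value"].to_numpy()
        return tab


def all_main_effects(ds: GenotypeDataset, base=2) -> pd.Series:
    """Mutual information I(A;C) for every SNP, as a Series over snp_ids."""
    from .estimators import InformationGainScorer

    scorer = InformationGainScorer(base=base, compute_pairs=False)
    scorer.fit(ds.genotypes, ds.phenotype, snp_ids=ds.snp_ids)
    return scorer.main_effects_


def all_pair_weights(ds: GenotypeDataset, base=2) -> PairWeightTable:
    """Information gain IG(A;B;C) for all m(m-1)/2 unordered SNP pairs."""
    from .estimators import InformationGainScorer

    scorer = InformationGainScorer(base=base)
    scorer.fit(ds.genotypes, ds.phenotype, snp_ids=ds.snp_ids)
    return scorer.pair_weights_


def write_main_effects(mains: pd.Series, path: str | Path,
                       header_comment: str = "") -> None:
    """Write the main-effect TSV (snp_id, mutual_information)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        mains.rename("mutual_information").rename_axis("snp_id").to_csv(
            fh, sep="\t", float_format="%.12g")


def read_main_effects(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="snp_id")
    return df["mutual_information"]
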