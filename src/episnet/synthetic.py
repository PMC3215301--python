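"""Synthetic case-control genotype data with known epistatic structure.

Emulates the kind of candidate-gene case-control panel the analysis targets:
mostly null SNPs whose genotypes follow Hardy-Weinberg frequencies
independently of the phenotype, a minority of planted two-SNP penetrance
models arranged into motifs (isolated pairs, lines, stars), and retrospective
sampling — individuals are drawn from the population until fixed case and
control quotas fill, so the sample case fraction is a design constant, not an
estimate. Because the generating penetrance models are known exactly, an
exact population information-gain oracle (:func:`expected_ig`) is available
for every planted pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import xlogy

from .data import GenotypeDataset

__all__ = [
    "PenetranceModel",
    "PlantedModel",
    "SimulationDesign",
    "UnsatisfiableDesignError",
    "generate_dataset",
    "expected_ig",
    "xor_parity",
    "pure_epistasis",
    "main_effect_only",
    "line_motif",
    "star_motif",
]


class UnsatisfiableDesignError(RuntimeError):
    """Raised when the draw bound is exhausted before the quotas fill."""


@dataclass
class PenetranceModel:
    """P(case | genotype) for one SNP (length-3) or a SNP pair (3x3).

    Genotype priors default to Hardy-Weinberg frequencies
    ((1-q)^2, 2q(1-q), q^2) from the minor-allele frequencies ``mafs``;
    explicit ``priors`` override them (e.g. equiprobable genotypes for exact
    textbook fixtures).
    """

    table: np.ndarray
    mafs: tuple[float, ...] = (0.3, 0.3)
    priors: tuple[np.ndarray, ...] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape not in ((3,), (3, 3)):
            raise ValueError("penetrance table must be length-3 or 3x3")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")
        self.mafs = tuple(float(q) for q in self.mafs)[: self.n_snps]
        if any(not 0 < q <= 0.5 for q in self.mafs):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        if self.priors is not None:
            self.priors = tuple(np.asarray(p, dtype=float)
                                for p in self.priors)
            for p in self.priors:
                if p.shape != (3,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                    raise ValueError("each genotype prior must be a "
                                     "probability vector of length 3")

    @property
    def n_snps(self) -> int:
        return self.table.ndim

    def genotype_priors(self) -> list[np.ndarray]:
        if self.priors is not None:
            return [p.copy() for p in self.priors]
        return [np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
                for q in self.mafs]


def xor_parity(high: float = 0.6, low: float = 0.2,
               mafs: tuple[float, float] = (0.5, 0.5)) -> PenetranceModel:
    """Parity-XOR penetrance: risk is ``high`` when exactly one of the two
    genotypes is heterozygous, else ``low``. At MAF 0.5 the marginal
    penetrance of each SNP is constant (pure epistasis, zero main effect)."""
    g = np.arange(3)
    tab = np.where((g[:, None] % 2) ^ (g[None, :] % 2), high, low)
    return PenetranceModel(table=tab.astype(float), mafs=mafs,
                           name="xor_parity")


def pure_epistasis(high: float = 0.6, low: float = 0.2) -> PenetranceModel:
    """Parity-XOR at MAF 0.5: exactly zero marginal penetrance difference."""
    m = xor_parity(high, low, mafs=(0.5, 0.5))
    m.name = "pure_epistasis"
    return m


def main_effect_only(base: float = 0.25, effect: float = 0.12,
                     maf: float = 0.3) -> PenetranceModel:
    """Additive single-SNP model: P(case | g) = base + g * effect."""
    return PenetranceModel(table=np.array([base, base + effect,
                                           base + 2 * effect]),
                           mafs=(maf,), name="main_effect_only")


@dataclass
class PlantedModel:
    """A penetrance model attached to specific SNP columns (slots)."""

    slots: tuple[int, ...]
    model: PenetranceModel

    def __post_init__(self) -> None:
        self.slots = tuple(int(s) for s in self.slots)
        if len(self.slots) != self.model.n_snps:
            raise ValueError("slot count must match the model arity")
        if len(set(self.slots)) != len(self.slots):
            raise ValueError("a planted model cannot reuse a slot")


def line_motif(slots: tuple[int, ...],
               model: PenetranceModel) -> list[PlantedModel]:
    """A line A—B—C—...: one two-SNP model per consecutive slot pair."""
    return [PlantedModel((a, b), model) for a, b in zip(slots, slots[1:])]


def star_motif(hub: int, leaves: tuple[int, ...],
               model: PenetranceModel) -> list[PlantedModel]:
    """A star: the hub slot pairs with every leaf slot."""
    return [PlantedModel((hub, leaf), model) for leaf in leaves]


@dataclass
class SimulationDesign:
    """Full specification of one synthetic case-control dataset.

    Defaults mirror the study scale (1,422 SNPs, 491 cases, 791 controls);
    :meth:`reduced_scale` gives the small configuration used throughout the
    test suite (100 SNPs, 200 cases, 300 controls).
    """

    m_snps: int = 1422
    n_cases: int = 491
    n_controls: int = 791
    planted: list[PlantedModel] = field(default_factory=list)
    background_maf: float | tuple[float, float] = (0.05, 0.5)
    baseline_prevalence: float | None = None
    seed: int = 0
    max_draws: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        slots = [s for pm in self.planted for s in pm.slots]
        if any(not 0 <= s < self.m_snps for s in slots):
            raise ValueError("planted slot index out of range")
        for pm in self.planted:
            if len(set(pm.slots)) != len(pm.slots):
                raise ValueError("a planted model cannot reuse a slot")

    @classmethod
    def reduced_scale(cls, **kwargs) -> "SimulationDesign":
        kwargs.setdefault("m_snps", 100)
        kwargs.setdefault("n_cases", 200)
        kwargs.setdefault("n_controls", 300)
        return cls(**kwargs)

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)

    # -- JSON round trip ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "m_snps": self.m_snps,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "background_maf": self.background_maf,
            "baseline_prevalence": self.baseline_prevalence,
            "seed": self.seed,
            "max_draws": self.max_draws,
            "planted": [
                {"slots": list(pm.slots),
                 "table": pm.model.table.tolist(),
                 "mafs": list(pm.model.mafs),
                 "priors": ([p.tolist() for p in pm.model.priors]
                            if pm.model.priors is not None else None),
                 "name": pm.model.name}
                for pm in self.planted
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationDesign":
        doc = json.loads(Path(path).read_text())
        planted = [
            PlantedModel(
                slots=tuple(e["slots"]),
                model=PenetranceModel(
                    table=np.array(e["table"]), mafs=tuple(e["mafs"]),
                    priors=(tuple(np.array(p) for p in e["priors"])
                            if e.get("priors") else None),
                    name=e.get("name", "")))
            for e in doc.pop("planted")
        ]
        bm = doc.pop("background_maf")
        return cls(planted=planted,
                   background_maf=(tuple(bm) if isinstance(bm, list) else bm),
                   **doc)


def _snp_priors(design: SimulationDesign,
                rng: np.random.Generator) -> np.ndarray:
    """(m, 3) genotype prior per SNP: HWE from background MAFs, overridden on
    planted slots by the planted models' priors."""
    if isinstance(design.background_maf, tuple):
        lo, hi = design.background_maf
        q = rng.uniform(lo, hi, size=design.m_snps)
    else:
        q = np.full(design.m_snps, float(design.background_maf))
    priors = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2], axis=1)
    for pm in design.planted:
        for slot, prior in zip(pm.slots, pm.model.genotype_priors()):
            priors[slot] = prior
    return priors


def generate_dataset(design: SimulationDesign) -> GenotypeDataset:
    """Draw a dataset by retrospective sampling under the design.

    Population individuals are simulated (genotypes independent across SNPs
    with the per-SNP priors; disease risk combined across planted models as
    independent causes, ``P(case) = 1 - (1 - baseline) * prod_k (1 - f_k)``)
    until the case and control quotas are both full. With no planted models
    the baseline prevalence defaults to the design case fraction, making the
    phenotype independent of every genotype; with planted models it defaults
    to 0 so all risk comes from the planted penetrances. Deterministic given
    the design seed; raises :class:`UnsatisfiableDesignError` if ``max_draws``
    population draws cannot fill the quotas.
    """
    rng = np.random.default_rng(design.seed)
    priors = _snp_priors(design, rng)
    cum = np.cumsum(priors, axis=1)
    baseline = design.baseline_prevalence
    if baseline is None:
        baseline = design.case_fraction if not design.planted else 0.0

    need_cases, need_controls = design.n_cases, design.n_controls
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    drawn = 0
    batch = max(1024, 2 * (design.n_cases + design.n_controls))
    while need_cases > 0 or need_controls > 0:
        if drawn >= design.max_draws:
            raise UnsatisfiableDesignError(
                f"quotas unfilled after {drawn} population draws "
                f"(still need {need_cases} cases, {need_controls} controls); "
                "check the penetrance tables and baseline prevalence")
        b = min(batch, design.max_draws - drawn)
        u = rng.random((b, design.m_snps))
        geno = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
        healthy = np.full(b, 1.0 - baseline)
        for pm in design.planted:
            if pm.model.n_snps == 2:
                f = pm.model.table[geno[:, pm.slots[0]], geno[:, pm.slots[1]]]
            else:
                f = pm.model.table[geno[:, pm.slots[0]]]
            healthy *= 1.0 - f
        is_case = rng.random(b) >= healthy
        drawn += b
        for rows, mask, need in ((cases, is_case, need_cases),
                                 (controls, ~is_case, need_controls)):
            take = geno[mask][:max(need, 0)]
            if take.size:
                rows.append(take)
        need_cases = design.n_cases - sum(len(x) for x in cases)
        need_controls = design.n_controls - sum(len(x) for x in controls)

    geno = np.vstack([*cases, *controls])
    phenotype = np.concatenate([
        np.ones(design.n_cases, dtype=np.int8),
        np.zeros(design.n_controls, dtype=np.int8)])
    return GenotypeDataset(
        snp_ids=[f"snp{k:05d}" for k in range(design.m_snps)],
        genotypes=geno, phenotype=phenotype)


def _mi_from_joint(p: np.ndarray) -> float:
    """I(X;C) in nats from a joint probability table (k, 2)."""
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    return float((xlogy(p, p) - xlogy(p, row * col)).sum())


def expected_ig(model: PenetranceModel, case_fraction: float,
                base=2) -> float:
    """Exact population information gain of a two-SNP model under
    retrospective sampling.

    Within the case class the joint genotype distribution is proportional to
    prior(g) * P(case|g) (and to prior(g) * (1 - P(case|g)) among controls);
    the class prior is the sample case fraction. Evaluated by exhaustive
    enumeration of the 9 genotype combinations — this is the analytic oracle
    finite-sample estimates converge to.
    """
    from .infotheory import _log_base

    if model.n_snps != 2:
        raise ValueError("expected_ig needs a two-SNP penetrance model")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie strictly between 0 and 1")
    pa, pb = model.genotype_priors()
    prior = np.outer(pa, pb)
    w_case = prior * model.table
    w_ctrl = prior * (1 - model.table)
    if w_case.sum() == 0 or w_ctrl.sum() == 0:
        raise ValueError("degenerate model: one class has zero probability")
    joint = np.empty((3, 3, 2))
    joint[:, :, 1] = case_fraction * w_case / w_case.sum()
    joint[:, :, 0] = (1 - case_fraction) * w_ctrl / w_ctrl.sum()
    ln_b = np.log(_log_base(base))
    i_joint = _mi_from_joint(joint.reshape(9, 2)) / ln_b
    i_a = _mi_from_joint(joint.sum(axis=1)) / ln_b
    i_b = _mi_from_joint(joint.sum(axis=0)) / ln_b
    return i_joint - i_a - i_b
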