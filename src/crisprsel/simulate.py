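"""Synthetic two-arm pooled CRISPR screen generator with known ground truth.

The generator emulates the design of a drug-vs-vehicle metabolic knockout
screen: one initial library sample taken after selection, then two culture
arms (vehicle control and drug) grown from that same population for a fixed
number of doublings and sequenced at endpoint.

Generative model
----------------
* Initial library composition ``p0`` is skewed log-normal across sgRNAs
  (cloning bias), normalized to a probability vector.
* Each targeting sgRNA carries an efficacy ``e ∈ [0, 1]`` (Beta-distributed,
  mode near 1) modelling incomplete knockout.
* Each gene has a planted fitness effect ``f`` per arm (0 neutral, negative
  depleting, positive enriching, in growth-rate units where −1 abolishes
  growth when fully knocked out). On top of the planted value, every gene
  receives an independent per-arm Gaussian jitter (``gene_arm_noise_sd``)
  modelling biological variability between the separately cultured arms;
  the jittered value is the realized fitness of that gene in that arm.
* Cells carrying sgRNA ``i`` double ``g·(1 + e_i·f)`` times over the screen,
  so the expected final abundance is ``p_i ∝ p0_i · 2^{g·(1 + e_i·f)}``.
* Sequencing draws ``depth × n_sgRNA`` reads per sample, multinomially from
  the expected composition; an optional gamma overdispersion parameter
  produces negative-binomial-like extra-Poisson noise for stress tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import (
    CLASS_NON_TARGETING,
    CLASS_TARGETING,
    CountMatrix,
    LibraryAnnotation,
    ROLE_FINAL_CONTROL,
    ROLE_FINAL_TREATED,
    ROLE_INITIAL,
    ValidationError,
)
from .scoring import (
    CATEGORY_ESSENTIAL_BOTH,
    CATEGORY_NEUTRAL,
    CATEGORY_SELECTIVE,
    CATEGORY_SENSITIZING,
    ScreenResult,
    score_screen,
)

SAMPLE_INITIAL = "initial"
SAMPLE_CONTROL = "dmso"
SAMPLE_TREATED = "drug"

ARM_COLUMNS = {"control": SAMPLE_CONTROL, "treated": SAMPLE_TREATED}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated screen."""

    n_genes: int = 300
    sgrnas_per_gene: int = 8
    n_nontargeting: int = 200
    core_essential_fraction: float = 40 / 300
    n_selective: int = 20
    selective_fitness: float = -0.4     # drug arm only
    n_sensitizing: int = 10
    sensitizing_fitness: float = 0.3    # drug arm only
    core_fitness: float = -1.0          # both arms
    generations: float = 8.0            # population doublings per arm
    depth: float = 500.0                # expected reads per sgRNA
    overdispersion: float = 0.0         # 0 = multinomial; >0 gamma-multinomial
    gene_arm_noise_sd: float = 0.06     # biological fitness jitter per gene × arm
    efficacy_beta: tuple | None = (9.0, 2.0)  # None → all efficacies 1
    initial_lognorm_sigma: float = 0.5  # library skew
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.sgrnas_per_gene <= 0:
            raise ValidationError("library must contain at least one targeting sgRNA")
        if not 0 <= self.core_essential_fraction <= 1:
            raise ValidationError("core_essential_fraction must lie in [0, 1]")
        n_special = self.n_core_essential + self.n_selective + self.n_sensitizing
        if n_special > self.n_genes:
            raise ValidationError("planted gene classes exceed the library size")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.overdispersion < 0 or self.gene_arm_noise_sd < 0:
            raise ValidationError("noise parameters must be non-negative")

    @property
    def n_core_essential(self) -> int:
        return int(round(self.core_essential_fraction * self.n_genes))


@dataclass
class SimTruth:
    """Planted ground truth: per-gene effects and category, per-sgRNA efficacy."""

    genes: pd.DataFrame   # index gene: fitness_control, fitness_treated, category, is_core_essential
    sgrnas: pd.DataFrame  # index sgrna: gene, efficacy


@dataclass
class SimStructure:
    """The deterministic part of one screen realization (no count sampling)."""

    annotation: LibraryAnnotation
    truth: SimTruth
    p0: np.ndarray                 # initial composition, sums to 1, sgRNA order = annotation
    efficacy: np.ndarray           # per sgRNA; 0 for non-targeting (no knockout)
    realized_fitness: pd.DataFrame  # index gene, columns control/treated, jitter included


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def build_structure(config: SimConfig, rng: np.random.Generator | None = None) -> SimStructure:
    """Draw library composition, efficacies and realized fitness effects."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_targ = config.n_genes * config.sgrnas_per_gene
    n_total = n_targ + config.n_nontargeting

    sgrna_ids = [
        f"{g}_sg{j}" for g in genes for j in range(1, config.sgrnas_per_gene + 1)
    ] + [f"NT_{k:04d}" for k in range(1, config.n_nontargeting + 1)]
    gene_per_sgrna = np.repeat(genes, config.sgrnas_per_gene).tolist() + [
        "non-targeting"
    ] * config.n_nontargeting

    p0 = rng.lognormal(mean=0.0, sigma=config.initial_lognorm_sigma, size=n_total)
    p0 /= p0.sum()

    efficacy = np.zeros(n_total)
    if config.efficacy_beta is None:
        efficacy[:n_targ] = 1.0
    else:
        a, b = config.efficacy_beta
        efficacy[:n_targ] = rng.beta(a, b, size=n_targ)

    order = rng.permutation(config.n_genes)
    n_ce, n_sel, n_sen = (
        config.n_core_essential,
        config.n_selective,
        config.n_sensitizing,
    )
    category = np.full(config.n_genes, CATEGORY_NEUTRAL, dtype=object)
    category[order[:n_ce]] = CATEGORY_ESSENTIAL_BOTH
    category[order[n_ce : n_ce + n_sel]] = CATEGORY_SELECTIVE
    category[order[n_ce + n_sel : n_ce + n_sel + n_sen]] = CATEGORY_SENSITIZING

    f_control = np.where(category == CATEGORY_ESSENTIAL_BOTH, config.core_fitness, 0.0)
    f_treated = f_control.copy()
    f_treated[category == CATEGORY_SELECTIVE] = config.selective_fitness
    f_treated[category == CATEGORY_SENSITIZING] = config.sensitizing_fitness

    jitter = rng.normal(0.0, config.gene_arm_noise_sd, size=(config.n_genes, 2))
    realized = pd.DataFrame(
        {
            "control": f_control + jitter[:, 0],
            "treated": f_treated + jitter[:, 1],
        },
        index=pd.Index(genes, name="gene"),
    )

    ann_table = pd.DataFrame(
        {
            "gene": [g if g != "non-targeting" else "" for g in gene_per_sgrna],
            "control_class": [
                CLASS_TARGETING if g != "non-targeting" else CLASS_NON_TARGETING
                for g in gene_per_sgrna
            ],
            "is_core_essential": np.concatenate(
                [
                    np.repeat(category == CATEGORY_ESSENTIAL_BOTH, config.sgrnas_per_gene),
                    np.zeros(config.n_nontargeting, dtype=bool),
                ]
            ),
        },
        index=pd.Index(sgrna_ids, name="sgrna"),
    )
    annotation = LibraryAnnotation(ann_table)

    truth_genes = pd.DataFrame(
        {
            "fitness_control": f_control,
            "fitness_treated": f_treated,
            "category": category,
            "is_core_essential": category == CATEGORY_ESSENTIAL_BOTH,
        },
        index=pd.Index(genes, name="gene"),
    )
    truth_sgrnas = pd.DataFrame(
        {"gene": gene_per_sgrna, "efficacy": efficacy},
        index=pd.Index(sgrna_ids, name="sgrna"),
    )
    return SimStructure(
        annotation=annotation,
        truth=SimTruth(truth_genes, truth_sgrnas),
        p0=p0,
        efficacy=efficacy,
        realized_fitness=realized,
    )


def _final_composition(structure: SimStructure, config: SimConfig, arm: str) -> np.ndarray:
    """Expected endpoint composition of one arm (normalized)."""
    ann = structure.annotation.table
    fitness = structure.realized_fitness[arm].reindex(ann["gene"]).fillna(0.0).to_numpy()
    # common 2^g factor cancels under normalization; keep only the effect term
    exponent = config.generations * structure.efficacy * fitness
    w = structure.p0 * np.exp2(exponent)
    if not np.all(np.isfinite(w)) or not w.sum() > 0:
        raise ValidationError("non-finite expected abundances; check fitness/generations")
    return w / w.sum()


def expected_lfc(
    structure: SimStructure, config: SimConfig, arm: str = "treated"
) -> pd.Series:
    """Analytic expected log2 fold-change per sgRNA, free of count sampling.

    This is the sampling-free oracle: the log2 ratio of the renormalized
    expected endpoint composition to the initial composition.
    """
    p_final = _final_composition(structure, config, arm)
    return pd.Series(
        np.log2(p_final / structure.p0),
        index=structure.annotation.sgrna_ids,
        name=f"expected_lfc_{arm}",
    )


def _sample_counts(
    p: np.ndarray, n_reads: int, overdispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if overdispersion > 0:
        noisy = p * rng.gamma(shape=1.0 / overdispersion, scale=overdispersion, size=p.size)
        p = noisy / noisy.sum()
    return rng.multinomial(n_reads, p)


def simulate_screen(
    config: SimConfig,
) -> tuple[CountMatrix, LibraryAnnotation, SimTruth]:
    """Simulate one two-arm screen; returns counts, annotation and ground truth."""
    rng = np.random.default_rng(config.seed)
    structure = build_structure(config, rng)
    n_total = len(structure.annotation.sgrna_ids)
    n_reads = int(round(config.depth * n_total))

    compositions = {
        SAMPLE_INITIAL: structure.p0,
        SAMPLE_CONTROL: _final_composition(structure, config, "control"),
        SAMPLE_TREATED: _final_composition(structure, config, "treated"),
    }
    counts = pd.DataFrame(
        {
            sample: _sample_counts(p, n_reads, config.overdispersion, rng)
            for sample, p in compositions.items()
        },
        index=structure.annotation.sgrna_ids,
    )
    roles = {
        SAMPLE_INITIAL: ROLE_INITIAL,
        SAMPLE_CONTROL: ROLE_FINAL_CONTROL,
        SAMPLE_TREATED: ROLE_FINAL_TREATED,
    }
    genes = structure.annotation.table["gene"].rename("gene")
    cm = CountMatrix(counts, roles, genes)
    return cm, structure.annotation, structure.truth


def score_simulated_screen(
    config: SimConfig, **scoring_kwargs
) -> tuple[ScreenResult, SimTruth]:
    """Simulate one screen and run the full scoring pipeline on it."""
    counts, annotation, truth = simulate_screen(config)
    return score_screen(counts, annotation, **scoring_kwargs), truth


def recovery_metrics(
    gene_table: pd.DataFrame, truth: SimTruth, top_n: int | None = None
) -> dict:
    """How well the scored screen recovers the planted gene classes.

    Reports the AUROC of ``-selective_z`` for planted drug-selective genes
    against planted neutral genes, the recall of planted selective genes among
    the ``top_n`` most negative z (default: the number planted), and the sign
    accuracy (z > 0) for planted sensitizing genes.
    """
    scored = gene_table.set_index("gene")
    unknown = scored.index.difference(truth.genes.index)
    if len(unknown):
        raise ValidationError(
            f"scored genes absent from ground truth: {unknown.tolist()[:5]}"
        )
    merged = scored.join(truth.genes.add_prefix("true_"), how="inner")
    selective = merged["true_category"] == CATEGORY_SELECTIVE
    neutral = merged["true_category"] == CATEGORY_NEUTRAL
    sensitizing = merged["true_category"] == CATEGORY_SENSITIZING
    n_selective_planted = int((truth.genes["category"] == CATEGORY_SELECTIVE).sum())

    out: dict = {
        "n_genes_scored": int(len(merged)),
        "n_selective_planted": n_selective_planted,
    }
    mask = selective | neutral
    if selective.any() and neutral.any():
        out["auroc_selective_vs_neutral"] = float(
            roc_auc_score(selective[mask].astype(int), -merged.loc[mask, "selective_z"])
        )
    if n_selective_planted:
        n = top_n if top_n is not None else n_selective_planted
        top = merged["selective_z"].nsmallest(n).index
        out["recall_top_n"] = float(
            len(set(top) & set(merged.index[selective])) / n_selective_planted
        )
        out["top_n"] = int(n)
    if sensitizing.any():
        out["sensitizing_sign_accuracy"] = float(
            (merged.loc[sensitizing, "selective_z"] > 0).mean()
        )
    return out


#: Named screen designs. ``lowdose`` mirrors the 14-day screen (moderate dose,
#: ~8 doublings); ``highdose`` the 17-day high-dose screen (longer culture,
#: stronger drug-arm effects); ``small`` is a fast fixture-sized library.
PRESETS: dict[str, SimConfig] = {
    "lowdose": SimConfig(),
    "highdose": SimConfig(
        generations=10.0, selective_fitness=-0.6, sensitizing_fitness=0.4
    ),
    "small": SimConfig(
        n_genes=24,
        sgrnas_per_gene=6,
        n_nontargeting=30,
        core_essential_fraction=0.25,
        n_selective=3,
        n_sensitizing=2,
        depth=400.0,
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """A named preset, optionally with field overrides (e.g. ``seed=7``)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[name], **overrides)
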