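"""Filtering, normalization, scoring and selective-essentiality calling.

The pipeline turns a two-arm pooled knockout screen (one initial library
sample, final samples for a vehicle arm and a drug arm) into categorized
per-gene hits:

1. drop sgRNAs under-represented in the initial library (< 100 reads);
2. drop genes left with fewer than 6 distinct sgRNAs;
3. normalize counts to relative abundances with a pseudocount of one;
4. per arm, score each sgRNA as log2(final abundance / initial abundance);
5. average sgRNA scores into gene scores;
6. rescale per arm so the median non-targeting sgRNA sits at 0 and the
   median core-essential-gene sgRNA at −1;
7. z-score the per-gene difference (treated − control) of scaled scores;
   strongly negative z marks drug-selective (synthetic-lethal) dependencies,
   strongly positive z marks knockouts that blunt the drug's effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    LibraryAnnotation,
    ROLE_FINAL_CONTROL,
    ROLE_FINAL_TREATED,
    ValidationError,
)

logger = logging.getLogger(__name__)

CATEGORY_SELECTIVE = "selectively_lethal"
CATEGORY_SENSITIZING = "sensitizing_enriched"
CATEGORY_ESSENTIAL_BOTH = "essential_both"
CATEGORY_NEUTRAL = "neutral"


class ScreenQualityError(ValueError):
    """Raised when a screen fails an internal control (degenerate references)."""


@dataclass(frozen=True)
class ScalingAnchors:
    """Per-arm reference medians of sgRNA-level log2 fold-changes (log2 units)."""

    median_nontargeting: float
    median_core_essential: float

    def __post_init__(self) -> None:
        if not self.median_nontargeting > self.median_core_essential:
            raise ScreenQualityError(
                "non-targeting median must exceed core-essential median "
                f"(got {self.median_nontargeting:g} ≤ {self.median_core_essential:g}); "
                "the screen failed its internal depletion control"
            )

    @property
    def denominator(self) -> float:
        return self.median_nontargeting - self.median_core_essential


@dataclass
class ScreenResult:
    """Full output of :func:`score_screen`."""

    gene_table: pd.DataFrame        # gene, n_sgrnas_used, raw/scaled per arm, z, category
    sgrna_table: pd.DataFrame       # sgrna, gene, lfc_control, lfc_treated
    anchors: dict                   # arm -> ScalingAnchors
    tallies: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_genes_scored": int(len(self.gene_table)),
            "anchors": {
                arm: {
                    "median_nontargeting": a.median_nontargeting,
                    "median_core_essential": a.median_core_essential,
                }
                for arm, a in self.anchors.items()
            },
            "tallies": self.tallies,
            "categories": self.gene_table["category"].value_counts().to_dict(),
        }


def filter_sgrnas(counts: CountMatrix, min_initial: int = 100) -> CountMatrix:
    """Remove sgRNAs with fewer than ``min_initial`` reads in the initial sample."""
    initial = counts.initial_sample
    keep = counts.counts.index[counts.counts[initial] >= min_initial]
    n_removed = len(counts.counts) - len(keep)
    logger.info("initial-count filter: removed %d of %d sgRNAs", n_removed, len(counts.counts))
    return counts.restrict(keep)


def filter_genes(
    counts: CountMatrix, annotation: LibraryAnnotation, min_sgrnas: int = 6
) -> CountMatrix:
    """Remove all sgRNAs of genes with fewer than ``min_sgrnas`` surviving sgRNAs.

    Non-targeting controls carry no gene and are never removed here.
    """
    gene = annotation.table["gene"].reindex(counts.counts.index)
    is_targeting = (
        annotation.table["control_class"].reindex(counts.counts.index) == "targeting"
    )
    per_gene = gene[is_targeting].value_counts()
    bad_genes = set(per_gene.index[per_gene < min_sgrnas])
    keep = counts.counts.index[~is_targeting | ~gene.isin(bad_genes)]
    logger.info(
        "gene filter: removed %d genes (%d sgRNAs)",
        len(bad_genes),
        len(counts.counts) - len(keep),
    )
    return counts.restrict(keep)


def normalize_abundance(counts: CountMatrix) -> pd.DataFrame:
    """Relative abundances with a pseudocount of one: (c+1) / Σ(c+1) per sample."""
    if counts.counts.empty:
        raise ValidationError("cannot normalize an empty count matrix")
    shifted = counts.counts.astype(float) + 1.0
    return shifted / shifted.sum(axis=0)


def sgrna_lfc(
    abundance: pd.DataFrame, final_sample: str, initial_sample: str
) -> pd.Series:
    """log2 fold-change of each sgRNA between a final and the initial sample."""
    return np.log2(abundance[final_sample] / abundance[initial_sample])


def arm_lfc(
    abundance: pd.DataFrame, final_samples: list[str], initial_sample: str
) -> pd.Series:
    """sgRNA lfc for one arm; replicate finals are averaged at sgRNA level."""
    if not final_samples:
        raise ValidationError("arm has no final samples")
    lfcs = [sgrna_lfc(abundance, s, initial_sample) for s in final_samples]
    return sum(lfcs) / len(lfcs)


def gene_score(lfc: pd.Series, annotation: LibraryAnnotation) -> pd.DataFrame:
    """Raw gene scores: arithmetic mean lfc over each gene's surviving sgRNAs."""
    gene = annotation.table["gene"].reindex(lfc.index)
    targeting = (
        annotation.table["control_class"].reindex(lfc.index) == "targeting"
    )
    grouped = lfc[targeting].groupby(gene[targeting])
    out = pd.DataFrame({"raw": grouped.mean(), "n_sgrnas_used": grouped.size()})
    assert (out["n_sgrnas_used"] > 0).all()
    out.index.name = "gene"
    return out


def compute_anchors(
    lfc: pd.Series, annotation: LibraryAnnotation, min_reference: int = 10
) -> ScalingAnchors:
    """Reference medians over sgRNA-level lfcs of the two control classes.

    The even-length median is the midpoint of the two central values
    (numpy's convention).
    """
    nt = annotation.nontargeting_ids.intersection(lfc.index)
    ce = annotation.core_essential_ids.intersection(lfc.index)
    if len(nt) < min_reference:
        raise ScreenQualityError(
            f"only {len(nt)} non-targeting sgRNAs survive filters "
            f"(minimum {min_reference})"
        )
    if len(ce) < min_reference:
        raise ScreenQualityError(
            f"only {len(ce)} core-essential sgRNAs survive filters "
            f"(minimum {min_reference})"
        )
    return ScalingAnchors(
        median_nontargeting=float(np.median(lfc.loc[nt])),
        median_core_essential=float(np.median(lfc.loc[ce])),
    )


def scale_scores(raw, anchors: ScalingAnchors):
    """Affine rescaling mapping the non-targeting anchor to 0, core-essential to −1."""
    return (raw - anchors.median_nontargeting) / anchors.denominator


def selective_essentiality(
    scaled_treated: pd.Series, scaled_control: pd.Series, robust: bool = False
) -> pd.Series:
    """z-scored difference of scaled gene scores, treated − control.

    The default standardizes with the plain sample mean and sample standard
    deviation (ddof=1) over all scored genes; ``robust=True`` substitutes the
    median and the normal-consistent MAD.
    """
    if not scaled_treated.index.equals(scaled_control.index):
        raise ValidationError("arms were not scored on the identical gene set")
    d = scaled_treated - scaled_control
    if robust:
        center = float(d.median())
        scale = float((d - center).abs().median()) * 1.4826022185056018
    else:
        center = float(d.mean())
        scale = float(d.std(ddof=1))
    if not scale > 0:
        raise ScreenQualityError(
            "selective-essentiality differences have zero spread; degenerate screen"
        )
    return (d - center) / scale


def classify_genes(
    gene_table: pd.DataFrame, z_cut: float = 2.0, essential_cut: float = -0.5
) -> pd.Series:
    """Assign hit categories; essential-in-both-arms takes precedence over z cuts."""
    z = gene_table["selective_z"]
    essential_both = (gene_table["scaled_control"] <= essential_cut) & (
        gene_table["scaled_treated"] <= essential_cut
    )
    cat = pd.Series(CATEGORY_NEUTRAL, index=gene_table.index, dtype=object)
    cat[z <= -z_cut] = CATEGORY_SELECTIVE
    cat[z >= z_cut] = CATEGORY_SENSITIZING
    cat[essential_both] = CATEGORY_ESSENTIAL_BOTH
    return cat


def rank_plot_data(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Genes ordered by selective_z ascending with ranks 1..G (ties: gene id)."""
    out = gene_table.sort_values(
        ["selective_z", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out[["rank", "gene", "selective_z", "category"]]


def top_hits(gene_table: pd.DataFrame, n: int = 30) -> dict[str, list[str]]:
    """Top-N gene lists by selective_z in each tail (depleted and enriched)."""
    ordered = gene_table.sort_values(["selective_z", "gene"], kind="mergesort")
    return {
        "top_depleted": ordered["gene"].head(n).tolist(),
        "top_enriched": ordered["gene"].tail(n).tolist()[::-1],
    }


def score_screen(
    counts: CountMatrix,
    annotation: LibraryAnnotation,
    *,
    min_initial: int = 100,
    min_sgrnas: int = 6,
    min_reference: int = 10,
    z_cut: float = 2.0,
    essential_cut: float = -0.5,
    robust_z: bool = False,
) -> ScreenResult:
    """Run the full counts → categorized gene hits pipeline on a two-arm screen."""
    extra = counts.counts.index.difference(annotation.sgrna_ids)
    if len(extra):
        raise ValidationError(
            f"count table contains unannotated sgRNAs: {extra.tolist()[:5]}"
        )
    initial = counts.initial_sample
    controls = counts.samples_with_role(ROLE_FINAL_CONTROL)
    treateds = counts.samples_with_role(ROLE_FINAL_TREATED)
    if not controls or not treateds:
        raise ValidationError("both a final_control and a final_treated sample are required")

    n0 = len(counts.counts)
    filtered = filter_sgrnas(counts, min_initial)
    n1 = len(filtered.counts)
    filtered = filter_genes(filtered, annotation, min_sgrnas)
    n2 = len(filtered.counts)

    abundance = normalize_abundance(filtered)
    lfc = {
        "control": arm_lfc(abundance, controls, initial),
        "treated": arm_lfc(abundance, treateds, initial),
    }
    anchors = {
        arm: compute_anchors(lfc[arm], annotation, min_reference) for arm in lfc
    }
    per_arm = {}
    for arm in ("control", "treated"):
        g = gene_score(lfc[arm], annotation)
        g["scaled"] = scale_scores(g["raw"], anchors[arm])
        per_arm[arm] = g

    gene_table = pd.DataFrame(
        {
            "gene": per_arm["control"].index,
            "n_sgrnas_used": per_arm["control"]["n_sgrnas_used"].to_numpy(),
            "raw_control": per_arm["control"]["raw"].to_numpy(),
            "raw_treated": per_arm["treated"]["raw"].to_numpy(),
            "scaled_control": per_arm["control"]["scaled"].to_numpy(),
            "scaled_treated": per_arm["treated"]["scaled"].to_numpy(),
        }
    )
    z = selective_essentiality(
        per_arm["treated"]["scaled"], per_arm["control"]["scaled"], robust=robust_z
    )
    gene_table["selective_z"] = z.to_numpy()
    gene_table["category"] = classify_genes(
        gene_table, z_cut=z_cut, essential_cut=essential_cut
    ).to_numpy()

    sgrna_table = pd.DataFrame(
        {
            "sgrna": abundance.index,
            "gene": annotation.table["gene"].reindex(abundance.index).to_numpy(),
            "lfc_control": lfc["control"].to_numpy(),
            "lfc_treated": lfc["treated"].to_numpy(),
        }
    )
    tallies = {
        "n_sgrnas_input": n0,
        "n_sgrnas_removed_initial_filter": n0 - n1,
        "n_sgrnas_removed_gene_filter": n1 - n2,
        "n_sgrnas_scored": n2,
    }
    return ScreenResult(gene_table, sgrna_table, anchors, tallies)
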