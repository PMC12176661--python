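"""Tabular input/output for the screen pipeline.

Count tables follow the MAGeCK-count layout: a header row, then one row per
sgRNA with columns ``sgRNA``, ``gene`` and one integer column per sequenced
sample. Sample roles (which sample is the initial library, which final samples
belong to the vehicle and drug arms) are supplied explicitly by the caller or
via a run-configuration file rather than inferred from column names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLE_INITIAL = "initial"
ROLE_FINAL_CONTROL = "final_control"
ROLE_FINAL_TREATED = "final_treated"
VALID_ROLES = frozenset({ROLE_INITIAL, ROLE_FINAL_CONTROL, ROLE_FINAL_TREATED})

#: gene-column sentinel accepted for non-targeting control sgRNAs
NON_TARGETING_SENTINELS = frozenset({"", "-", "NA", "non-targeting", "NonTargeting"})

CLASS_TARGETING = "targeting"
CLASS_NON_TARGETING = "non_targeting"

SCORE_COLUMNS = [
    "gene",
    "n_sgrnas_used",
    "raw_control",
    "raw_treated",
    "scaled_control",
    "scaled_treated",
    "selective_z",
    "category",
]

_FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class LibraryAnnotation:
    """sgRNA library annotation: sgRNA → gene map plus control classes.

    ``table`` is indexed by sgRNA id with columns ``gene`` (empty string for
    non-targeting controls), ``control_class`` and ``is_core_essential``
    (a per-gene flag marking the core-essential reference set, repeated on
    each of the gene's sgRNAs).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene", "control_class", "is_core_essential"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sgRNA ids in annotation: {dups[:5]}")
        bad_class = set(t["control_class"]) - {CLASS_TARGETING, CLASS_NON_TARGETING}
        if bad_class:
            raise ValidationError(f"unknown control_class values: {sorted(bad_class)}")
        nt = t["control_class"] == CLASS_NON_TARGETING
        nt_with_gene = t.index[nt & ~t["gene"].isin(NON_TARGETING_SENTINELS)]
        if len(nt_with_gene):
            raise ValidationError(
                f"non-targeting sgRNAs carry a gene id: {nt_with_gene.tolist()[:5]}"
            )
        targ_no_gene = t.index[~nt & t["gene"].isin(NON_TARGETING_SENTINELS)]
        if len(targ_no_gene):
            raise ValidationError(
                f"targeting sgRNAs lack a gene id: {targ_no_gene.tolist()[:5]}"
            )
        if bool(t.loc[nt, "is_core_essential"].any()):
            raise ValidationError(
                "is_core_essential set on non-targeting sgRNAs; the flag is "
                "defined only for genes of targeting sgRNAs"
            )
        # the flag must be consistent within each gene
        per_gene = t.loc[~nt].groupby("gene")["is_core_essential"].nunique()
        inconsistent = per_gene.index[per_gene > 1].tolist()
        if inconsistent:
            raise ValidationError(
                f"is_core_essential inconsistent within genes: {inconsistent[:5]}"
            )
        if len(t.loc[~nt]) and not bool(t["is_core_essential"].any()):
            logger.warning(
                "annotation defines no core-essential reference genes; "
                "reference scaling will fail downstream"
            )

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.table.index

    @property
    def nontargeting_ids(self) -> pd.Index:
        return self.table.index[self.table["control_class"] == CLASS_NON_TARGETING]

    @property
    def targeting_ids(self) -> pd.Index:
        return self.table.index[self.table["control_class"] == CLASS_TARGETING]

    @property
    def gene_of(self) -> pd.Series:
        """gene id per targeting sgRNA."""
        return self.table.loc[self.targeting_ids, "gene"]

    @property
    def core_essential_genes(self) -> frozenset:
        t = self.table
        mask = (t["control_class"] == CLASS_TARGETING) & t["is_core_essential"]
        return frozenset(t.loc[mask, "gene"])

    @property
    def core_essential_ids(self) -> pd.Index:
        t = self.table
        mask = (t["control_class"] == CLASS_TARGETING) & t["is_core_essential"]
        return t.index[mask]


@dataclass
class CountMatrix:
    """sgRNA × sample read counts with sample roles.

    ``counts`` is an integer DataFrame indexed by sgRNA id; ``sample_roles``
    maps every sample column to one of ``initial`` / ``final_control`` /
    ``final_treated``. ``genes`` retains the gene column of the source file
    for cross-validation against the annotation.
    """

    counts: pd.DataFrame
    sample_roles: Mapping[str, str]
    genes: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sgRNA ids in count table: {dups[:5]}")
        if c.shape[1] == 0:
            raise ValidationError("count table has no sample columns")
        if not all(pd.api.types.is_integer_dtype(d) for d in c.dtypes):
            raise ValidationError("counts must be integer-valued")
        if (c.values < 0).any():
            r, s = divmod(int((c.values < 0).argmax()), c.shape[1])
            raise ValidationError(
                f"negative count at sgRNA {c.index[r]!r}, sample {c.columns[s]!r}"
            )
        unknown = set(self.sample_roles.values()) - VALID_ROLES
        if unknown:
            raise ValidationError(f"unknown sample roles: {sorted(unknown)}")
        missing = set(c.columns) - set(self.sample_roles)
        if missing:
            raise ValidationError(f"samples without a role: {sorted(missing)}")
        absent = set(self.sample_roles) - set(c.columns)
        if absent:
            raise ValidationError(f"roles reference missing samples: {sorted(absent)}")

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_roles[s] == role]

    @property
    def initial_sample(self) -> str:
        initial = self.samples_with_role(ROLE_INITIAL)
        if len(initial) != 1:
            raise ValidationError(
                f"exactly one initial sample required, found {len(initial)}"
            )
        return initial[0]

    def restrict(self, sgrna_ids: Iterable[str]) -> "CountMatrix":
        ids = pd.Index(sgrna_ids)
        genes = None if self.genes is None else self.genes.loc[ids]
        return CountMatrix(self.counts.loc[ids], dict(self.sample_roles), genes)


def read_count_table(
    path: str | Path,
    sample_roles: Mapping[str, str],
    annotation: LibraryAnnotation | None = None,
) -> CountMatrix:
    """Read a MAGeCK-count-style TSV into a :class:`CountMatrix`.

    The first two columns must be the sgRNA id and gene id; every remaining
    column is a sample. When ``annotation`` is given, sgRNA ids must be a
    subset of the annotation and the file's gene column must agree with it;
    annotated sgRNAs absent from the file are appended with zero counts (they
    are then removed by the initial-count filter) and logged.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 3:
        raise ValidationError(f"{path}: no sample columns (need sgRNA, gene, samples)")
    sgrna_col, gene_col = raw.columns[:2]
    sample_cols = list(raw.columns[2:])
    if raw[sgrna_col].duplicated().any():
        dup = raw.loc[raw[sgrna_col].duplicated(), sgrna_col].iloc[0]
        raise ValidationError(f"{path}: duplicate sgRNA id {dup!r}")
    absent = set(sample_roles) - set(sample_cols)
    if absent:
        raise ValidationError(
            f"{path}: design references missing sample ids: {sorted(absent)}"
        )
    sample_cols = [c for c in sample_cols if c in sample_roles]
    counts = pd.DataFrame(index=pd.Index(raw[sgrna_col], name="sgrna"))
    for col in sample_cols:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            i = int(bad.idxmax())
            raise ValidationError(
                f"{path}: non-integer or negative count {raw[col][i]!r} at "
                f"sgRNA {raw[sgrna_col][i]!r}, sample {col!r}"
            )
        counts[col] = numeric.astype("int64").to_numpy()
    genes = pd.Series(raw[gene_col].fillna("").to_numpy(), index=counts.index, name="gene")

    if annotation is not None:
        extra = counts.index.difference(annotation.sgrna_ids)
        if len(extra):
            raise ValidationError(
                f"{path}: sgRNAs not present in annotation: {extra.tolist()[:5]}"
            )
        ann_gene = annotation.table["gene"].reindex(counts.index)
        is_nt = (
            annotation.table["control_class"].reindex(counts.index)
            == CLASS_NON_TARGETING
        )
        mismatch = counts.index[
            (~is_nt & (genes != ann_gene))
            | (is_nt & ~genes.isin(NON_TARGETING_SENTINELS))
        ]
        if len(mismatch):
            raise ValidationError(
                f"{path}: gene column disagrees with annotation for "
                f"sgRNAs {mismatch.tolist()[:10]}"
            )
        missing = annotation.sgrna_ids.difference(counts.index)
        if len(missing):
            logger.warning(
                "%s: %d annotated sgRNAs absent from counts; treated as count 0",
                path,
                len(missing),
            )
            pad = pd.DataFrame(0, index=missing, columns=counts.columns, dtype="int64")
            counts = pd.concat([counts, pad])
            genes = pd.concat(
                [genes, annotation.table.loc[missing, "gene"]]
            ).rename("gene")

    return CountMatrix(counts, dict(sample_roles), genes)


def read_annotation(path: str | Path) -> LibraryAnnotation:
    """Read a library annotation TSV (sgrna, gene, control_class, core_essential)."""
    raw = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
    required = ["sgrna", "gene", "control_class", "core_essential"]
    missing = set(required) - set(raw.columns)
    if missing:
        raise ValidationError(f"{path}: annotation missing columns {sorted(missing)}")
    truthy = {"1", "true", "True", "TRUE", "yes"}
    falsy = {"0", "false", "False", "FALSE", "no", ""}
    bad = set(raw["core_essential"]) - truthy - falsy
    if bad:
        raise ValidationError(f"{path}: unparseable core_essential values {sorted(bad)}")
    table = pd.DataFrame(
        {
            "gene": raw["gene"].to_numpy(),
            "control_class": raw["control_class"].to_numpy(),
            "is_core_essential": raw["core_essential"].isin(truthy).to_numpy(),
        },
        index=pd.Index(raw["sgrna"], name="sgrna"),
    )
    return LibraryAnnotation(table)


def write_annotation(annotation: LibraryAnnotation, path: str | Path) -> None:
    t = annotation.table
    out = pd.DataFrame(
        {
            "sgrna": t.index,
            "gene": t["gene"].to_numpy(),
            "control_class": t["control_class"].to_numpy(),
            "core_essential": t["is_core_essential"].astype(int).to_numpy(),
        }
    )
    out.to_csv(Path(path), sep="\t", index=False)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    genes = cm.genes if cm.genes is not None else pd.Series("", index=cm.counts.index)
    out = cm.counts.copy()
    out.insert(0, "gene", genes)
    out.insert(0, "sgRNA", cm.counts.index)
    out.to_csv(Path(path), sep="\t", index=False)


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a gene score table sorted by selective_z ascending (ties: gene id)."""
    missing = set(SCORE_COLUMNS) - set(scores.columns)
    if missing:
        raise ValidationError(f"score table missing columns {sorted(missing)}")
    out = scores[SCORE_COLUMNS].sort_values(
        ["selective_z", "gene"], kind="mergesort"
    )
    out.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


@dataclass
class RunConfig:
    """Configuration for one screen analysis run."""

    counts: str | None = None
    annotation: str | None = None
    design: dict = field(default_factory=dict)  # initial / control / treated samples
    min_initial: int = 100
    min_sgrnas: int = 6
    min_reference: int = 10
    z_cut: float = 2.0
    essential_cut: float = -0.5
    top_n: int = 30
    robust_z: bool = False
    seed: int = 0
    outdir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        filters = data.pop("filters", {})
        classify = data.pop("classify", {})
        cfg = cls(**{**data, **filters, **classify})
        if cfg.min_initial < 0 or cfg.min_sgrnas < 0 or cfg.min_reference < 0:
            raise ValidationError("filter thresholds must be non-negative")
        return cfg

    def sample_roles(self) -> dict[str, str]:
        d = self.design
        roles: dict[str, str] = {}
        if "initial" in d:
            roles[d["initial"]] = ROLE_INITIAL
        for s in d.get("control", []):
            roles[s] = ROLE_FINAL_CONTROL
        for s in d.get("treated", []):
            roles[s] = ROLE_FINAL_TREATED
        return roles
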