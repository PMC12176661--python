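"""Small defined assay statistics: RNA-ISH composite score, autophagic-flux
index, Bliss synergy excess, and phosphoinositide peak percentages.

Each operation consumes already-quantified inputs (binned cell percentages,
plate-reader fluorescence, viability-derived inhibition fractions,
scintillation counts); microscopy, curve fitting and image analysis are out
of scope.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PIP_PEAKS = (
    "PtdIns",
    "PtdIns3P",
    "PtdIns4P",
    "PtdIns5P",
    "PtdIns(3,5)P2",
    "PtdIns(4,5)P2",
)


def ish_composite_score(bins: Sequence[float]) -> float:
    """Composite RNA in-situ hybridization expression score, range 0–400.

    ``bins`` are the percentages of cells at expression levels 0–4
    (A%, B%, C%, D%, E%); they must sum to 100. The score is
    ``0·A + 1·B + 2·C + 3·D + 4·E``.
    """
    b = np.asarray(bins, dtype=float)
    if b.shape != (5,):
        raise ValueError("expected five bin percentages (levels 0-4)")
    if (b < 0).any() or (b > 100).any():
        raise ValueError("bin percentages must lie in [0, 100]")
    if abs(b.sum() - 100.0) > 1e-9:
        raise ValueError(f"bin percentages must sum to 100, got {b.sum()!r}")
    return float(np.dot(b, np.arange(5)))


def autophagy_index(
    wells: pd.DataFrame, normalizer_condition: str = "DMSO"
) -> pd.Series:
    """Per-well autophagic-flux index from a GFP-LC3-RFP-LC3ΔG reporter assay.

    The reporter's GFP moiety is degraded by autophagy while the cleaved RFP
    fragment is not, so the RFP/GFP ratio rises with flux. The index is each
    well's RFP/GFP ratio divided by the mean RFP/GFP ratio of the vehicle
    (``normalizer_condition``) wells; the vehicle wells therefore average to
    exactly 1.

    ``wells`` needs columns ``gfp``, ``rfp`` and ``condition``.
    """
    for col in ("gfp", "rfp", "condition"):
        if col not in wells.columns:
            raise ValueError(f"wells table missing column {col!r}")
    if (wells["gfp"] <= 0).any():
        raise ValueError("gfp signal must be positive in every well")
    if (wells["rfp"] < 0).any():
        raise ValueError("rfp signal must be non-negative")
    ratio = wells["rfp"] / wells["gfp"]
    dmso = ratio[wells["condition"] == normalizer_condition]
    if dmso.empty:
        raise ValueError(f"no wells with condition {normalizer_condition!r}")
    return (ratio / dmso.mean()).rename("autophagy_index")


def bliss_excess(
    matrix: pd.DataFrame, clamp: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Bliss-independence excess over a dose-combination inhibition matrix.

    ``matrix`` is indexed by doses of drug A with columns the doses of drug B;
    values are observed inhibition fractions in [0, 1] relative to the
    untreated baseline. The zero-dose row and column hold the single-agent
    responses. Under Bliss independence the expected combination inhibition is
    ``yA + yB − yA·yB``; the excess (observed − expected) is positive where
    the combination beats independence (synergy).

    Returns the per-cell excess over combination cells and a summary with the
    mean and peak excess in percentage points. Out-of-range observations are
    clamped into [0, 1] (and logged) when ``clamp`` is true, else rejected.
    """
    m = matrix.astype(float).copy()
    if 0 not in m.index or 0 not in m.columns:
        raise ValueError("dose matrix must include zero-dose row and column")
    if list(m.index) != sorted(m.index) or list(m.columns) != sorted(m.columns):
        raise ValueError("dose axes must be sorted ascending")
    out_of_range = int(((m.values < 0) | (m.values > 1)).sum())
    if out_of_range:
        if not clamp:
            raise ValueError(
                f"{out_of_range} inhibition values outside [0, 1] and clamping disabled"
            )
        logger.info("clamped %d inhibition values into [0, 1]", out_of_range)
        m = m.clip(0.0, 1.0)

    y_a = m.loc[:, 0]  # drug A alone, per A dose
    y_b = m.loc[0, :]  # drug B alone, per B dose
    expected = pd.DataFrame(
        np.add.outer(y_a.to_numpy(), y_b.to_numpy())
        - np.multiply.outer(y_a.to_numpy(), y_b.to_numpy()),
        index=m.index,
        columns=m.columns,
    )
    excess = m - expected
    combo = excess.loc[excess.index != 0, excess.columns != 0]
    summary = {
        "mean_excess_pct": float(combo.to_numpy().mean() * 100.0),
        "peak_excess_pct": float(combo.to_numpy().max() * 100.0),
        "n_combination_cells": int(combo.size),
        "n_clamped": out_of_range,
    }
    return combo, summary


def pip_percentages(
    raw_counts: Mapping[str, float] | Sequence[float],
    background: Mapping[str, float] | Sequence[float] | float = 0.0,
) -> dict[str, float]:
    """Phosphoinositide peak percentages from radiolabel HPLC scintillation counts.

    Background is subtracted from each of the six glycero-inositol peaks
    (clamping negative net counts to zero), and each net peak is expressed as
    a percentage of the summed net counts — the total phosphatidylinositol
    signal. Percentages sum to 100.
    """
    if isinstance(raw_counts, Mapping):
        missing = set(PIP_PEAKS) - set(raw_counts)
        if missing:
            raise ValueError(f"missing peaks: {sorted(missing)}")
        raw = np.array([raw_counts[p] for p in PIP_PEAKS], dtype=float)
    else:
        raw = np.asarray(raw_counts, dtype=float)
        if raw.shape != (len(PIP_PEAKS),):
            raise ValueError(f"expected {len(PIP_PEAKS)} peak counts")
    if isinstance(background, Mapping):
        bg = np.array([background.get(p, 0.0) for p in PIP_PEAKS], dtype=float)
    else:
        bg = np.broadcast_to(np.asarray(background, dtype=float), raw.shape)
    if (raw < 0).any() or (bg < 0).any():
        raise ValueError("counts and backgrounds must be non-negative")
    net = raw - bg
    n_clamped = int((net < 0).sum())
    if n_clamped:
        logger.info("clamped %d negative net peak counts to zero", n_clamped)
    net = np.maximum(net, 0.0)
    total = net.sum()
    if total == 0:
        raise ValueError("all net peak counts are zero; cannot form percentages")
    return dict(zip(PIP_PEAKS, (100.0 * net / total).tolist()))
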