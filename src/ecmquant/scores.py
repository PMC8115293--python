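"""Expression- and score-level computations.

qPCR relative expression (2^−ΔCt against the geometric mean of housekeeping
genes), fold changes, the fibroblast-signature (MAF) geometric-mean score with
median split, collagen-gene stripping, histology-score binarisation, and a
Kaplan–Meier / log-rank comparison used to exercise score groupings on
synthetic cohorts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "CtRecord",
    "relative_expression",
    "fold_change",
    "maf_score",
    "median_split",
    "strip_collagen_genes",
    "binarize_histology",
    "km_logrank",
    "LogrankResult",
    "ELASTOSIS_LADDER",
]

logger = logging.getLogger(__name__)

#: 11-point solar-elastosis ladder (Landi scoring), index 0..10; the binary
#: chronic-sun-damage cut falls between "2-" (index 5) and "2" (index 6).
ELASTOSIS_LADDER = ("0", "0+", "1-", "1", "1+", "2-", "2", "2+", "3-", "3", "3+")
_CSD_CUT_INDEX = 6


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target Ct and >=1 housekeeping-gene Ct values."""

    ct_target: float
    ct_housekeepers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_housekeepers) == 0:
            raise ValueError("need at least one housekeeping Ct")
        vals = (self.ct_target, *self.ct_housekeepers)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("Ct values must be finite and positive")


def relative_expression(r: CtRecord) -> float:
    """2^−ΔCt relative expression.

    ΔCt = ct_target − mean(ct_housekeepers); on the Ct (log2) scale the
    arithmetic mean of housekeeper Cts corresponds to the geometric mean of
    their expression levels.
    """
    dct = r.ct_target - float(np.mean(r.ct_housekeepers))
    return float(2.0 ** (-dct))


def fold_change(re_treated: float, re_control: float) -> float:
    """Ratio of relative expressions (treated over control)."""
    if re_control <= 0:
        raise ValueError("control relative expression must be positive")
    return re_treated / re_control


def maf_score(
    values: pd.DataFrame,
    signature_genes,
    zero_floor: float = 0.01,
) -> pd.Series:
    """Per-sample geometric mean of signature-gene expression.

    ``values`` is genes x samples on the log2(x+1)-normalised scale; the score
    is the geometric mean of the signature rows, taken directly on that scale.
    Signature genes absent from the matrix are dropped with a warning; values
    of zero (or below) are floored at ``zero_floor`` so the geometric mean
    stays defined.

    Raises if no signature gene is present.
    """
    signature_genes = list(signature_genes)
    present = [g for g in signature_genes if g in values.index]
    missing = sorted(set(signature_genes) - set(present))
    if missing:
        logger.warning("dropping %d signature genes absent from matrix: %s",
                       len(missing), ", ".join(missing[:10]))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    mat = values.loc[present].to_numpy(dtype=float)
    mat = np.where(mat > 0, mat, zero_floor)
    return pd.Series(gmean(mat, axis=0), index=values.columns, name="maf_score")


def median_split(scores: pd.Series) -> pd.Series:
    """Classify samples as "high" (score > cohort median) or "low" (<=).

    The tie rule puts the median itself in "low", so the assignment is
    deterministic; with distinct scores the groups differ in size by at most
    one.  Invariant under strictly monotone transforms of the scores.
    """
    s = pd.Series(scores)
    if s.empty:
        raise ValueError("no scores")
    med = float(s.median())
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


def strip_collagen_genes(
    signature_genes, pattern: str = r"^COL\d"
) -> tuple[list[str], list[str]]:
    """Remove collagen genes (default: symbols starting COL+digit) from a
    signature; returns (kept, removed) for audit."""
    rx = re.compile(pattern)
    kept = [g for g in signature_genes if not rx.match(g)]
    removed = [g for g in signature_genes if rx.match(g)]
    if not kept:
        logger.warning("signature is empty after removing collagen genes")
    return kept, removed


def binarize_histology(score_kind: str, raw_score) -> str:
    """Binarise an ordinal histology score.

    ``elastosis``: the 11-point 0…3+ ladder (given as an integer index 0–10
    or a ladder label) maps to "noCSD" for 0…2− and "CSD" for 2…3+.
    ``invasion``: the 0–4 invasion score maps to "low" for 0–2 and "high"
    for 3–4.
    """
    if score_kind == "elastosis":
        if isinstance(raw_score, str):
            if raw_score not in ELASTOSIS_LADDER:
                raise ValueError(f"unknown elastosis grade {raw_score!r}")
            idx = ELASTOSIS_LADDER.index(raw_score)
        else:
            idx = int(raw_score)
            if not 0 <= idx <= 10:
                raise ValueError("elastosis index must be 0..10")
        return "CSD" if idx >= _CSD_CUT_INDEX else "noCSD"
    if score_kind == "invasion":
        s = int(raw_score)
        if not 0 <= s <= 4:
            raise ValueError("invasion score must be 0..4")
        return "high" if s >= 3 else "low"
    raise ValueError("score_kind must be 'elastosis' or 'invasion'")


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    curves: dict  # group -> survival-function DataFrame


def km_logrank(groups: pd.Series, survival: pd.DataFrame) -> LogrankResult:
    """Kaplan–Meier curves per group and a two-sided log-rank test.

    ``groups`` maps sample id to group label (>=2 groups); ``survival`` has
    columns ``time`` (>0) and ``event`` (0/1) indexed by sample id.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = pd.Series(groups)
    df = survival.loc[groups.index].copy()
    df["group"] = groups.values
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    curves = {}
    for name, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(name))
        curves[name] = kmf.survival_function_
    return LogrankResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value), curves=curves
    )
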