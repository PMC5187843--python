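"""Count tabulation, size-factor normalization, and fold-change tables.

Per-sample counts (one alignment per read) are normalized with
median-of-ratios size factors: each sample's factor is the median over
species of its count divided by the species' geometric mean across
samples, computed on species detected in every sample.  Fold changes
between sample groups are classified against inclusive thresholds
(suppressed <= 0.5, elevated >= 2 by default), and a species is flagged
differential between two samples when a two-sided exact binomial test on
normalized totals gives p < 0.001 and |log2 fold change| >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class NormalizationError(ValueError):
    pass


def size_factors(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Species (rows) with any zero count are excluded from estimation, the
    standard contract of the estimator; ``pseudocount`` can be added to
    every entry for sparse matrices where no all-positive row exists.
    """
    if matrix.shape[1] < 2:
        raise NormalizationError("need at least two samples")
    counts = matrix.to_numpy(dtype=float) + pseudocount
    if (counts < 0).any():
        raise NormalizationError("negative counts")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no species detected in every sample; consider pseudocount > 0")
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalize(matrix: pd.DataFrame, factors: Optional[pd.Series] = None,
              pseudocount: float = 0.0) -> pd.DataFrame:
    """Divide each column by its size factor."""
    if factors is None:
        factors = size_factors(matrix, pseudocount=pseudocount)
    return matrix / factors


@dataclass(frozen=True)
class FoldChangeRecord:
    species: str
    mean_a: float
    mean_b: float
    fold_change: float  # B / A; inf when A == 0 and B > 0, nan when both 0
    label: str  # elevated | suppressed | neutral | undefined


def classify_value(fc: float, hi: float = 2.0, lo: float = 0.5) -> str:
    """Label one fold-change value; thresholds inclusive at both bounds."""
    if math.isnan(fc):
        return "undefined"
    if fc >= hi:
        return "elevated"
    if fc <= lo:
        return "suppressed"
    return "neutral"


def classify_fold_changes(normalized: pd.DataFrame,
                          groups: Mapping[str, Sequence[str]],
                          hi: float = 2.0, lo: float = 0.5,
                          numerator: Optional[str] = None,
                          denominator: Optional[str] = None
                          ) -> List[FoldChangeRecord]:
    """Fold change of group-mean normalized counts (numerator/denominator)
    per species, labelled against the inclusive thresholds.

    ``groups`` maps group name -> sample ids (non-empty, disjoint).  With
    exactly two groups the denominator defaults to the first and the
    numerator to the second.  Zero-denominator species are flagged
    (infinite fold change, label elevated when the numerator is positive,
    undefined when both means are zero), not dropped.
    """
    names = list(groups)
    if numerator is None or denominator is None:
        if len(names) != 2:
            raise ValueError("specify numerator/denominator for >2 groups")
        denominator, numerator = names
    seen: set = set()
    for g in (denominator, numerator):
        cols = set(groups[g])
        if not cols:
            raise ValueError(f"group {g!r} is empty")
        if cols & seen:
            raise ValueError("groups must be disjoint")
        seen |= cols
    a = normalized[list(groups[denominator])].mean(axis=1)
    b = normalized[list(groups[numerator])].mean(axis=1)
    out: List[FoldChangeRecord] = []
    for sp in normalized.index:
        ma, mb = float(a[sp]), float(b[sp])
        if ma == 0:
            fc = float("nan") if mb == 0 else float("inf")
        else:
            fc = mb / ma
        out.append(FoldChangeRecord(str(sp), ma, mb, fc,
                                    classify_value(fc, hi, lo)))
    return out


def is_differential(p_value: float, log2_fc: float,
                    p_max: float = 0.001,
                    min_abs_log2fc: float = 2.0) -> bool:
    """Differential-expression decision: p strictly below ``p_max`` AND
    |log2 fold change| at least ``min_abs_log2fc`` (inclusive)."""
    return p_value < p_max and abs(log2_fc) >= min_abs_log2fc


@dataclass(frozen=True)
class DifferentialFlag:
    species: str
    pair: Tuple[str, str]
    log2_fc: float
    p_value: float
    flagged: bool


def differential_flags(normalized: pd.DataFrame,
                       pairs: Sequence[Tuple[str, str]],
                       p_max: float = 0.001,
                       min_abs_log2fc: float = 2.0) -> List[DifferentialFlag]:
    """Flag species differential between sample pairs.

    The test is a two-sided exact binomial test on the species' rounded
    normalized counts against the null that the two samples contribute
    equally (p = 1/2) — a documented, dependency-free stand-in for the
    MA-plot based caller used at full scale; the thresholds (p < 0.001
    strict, |log2FC| >= 2 inclusive) are what downstream logic consumes.
    """
    out: List[DifferentialFlag] = []
    for (sa, sb) in pairs:
        for sp in normalized.index:
            ca = float(normalized.at[sp, sa])
            cb = float(normalized.at[sp, sb])
            if ca == 0 and cb == 0:
                out.append(DifferentialFlag(str(sp), (sa, sb), 0.0, 1.0, False))
                continue
            if ca == 0:
                lfc = float("inf")
            elif cb == 0:
                lfc = float("-inf")
            else:
                lfc = math.log2(cb / ca)
            na, nb = int(round(ca)), int(round(cb))
            p = float(stats.binomtest(nb, na + nb, 0.5).pvalue) \
                if na + nb > 0 else 1.0
            out.append(DifferentialFlag(
                str(sp), (sa, sb), lfc, p,
                is_differential(p, lfc, p_max, min_abs_log2fc)))
    return out


def counts_to_frame(counts: Mapping[str, Mapping[str, int]],
                    samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Species -> sample -> count mapping as a rectangular DataFrame with
    zeros for missing entries."""
    df = pd.DataFrame(counts).T.fillna(0)
    if samples is not None:
        df = df.reindex(columns=list(samples), fill_value=0)
    return df.astype(float)
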