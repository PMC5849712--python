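"""Comparative statistics: G-test, Wilcoxon rank-sum, and summary tables.

The G-test is the likelihood-ratio test of independence,
G = 2 Σ O ln(O/E) with E from the product of the margins; cells with
O = 0 contribute nothing. The Wilcoxon rank-sum test is exact (full
enumeration of group assignments) for small samples and uses a normal
approximation with tie-corrected variance and continuity correction
otherwise. Both report two-sided p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ecas_splice.as_caller import ALTA, ALTD, ASEvent, ES, IR
from ecas_splice.annotation_model import CDS, UTR5, UTR3
from ecas_splice.consequence_caller import ECAS_CLASS, NON_ECAS_CLASS


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _validate_table(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("contingency table requires non-negative integer counts")
    if arr.sum() <= 0:
        raise ValueError("contingency table grand total must be positive")
    return arr


def g_test(table, williams_correction: bool = False) -> TestResult:
    """Likelihood-ratio G-test of independence on an r x c count table.

    Williams' correction divides G by
    q = 1 + (N·Σ(1/rowᵢ) − 1)(N·Σ(1/colⱼ) − 1) / (6·N·(r−1)(c−1)).
    """
    arr = _validate_table(table)
    n = arr.sum()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    expected = np.outer(rows, cols) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(arr > 0, arr * np.log(arr / expected), 0.0)
    g = 2.0 * terms.sum()
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    if williams_correction:
        if np.any(rows == 0) or np.any(cols == 0):
            raise ValueError("Williams correction requires positive margins")
        q = 1.0 + (n * (1.0 / rows).sum() - 1.0) * (n * (1.0 / cols).sum() - 1.0) / (
            6.0 * n * df
        )
        g /= q
    g = max(g, 0.0)
    p = float(sps.chi2.sf(g, df))
    return TestResult(statistic=float(g), p_value=p, df=df, method="g_test")


def _rank(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values)


def wilcoxon_rank_sum(
    sample_a, sample_b, exact_max: int = 8
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test on two samples.

    Exact enumeration over all C(n+m, n) group assignments when
    min(n, m) <= ``exact_max``; otherwise a normal approximation with
    tie-corrected variance and 0.5 continuity correction. The statistic
    is the rank sum W of the first sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _rank(pooled)
    w = float(ranks[:n].sum())

    if min(n, m) <= exact_max:
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n + m), n)]
        )
        total = sums.size
        p_le = np.count_nonzero(sums <= w + 1e-9) / total
        p_ge = np.count_nonzero(sums >= w - 1e-9) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(statistic=w, p_value=p, method="wilcoxon_exact")

    mean = n * (n + m + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n + m) * (n + m - 1.0))
    var = n * m / 12.0 * ((n + m + 1.0) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, p_value=1.0, method="wilcoxon_normal")
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * sps.norm.sf(z))
    return TestResult(statistic=w, p_value=min(p, 1.0), method="wilcoxon_normal")


LENGTH_TYPES = (ES, IR, ALTD, ALTA)


def length_summary(
    labeled_events: list[tuple[ASEvent, str]]
) -> pd.DataFrame:
    """Mean/median event length per type per conservation class + Wilcoxon p.

    ``labeled_events`` pairs each event (one per signature per class) with
    "ECAS" or "non-ECAS". A class with fewer than two lengths in a type
    propagates NA for the test.
    """
    rows = []
    for etype in LENGTH_TYPES:
        lengths = {
            cls: [e.event_length for e, label in labeled_events
                  if label == cls and e.event_type == etype]
            for cls in (ECAS_CLASS, NON_ECAS_CLASS)
        }
        try:
            if not lengths[ECAS_CLASS] or not lengths[NON_ECAS_CLASS]:
                raise ValueError("empty class")
            if min(len(lengths[ECAS_CLASS]), len(lengths[NON_ECAS_CLASS])) < 2:
                raise ValueError("degenerate sample")
            p = wilcoxon_rank_sum(lengths[ECAS_CLASS], lengths[NON_ECAS_CLASS]).p_value
        except ValueError:
            p = float("nan")
        for cls in (ECAS_CLASS, NON_ECAS_CLASS):
            vals = lengths[cls]
            rows.append(
                {
                    "event_type": etype,
                    "class": cls,
                    "n": len(vals),
                    "mean_bp": round(float(np.mean(vals)), 2) if vals else float("nan"),
                    "median_bp": float(np.median(vals)) if vals else float("nan"),
                    "wilcoxon_p": p,
                }
            )
    return pd.DataFrame(rows)


def position_comparison(
    labeled_events: list[tuple[ASEvent, str]]
) -> pd.DataFrame:
    """Region distribution (CDS/5'UTR/3'UTR) per class with per-region G-tests.

    Spanning labels count toward CDS (the junction touches coding
    sequence). Each region gets a 2x2 G-test of class × in-region.
    """
    def region_of(e: ASEvent) -> str:
        return CDS if e.region not in (UTR5, UTR3) else e.region

    counts = {
        cls: {r: 0 for r in (CDS, UTR5, UTR3)} for cls in (ECAS_CLASS, NON_ECAS_CLASS)
    }
    for e, label in labeled_events:
        counts[label][region_of(e)] += 1

    totals = {cls: sum(counts[cls].values()) for cls in counts}
    rows = []
    for region in (CDS, UTR5, UTR3):
        in_e = counts[ECAS_CLASS][region]
        in_n = counts[NON_ECAS_CLASS][region]
        table = [
            [in_e, totals[ECAS_CLASS] - in_e],
            [in_n, totals[NON_ECAS_CLASS] - in_n],
        ]
        try:
            p = g_test(table).p_value
        except ValueError:
            p = float("nan")
        for cls, n_in in ((ECAS_CLASS, in_e), (NON_ECAS_CLASS, in_n)):
            rows.append(
                {
                    "region": region,
                    "class": cls,
                    "n_events": n_in,
                    "pct": round(100.0 * n_in / totals[cls], 2) if totals[cls] else 0.0,
                    "g_test_p": p,
                }
            )
    return pd.DataFrame(rows)
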