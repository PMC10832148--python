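"""Arm-level over-fragmentation test.

Highly fragmented arms (many short segments) can flag chromothripsis-like
events or caller artifacts.  Per chromosome arm, segments are labelled
*short* when they span less than a fraction ``mu`` (default 0.2) of the arm;
under the null, the short/long label is Bernoulli(``mu``), so the number of
short segments ``s`` among ``k`` follows Binomial(k, mu) and the one-tailed
p-value is P(X >= s).  Arms are only tested when they carry enough segments
and show a minimal total ploidy jump; p-values are Bonferroni-controlled
across the tested arms.  This is a triage signal, not a substitute for
dedicated chromothripsis/kataegis callers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import arm_lengths, assign_arms, smooth_segments

__all__ = [
    "classify_fragment_lengths",
    "arm_fragmentation_test",
    "ploidy_jump",
    "fragmentation_report",
]


def classify_fragment_lengths(lengths, arm_length: float, mu: float = 0.2):
    """Label segment lengths long (>= mu * arm length) or short (vectorized)."""
    if not 0 < mu < 1:
        raise ValueError("mu must be in (0, 1)")
    lengths = np.asarray(lengths, dtype=float)
    return np.where(lengths >= mu * arm_length, "long", "short")


def arm_fragmentation_test(k: int, s: int, mu: float = 0.2, n_tests: int = 1, alpha: float = 0.05) -> dict:
    """Exact upper binomial tail P(X >= s) with Bonferroni control."""
    if not 0 <= s <= k:
        raise ValueError("need 0 <= s <= k")
    p = float(stats.binom.sf(s - 1, k, mu)) if k > 0 else 1.0
    return {
        "p_value": p,
        "significant": bool(p < alpha / max(n_tests, 1)),
        "alpha_adjusted": alpha / max(n_tests, 1),
    }


def ploidy_jump(ploidies) -> int:
    """Sum of absolute ploidy differences between consecutive segments."""
    ploidies = np.asarray(ploidies)
    if ploidies.size < 2:
        return 0
    return int(np.abs(np.diff(ploidies)).sum())


def fragmentation_report(
    segments: pd.DataFrame,
    build: str = "GRCh38",
    mu: float = 0.2,
    alpha: float = 0.05,
    min_segments: int = 10,
    min_jump: int = 1,
    smooth: bool = True,
    max_gap: float = 1e6,
) -> pd.DataFrame:
    """Per-arm over-fragmentation table.

    Segments are smoothed first by default (same-state neighbours within
    ``max_gap`` merged) so caller-induced spurious breakpoints do not
    inflate the test, then split at centromeres and assigned to arms.
    Columns: ``arm, k, s, jump, tested, p_value, significant``.
    """
    if smooth:
        segments = smooth_segments(segments, max_gap=max_gap)
    arms = assign_arms(segments, build)
    if arms.empty:
        return pd.DataFrame(
            columns=["arm", "k", "s", "jump", "tested", "p_value", "significant"]
        )
    lengths = arm_lengths(build)
    rows = []
    for arm, grp in arms.groupby("arm"):
        grp = grp.sort_values("from")
        seg_len = (grp["to"] - grp["from"] + 1).to_numpy()
        labels = classify_fragment_lengths(seg_len, lengths[arm], mu)
        jump = ploidy_jump((grp["Major"] + grp["minor"]).to_numpy())
        rows.append(
            {
                "arm": arm,
                "k": len(grp),
                "s": int((labels == "short").sum()),
                "jump": jump,
            }
        )
    table = pd.DataFrame(rows)
    table["tested"] = (table["k"] >= min_segments) & (table["jump"] >= min_jump)
    n_tests = int(table["tested"].sum())
    pvals, sig = [], []
    for _, row in table.iterrows():
        if row["tested"] and n_tests > 0:
            res = arm_fragmentation_test(row["k"], row["s"], mu, n_tests, alpha)
            pvals.append(res["p_value"])
            sig.append(res["significant"])
        else:
            pvals.append(np.nan)
            sig.append(False)
    table["p_value"] = pvals
    table["significant"] = sig
    return table.sort_values("arm").reset_index(drop=True)
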