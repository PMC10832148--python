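"""Per-mutation cancer cell fractions with multiplicity phasing.

A mutation's CCF follows from its VAF once its multiplicity ``m`` is known,
by inverting the peak equation::

    c_m(pi, v) = v * [(nA + nB - 2) * pi + 2] / (m * pi)

For amplified simple karyotypes (2:0, 2:1, 2:2) ``m`` is ambiguous between
1 and 2.  Two phasing strategies are provided:

* *entropy* — a two-component binomial mixture anchored at the theoretical
  peaks ``v1``/``v2``; each mutation gets posterior responsibilities
  ``z = (z1, z2)`` and their entropy ``H(z)``.  Around the crossing of the
  two densities the entropy spikes and multiplicity cannot be phased from
  VAFs: mutations inside the bracketed spike ``[h1, h2]`` are reported NA
  (CCF NA as well).  This is the uncertainty-aware method whose NA fraction
  feeds the CCF QC status.
* *rough* — a hard VAF cut at the mixture-weighted midpoint between the two
  peaks; every mutation is assigned, no uncertainty is modelled, so this
  method always passes QC.

Per-mutation CCFs keep the binomial read-count noise of the VAFs: clonal
mutations spread *around* 1 and are deliberately not clipped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import SIMPLE_KARYOTYPES, expected_vaf

__all__ = [
    "ccf_from_vaf",
    "phase_entropy",
    "phase_rough",
    "ccf_qc",
    "binomial_entropy_profile",
]

_PHASEABLE = {"2:0", "2:1", "2:2"}  # m in {1, 2}; 1:0 and 1:1 are always m = 1
_GRID_STEP = 1e-3


def ccf_from_vaf(v, m, n_a: int, n_b: int, purity: float):
    """CCF of a mutation with multiplicity ``m`` (vectorized; NA propagates)."""
    if purity <= 0 or purity > 1:
        raise ValueError("purity must be in (0, 1]")
    v = np.asarray(v, dtype=float)
    m = np.asarray(m, dtype=float)
    out = v * ((n_a + n_b - 2) * purity + 2.0) / (m * purity)
    return out


def _mixture_weights(vafs: np.ndarray, v1: float, v2: float, n_trials: int):
    """Mixing proportions from counts in the 1-99% band of each component.

    Mutations falling in both bands go to the closer peak; mutations in
    neither are split proportionally to the unambiguous counts.
    """
    lo1, hi1 = (
        stats.binom.ppf([0.01, 0.99], n_trials, min(v1, 1 - 1e-9)) / n_trials
    )
    lo2, hi2 = (
        stats.binom.ppf([0.01, 0.99], n_trials, min(v2, 1 - 1e-9)) / n_trials
    )
    in1 = (vafs >= lo1) & (vafs <= hi1)
    in2 = (vafs >= lo2) & (vafs <= hi2)
    closer1 = np.abs(vafs - v1) <= np.abs(vafs - v2)
    n1 = float(np.sum((in1 & ~in2) | (in1 & in2 & closer1)))
    n2 = float(np.sum((in2 & ~in1) | (in1 & in2 & ~closer1)))
    n_out = float(np.sum(~in1 & ~in2))
    if n1 + n2 == 0:
        pi1 = 0.5
    else:
        pi1 = n1 / (n1 + n2)
    # spread unassigned mass proportionally; leaves pi1 unchanged
    return pi1, n1 + n_out * pi1, n2 + n_out * (1 - pi1)


def _responsibilities(nv, dp, v1, v2, pi1):
    l1 = stats.binom.logpmf(nv, dp, min(v1, 1 - 1e-9)) + np.log(max(pi1, 1e-12))
    l2 = stats.binom.logpmf(nv, dp, min(v2, 1 - 1e-9)) + np.log(
        max(1 - pi1, 1e-12)
    )
    mx = np.maximum(l1, l2)
    e1 = np.exp(l1 - mx)
    e2 = np.exp(l2 - mx)
    z1 = e1 / (e1 + e2)
    return z1, 1.0 - z1


def _entropy(z1, z2):
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -z1 * np.log(np.clip(z1, 1e-300, None)) - z2 * np.log(
            np.clip(z2, 1e-300, None)
        )
    return np.where((z1 <= 0) | (z2 <= 0), 0.0, h)


def binomial_entropy_profile(
    v1: float, v2: float, n_trials: int, pi1: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Assignment entropy H(z(v)) on a VAF grid between the two peaks."""
    grid = np.arange(v1, v2 + _GRID_STEP / 2, _GRID_STEP)
    counts = np.round(grid * n_trials)
    z1, z2 = _responsibilities(counts, n_trials, v1, v2, pi1)
    return grid, _entropy(z1, z2)


#: Entropy of responsibilities (0.9, 0.1): inside the spike neither
#: multiplicity reaches 90% posterior support and phasing is abstained.
_H_SPIKE = float(-(0.9 * np.log(0.9) + 0.1 * np.log(0.1)))


def _na_range(v1: float, v2: float, n_trials: int, pi1: float) -> tuple[float, float]:
    """Bracket the entropy spike between the two theoretical peaks.

    ``[h1, h2]`` are the outermost VAF grid points around the entropy
    maximum where H(z) still exceeds the 90%-responsibility level; their
    width shrinks with coverage (steeper responsibility switch) and purity
    (wider peak separation).
    """
    grid, h = binomial_entropy_profile(v1, v2, n_trials, pi1)
    if grid.size < 5:
        return v1 + _GRID_STEP, v2 - _GRID_STEP
    peak = int(np.argmax(h))
    above = h >= min(_H_SPIKE, h[peak])
    i = peak
    while i > 0 and above[i - 1]:
        i -= 1
    j = peak
    while j < grid.size - 1 and above[j + 1]:
        j += 1
    h1, h2 = grid[i], grid[j]
    # keep strictly inside (v1, v2)
    h1 = float(np.clip(h1, v1 + _GRID_STEP / 2, v2 - _GRID_STEP / 2))
    h2 = float(np.clip(h2, h1, v2 - _GRID_STEP / 2))
    return h1, h2


def _base_frame(nv, dp, method: str) -> pd.DataFrame:
    nv = np.asarray(nv, dtype=float)
    dp = np.asarray(dp, dtype=float)
    return pd.DataFrame(
        {
            "NV": nv.astype(int),
            "DP": dp.astype(int),
            "VAF": nv / dp,
            "method": method,
        }
    )


def phase_entropy(
    nv, dp, n_a: int, n_b: int, purity: float, min_mutations: int = 20
) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Entropy-based multiplicity phasing and CCFs for one karyotype pool.

    Returns the per-mutation table (columns ``m, z1, z2, H, ccf``; ``m`` and
    ``ccf`` are NaN inside the uncertainty range) and the NA VAF range
    ``(h1, h2)`` (None for karyotypes with a single admissible multiplicity).
    """
    karyotype = f"{max(n_a, n_b)}:{min(n_a, n_b)}"
    if karyotype not in SIMPLE_KARYOTYPES:
        raise ValueError(f"CCF phasing supports simple karyotypes, not {karyotype}")
    df = _base_frame(nv, dp, "entropy")
    if len(df) < min_mutations:
        raise ValueError(f"need >= {min_mutations} mutations, got {len(df)}")
    if karyotype not in _PHASEABLE:
        df["m"] = 1.0
        df["z1"], df["z2"], df["H"] = 1.0, 0.0, 0.0
        df["ccf"] = ccf_from_vaf(df["VAF"], 1, n_a, n_b, purity)
        return df, None

    v1 = expected_vaf(1, n_a, n_b, purity)
    v2 = expected_vaf(2, n_a, n_b, purity)
    n_med = int(np.median(df["DP"]))
    pi1, _, _ = _mixture_weights(df["VAF"].to_numpy(), v1, v2, n_med)
    z1, z2 = _responsibilities(
        df["NV"].to_numpy(), df["DP"].to_numpy(), v1, v2, pi1
    )
    h = _entropy(z1, z2)
    h1, h2 = _na_range(v1, v2, n_med, pi1)
    vaf = df["VAF"].to_numpy()
    na = (vaf >= h1) & (vaf <= h2)
    m = np.where(z1 >= z2, 1.0, 2.0)
    m[na] = np.nan
    df["m"], df["z1"], df["z2"], df["H"] = m, z1, z2, h
    df["ccf"] = ccf_from_vaf(vaf, m, n_a, n_b, purity)
    df["ccf_outlier"] = df["ccf"] > 1.5  # unclipped, but flagged as artifacts
    if na.all():
        warnings.warn(
            "all mutations fall in the multiplicity-uncertainty range "
            f"[{h1:.3f}, {h2:.3f}]; no CCF assignable"
        )
    return df, (h1, h2)


def phase_rough(nv, dp, n_a: int, n_b: int, purity: float, min_mutations: int = 20) -> pd.DataFrame:
    """Hard-cut multiplicity phasing: never abstains.

    The cut sits at the mixture-weighted midpoint
    ``o = v1 + (v2 - v1) * pi1`` between the theoretical peaks.
    """
    karyotype = f"{max(n_a, n_b)}:{min(n_a, n_b)}"
    if karyotype not in SIMPLE_KARYOTYPES:
        raise ValueError(f"CCF phasing supports simple karyotypes, not {karyotype}")
    df = _base_frame(nv, dp, "rough")
    if len(df) < min_mutations:
        raise ValueError(f"need >= {min_mutations} mutations, got {len(df)}")
    if karyotype not in _PHASEABLE:
        df["m"] = 1.0
        df["ccf"] = ccf_from_vaf(df["VAF"], 1, n_a, n_b, purity)
        return df
    v1 = expected_vaf(1, n_a, n_b, purity)
    v2 = expected_vaf(2, n_a, n_b, purity)
    n_med = int(np.median(df["DP"]))
    pi1, _, _ = _mixture_weights(df["VAF"].to_numpy(), v1, v2, n_med)
    cut = v1 + (v2 - v1) * pi1
    m = np.where(df["VAF"].to_numpy() < cut, 1.0, 2.0)
    df["m"] = m
    df["cut"] = cut
    df["ccf"] = ccf_from_vaf(df["VAF"], m, n_a, n_b, purity)
    df["ccf_outlier"] = df["ccf"] > 1.5
    return df


def ccf_qc(estimates: pd.DataFrame, na_cutoff: float = 0.10) -> dict:
    """Pass/fail from the fraction of unassignable CCFs.

    Fails when the NA fraction strictly exceeds ``na_cutoff`` (default 10%);
    the rough method never produces NAs and therefore always passes.
    """
    n = len(estimates)
    if n == 0:
        return {"status": "cannot_qc", "na_fraction": None, "n_mutations": 0}
    na_frac = float(estimates["m"].isna().mean())
    return {
        "status": "fail" if na_frac > na_cutoff else "pass",
        "na_fraction": na_frac,
        "n_mutations": n,
    }
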