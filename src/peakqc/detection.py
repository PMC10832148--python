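"""Empirical VAF peak detection.

Two complementary detectors:

* :func:`kde_peaks` — Gaussian kernel density estimate of the VAF
  distribution with a fixed bandwidth, returning local maxima above a
  relative height cut (1/20 of the tallest peak by default);
* :func:`fit_binomial_mixture` — maximum-likelihood finite binomial mixture
  on the raw read counts, fitted by EM for each component count ``w`` up to
  ``max_w``, selected by the integrated classification likelihood (ICL):
  the BIC penalized further by the entropy of the posterior responsibilities,
  so that overlapping components are charged for their assignment
  uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.special import gammaln, logsumexp

__all__ = ["DataPeak", "BinomialMixtureFit", "kde_peaks", "fit_binomial_mixture", "count_support"]

_GRID_STEP = 1e-3  # VAF grid resolution for the density estimate


@dataclass(frozen=True)
class DataPeak:
    """One detected peak of the empirical VAF distribution."""

    position: float
    height: float
    support: int  # mutations in the 0.01-wide bin containing the peak
    method: str = "kde"


@dataclass
class BinomialMixtureFit:
    """A fitted finite binomial mixture over (NV, DP) read counts."""

    n_components: int
    probs: np.ndarray  # binomial success probabilities, ascending
    weights: np.ndarray  # mixing proportions, sum to 1
    responsibilities: np.ndarray  # (n_mutations, n_components)
    log_likelihood: float
    icl: float
    converged: bool = True

    def peaks(self, vafs: np.ndarray | None = None) -> list[DataPeak]:
        out = []
        for p, w in zip(self.probs, self.weights):
            support = 0
            if vafs is not None:
                support = count_support(vafs, p)
            out.append(DataPeak(float(p), float(w), support, method="mixture"))
        return out


def kde_peaks(
    vafs,
    bandwidth: float = 0.01,
    min_rel_height: float = 1 / 20,
    min_mutations: int = 1,
) -> list[DataPeak]:
    """Local maxima of a fixed-bandwidth Gaussian KDE of the VAFs.

    The density is evaluated on a 0.001-step grid over [0, 1]; peaks lower
    than ``min_rel_height`` times the tallest peak are discarded (an
    empirical cut against noise bumps).  Peaks are returned sorted by
    position, each annotated with the number of mutations in the 0.01-wide
    bin containing it.
    """
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size == 0:
        raise ValueError("no VAFs to detect peaks from")
    if vafs.size < min_mutations:
        raise ValueError(f"need >= {min_mutations} mutations, got {vafs.size}")
    grid = np.arange(0.0, 1.0 + _GRID_STEP / 2, _GRID_STEP)
    hist, _ = np.histogram(vafs, bins=grid.size, range=(0.0, 1.0 + _GRID_STEP))
    density = gaussian_filter1d(
        hist.astype(float), sigma=bandwidth / _GRID_STEP, mode="constant"
    )
    density /= max(density.sum() * _GRID_STEP, np.finfo(float).tiny)
    # pad so that peaks at the support boundary are still local maxima;
    # require a minimum prominence (same relative cut) so that sampling
    # wiggles on a cluster shoulder do not split one peak into several
    padded = np.concatenate(([0.0], density, [0.0]))
    prominence = density.max() * min_rel_height
    idx, _ = signal.find_peaks(padded, prominence=prominence)
    idx = idx - 1
    if idx.size == 0:
        return []
    heights = density[idx]
    cut = heights.max() * min_rel_height
    keep = heights >= cut
    out = [
        DataPeak(
            position=float(grid[i]),
            height=float(h),
            support=count_support(vafs, float(grid[i])),
            method="kde",
        )
        for i, h in zip(idx[keep], heights[keep])
    ]
    return sorted(out, key=lambda p: p.position)


def count_support(vafs, peak_position: float) -> int:
    """Mutations in the 0.01-wide VAF bin containing ``peak_position``.

    Bins are ``[k/100, (k+1)/100)``; the final bin ``[0.99, 1.00]`` is
    right-closed so a peak at 1.0 counts mutations with VAF == 1.
    """
    vafs = np.asarray(vafs, dtype=float)
    k = min(int(np.floor(peak_position * 100 + 1e-9)), 99)
    lo, hi = k / 100.0, (k + 1) / 100.0
    if k == 99:
        return int(np.sum((vafs >= lo) & (vafs <= hi)))
    return int(np.sum((vafs >= lo) & (vafs < hi)))


def _binom_logpmf(nv, dp, p):
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return (
        gammaln(dp + 1)
        - gammaln(nv + 1)
        - gammaln(dp - nv + 1)
        + nv * np.log(p)
        + (dp - nv) * np.log1p(-p)
    )


def _em_fit(nv, dp, p_init, max_iter=300, tol=1e-6):
    n = nv.size
    w = p_init.size
    weights = np.full(w, 1.0 / w)
    probs = p_init.copy()
    prev_ll = -np.inf
    resp = np.full((n, w), 1.0 / w)
    for _ in range(max_iter):
        log_comp = _binom_logpmf(nv[:, None], dp[:, None], probs[None, :])
        log_w = np.log(np.clip(weights, 1e-12, None))
        log_joint = log_comp + log_w[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_joint - log_norm[:, None])
        weights = resp.mean(axis=0)
        probs = (resp * nv[:, None]).sum(axis=0) / np.maximum(
            (resp * dp[:, None]).sum(axis=0), 1e-12
        )
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(probs)
    return probs[order], weights[order], resp[:, order], prev_ll


def fit_binomial_mixture(
    nv,
    dp,
    max_w: int = 4,
    n_restarts: int = 5,
    seed: int = 0,
) -> BinomialMixtureFit:
    """EM fit of binomial mixtures with ``w = 1..max_w``; ICL model selection.

    Each ``w`` is initialized from evenly spread VAF quantiles plus
    ``n_restarts`` random perturbations drawn from a generator seeded by
    ``seed`` (fully deterministic).  The selected fit minimizes::

        ICL = -logL + sum_x H(z_x) + 0.5 * n_params * log(n)

    ties broken toward fewer components.
    """
    nv = np.asarray(nv, dtype=float)
    dp = np.asarray(dp, dtype=float)
    if nv.size == 0 or nv.size != dp.size:
        raise ValueError("NV/DP must be equal-length non-empty arrays")
    if np.any(nv > dp):
        raise ValueError("NV must not exceed DP")
    vafs = nv / dp
    rng = np.random.default_rng(seed)
    degenerate = np.all(nv == 0)
    best = None
    for w in range(1, max_w + 1):
        inits = [np.quantile(vafs, (np.arange(w) + 0.5) / w)]
        for _ in range(n_restarts):
            jitter = rng.uniform(-0.05, 0.05, size=w)
            inits.append(np.clip(inits[0] + jitter, 1e-4, 1 - 1e-4))
        for p0 in inits:
            probs, weights, resp, ll = _em_fit(nv, dp, np.asarray(p0, dtype=float))
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.nansum(resp * np.log(np.clip(resp, 1e-300, None)))
            n_params = 2 * w - 1
            icl = -ll + ent + 0.5 * n_params * np.log(nv.size)
            fit = BinomialMixtureFit(
                n_components=w,
                probs=probs,
                weights=weights,
                responsibilities=resp,
                log_likelihood=ll,
                icl=float(icl),
            )
            if best is None or fit.icl < best.icl - 1e-9 or (
                abs(fit.icl - best.icl) <= 1e-9 and w < best.n_components
            ):
                best = fit
        if degenerate:
            import warnings

            warnings.warn("all NV == 0: returning single-component fit")
            break
    return best
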