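"""Automatic purity-tolerance calibration from false-positive-rate curves.

The choice of the purity tolerance ``epsilon`` trades sensitivity against
false passes, and the right value depends on data quality.  This module
simulates, for a grid of (purity, coverage) cells, borderline-bad inputs:
tumors generated at true purity ``pi`` but QC-ed at input purity
``pi + epsilon + phi`` with ``phi ~ U[0, 0.03]`` — inputs whose purity error strictly exceeds the
tolerance and therefore must fail.  QC runs in strict mode (band factor 1,
no sigma slack) so the band being calibrated is the tolerance itself.
The fraction that nevertheless passes is the false positive rate (FPR) of
that cell.  Per cell, a binomial GLM (logit link) of FPR on ``epsilon`` is
inverted to find the largest ``epsilon`` keeping the FPR under a target;
the per-cell values are interpolated across the grid with a non-smoothing
piecewise-cubic (Akima) tensor interpolant (bilinear fallback for degenerate
grids, reported in the output).  No extrapolation outside the training hull.

A small pre-computed grid ships with the package so
:func:`suggest_epsilon` works out of the box; it can be regenerated
bit-identically from its stored seed with :func:`build_fpr_grid`.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .qc import CopyNumberQC
from .simulate import SimConfig, simulate_tumor

__all__ = ["FPRGrid", "build_fpr_grid", "suggest_epsilon", "load_frozen_grid"]

DEFAULT_PURITIES = (0.15, 0.35, 0.55, 0.75, 0.9)
DEFAULT_COVERAGES = (20.0, 45.0, 70.0, 95.0, 120.0)
DEFAULT_EPSILONS = tuple(np.round(np.arange(0.01, 0.101, 0.01), 3))


@dataclass
class FPRGrid:
    """False-positive-rate surface over (purity, coverage, epsilon)."""

    purities: tuple
    coverages: tuple
    epsilons: tuple
    passes: np.ndarray  # shape (n_purity, n_coverage, n_epsilon), int
    reps: int
    seed: int
    sim: dict = field(default_factory=dict)

    @property
    def fpr(self) -> np.ndarray:
        return self.passes / self.reps

    def to_json(self, path=None) -> str | None:
        d = asdict(self)
        d["passes"] = self.passes.tolist()
        text = json.dumps(d, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source: str) -> "FPRGrid":
        d = json.loads(source)
        d["passes"] = np.asarray(d["passes"], dtype=int)
        d["purities"] = tuple(d["purities"])
        d["coverages"] = tuple(d["coverages"])
        d["epsilons"] = tuple(d["epsilons"])
        return cls(**d)


def _cell_seed(seed: int, ip: int, ic: int, ie: int, rep: int) -> int:
    ss = np.random.SeedSequence([seed, ip, ic, ie, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def build_fpr_grid(
    purities=DEFAULT_PURITIES,
    coverages=DEFAULT_COVERAGES,
    epsilons=DEFAULT_EPSILONS,
    reps: int = 10,
    seed: int = 0,
    n_chromosomes: int = 4,
    muts_per_mb: float = 2.0,
    progress: bool = False,
) -> FPRGrid:
    """Simulate the FPR surface (deterministic given ``seed``)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    passes = np.zeros((len(purities), len(coverages), len(epsilons)), dtype=int)
    for ip, purity in enumerate(purities):
        for ic, cov in enumerate(coverages):
            for ie, eps in enumerate(epsilons):
                for rep in range(reps):
                    s = _cell_seed(seed, ip, ic, ie, rep)
                    rng = np.random.default_rng(s)
                    phi = rng.uniform(0.0, 0.03)
                    muts, segs, true_pi = simulate_tumor(
                        SimConfig(
                            purity=purity,
                            coverage=cov,
                            n_chromosomes=n_chromosomes,
                            muts_per_mb=muts_per_mb,
                            seed=s,
                        )
                    )
                    input_purity = float(np.clip(true_pi + eps + phi, 0.01, 1.0))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = CopyNumberQC(muts, segs, input_purity).fit(
                            epsilon=eps, sigma=0.0, band_factor=1.0
                        )
                    if res.status == "pass":
                        passes[ip, ic, ie] += 1
            if progress:
                print(f"purity {purity} coverage {cov} done")
    return FPRGrid(
        purities=tuple(purities),
        coverages=tuple(coverages),
        epsilons=tuple(epsilons),
        passes=passes,
        reps=reps,
        seed=seed,
        sim={"n_chromosomes": n_chromosomes, "muts_per_mb": muts_per_mb},
    )


def load_frozen_grid() -> FPRGrid:
    """The pre-computed grid bundled with the package."""
    ref = importlib.resources.files("peakqc.data") / "fpr_grid.json"
    return FPRGrid.from_json(ref.read_text())


def _invert_cell(epsilons, passes, reps, max_fpr, bounds) -> float:
    """Largest epsilon with GLM-predicted FPR <= max_fpr, capped to bounds."""
    import statsmodels.api as sm

    eps = np.asarray(epsilons, dtype=float)
    y = np.column_stack([passes, reps - passes]).astype(float)
    lo, hi = bounds
    if passes.sum() == 0:
        return float(hi)  # FPR zero everywhere: tolerate the loosest epsilon
    if np.all(passes == reps):
        return float(lo)  # FPR one everywhere: even the floor fails the target
    x = sm.add_constant(eps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    target = np.log(max_fpr / (1 - max_fpr))
    if abs(b1) < 1e-12:
        pred = 1 / (1 + np.exp(-b0))
        return float(hi if pred <= max_fpr else lo)
    eps_star = (target - b0) / b1
    if b1 < 0:
        # decreasing FPR in epsilon (noise): any epsilon above eps_star works
        return float(np.clip(hi, lo, hi))
    return float(np.clip(eps_star, lo, hi))


def _tensor_interpolate(purities, coverages, values, purity, coverage):
    """Akima-type tensor interpolation; bilinear fallback for small grids."""
    from scipy.interpolate import Akima1DInterpolator, RegularGridInterpolator

    purities = np.asarray(purities, dtype=float)
    coverages = np.asarray(coverages, dtype=float)
    if purities.size >= 3 and coverages.size >= 3:
        # interpolate along coverage for each purity row, then along purity
        row_vals = np.array(
            [
                Akima1DInterpolator(coverages, values[i])(coverage)
                for i in range(purities.size)
            ]
        )
        return float(Akima1DInterpolator(purities, row_vals)(purity)), "akima"
    interp = RegularGridInterpolator(
        (purities, coverages), values, method="linear"
    )
    return float(interp([[purity, coverage]])[0]), "bilinear"


def suggest_epsilon(
    purity: float,
    coverage: float,
    max_fpr: float = 0.10,
    bounds: tuple[float, float] = (0.01, 0.1),
    grid: FPRGrid | None = None,
) -> dict:
    """Data-quality-aware purity tolerance for a sample.

    Returns ``{"epsilon", "interpolation", "cell_epsilons"}``.  Queries
    outside the training hull raise (no extrapolation).
    """
    if grid is None:
        grid = load_frozen_grid()
    purs = np.asarray(grid.purities, dtype=float)
    covs = np.asarray(grid.coverages, dtype=float)
    if not (purs.min() <= purity <= purs.max()) or not (
        covs.min() <= coverage <= covs.max()
    ):
        raise ValueError(
            f"query ({purity}, {coverage}) outside the training hull "
            f"purity [{purs.min()}, {purs.max()}], "
            f"coverage [{covs.min()}, {covs.max()}]"
        )
    cell = np.zeros((purs.size, covs.size))
    for ip in range(purs.size):
        for ic in range(covs.size):
            cell[ip, ic] = _invert_cell(
                grid.epsilons, grid.passes[ip, ic], grid.reps, max_fpr, bounds
            )
    value, method = _tensor_interpolate(purs, covs, cell, purity, coverage)
    return {
        "epsilon": float(np.clip(value, *bounds)),
        "interpolation": method,
        "cell_epsilons": cell,
    }
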