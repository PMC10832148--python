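"""Synthetic tumor generator at read-count level.

Emulates the bulk-sequencing signal the QC engine consumes: per-chromosome
Poisson-distributed breakpoints, karyotypes drawn from a Dirichlet-weighted
categorical over the simple states (concentration 1 for 1:0, 1 for 2:0, 6
for 1:1, 2 for 2:1, 1 for 2:2 — the empirical prevalence in large pan-cancer
cohorts), Poisson sequencing depth and binomial alt-read counts around the
theoretical VAF peaks.  Optionally a two-subclone segment generated under an
explicit evolution model.  No read-level artifacts (mapping noise, strand
bias) are simulated: counts are exact binomial draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import peaks as pk
from .genome import arm_table

__all__ = ["SimConfig", "simulate_tumor", "corrupt_purity"]

DEFAULT_KARYOTYPE_WEIGHTS = {"1:0": 1.0, "2:0": 1.0, "1:1": 6.0, "2:1": 2.0, "2:2": 1.0}

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic tumor."""

    purity: float = 0.8
    coverage: float = 90.0
    segments_per_chromosome: float = 6.0
    karyotype_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_KARYOTYPE_WEIGHTS)
    )
    muts_per_mb: float = 2.0
    n_chromosomes: int = 22
    build: str = "GRCh38"
    subclonal: dict | None = None  # {state1, state2, rho1, model, n_mutations}
    seed: int = 0
    detection_floor: float = 0.03
    #: minimum alt-supporting reads for a mutation to be emitted: a somatic
    #: caller cannot report a variant with zero supporting reads.  Raise to
    #: ~3 to emulate stricter caller detection thresholds; that truncation
    #: visibly biases low-coverage VAF distributions.
    min_nv: int = 1

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        for name in ("coverage", "segments_per_chromosome", "muts_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def corrupt_purity(purity: float, phi: float) -> float:
    """Input purity corrupted by a known error ``phi``, clipped to (0, 1]."""
    out = purity + phi
    if out > 1.0 or out <= 0.0:
        warnings.warn(f"corrupted purity {out:.3f} clipped into (0, 1]")
    return float(np.clip(out, 0.01, 1.0))


def _chrom_lengths(build: str, n: int) -> pd.Series:
    tab = arm_table(build)
    tab = tab[~tab["chrom"].isin(["chrX", "chrY"])].head(n)
    return tab.set_index("chrom")["length"]


def simulate_tumor(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Generate (mutations, segments, true purity) for one synthetic tumor.

    Reproducible: the same config (including seed) yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    purity = config.purity
    states = list(config.karyotype_weights)
    conc = np.array([config.karyotype_weights[s] for s in states], dtype=float)
    probs = rng.dirichlet(conc)

    seg_rows = []
    mut_chunks = []
    floor_warned = False
    for chrom, length in _chrom_lengths(config.build, config.n_chromosomes).items():
        n_seg = max(1, rng.poisson(config.segments_per_chromosome))
        cuts = np.sort(rng.integers(1, length, size=n_seg - 1)) if n_seg > 1 else np.array([], dtype=int)
        bounds = np.concatenate(([1], cuts, [length]))
        for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
            lo = int(lo) + (1 if i > 0 else 0)  # closed intervals must not touch
            hi = int(hi)
            if hi <= lo:
                continue
            karyotype = states[rng.choice(len(states), p=probs)]
            n_a, n_b = (int(x) for x in karyotype.split(":"))
            seg_rows.append(
                {"chrom": chrom, "from": lo, "to": hi, "Major": n_a, "minor": n_b}
            )
            n_mut = rng.poisson((hi - lo) / 1e6 * config.muts_per_mb)
            if n_mut == 0:
                continue
            legal = pk.multiplicity_set(n_a, n_b)
            m = rng.choice(legal, size=n_mut)
            vaf_peak = np.array(
                [pk.expected_vaf(int(mi), n_a, n_b, purity) for mi in legal]
            )
            if not floor_warned and (vaf_peak < config.detection_floor).any():
                warnings.warn(
                    "expected peak below the detection floor "
                    f"({config.detection_floor}); QC will be unreliable"
                )
                floor_warned = True
            peak_of_m = dict(zip(legal, vaf_peak))
            p = np.array([peak_of_m[int(mi)] for mi in m])
            dp = np.maximum(rng.poisson(config.coverage, size=n_mut), 1)
            nv = rng.binomial(dp, p)
            pos = np.sort(rng.integers(lo, hi + 1, size=n_mut))
            ref = rng.choice(_BASES, size=n_mut)
            alt = rng.choice(_BASES, size=n_mut)
            detected = nv >= config.min_nv
            if not detected.any():
                continue
            pos, ref, alt = pos[detected], ref[detected], alt[detected]
            nv, dp = nv[detected], dp[detected]
            mut_chunks.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "NV": nv,
                        "DP": dp,
                    }
                )
            )

    if config.subclonal is not None:
        sub_m, sub_s = _simulate_subclonal(config, rng)
        seg_rows.append(sub_s)
        mut_chunks.append(sub_m)

    segments = pd.DataFrame(seg_rows)
    mutations = (
        pd.concat(mut_chunks, ignore_index=True)
        if mut_chunks
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "NV", "DP"])
    )
    return mutations, segments, purity


def _simulate_subclonal(config: SimConfig, rng) -> tuple[pd.DataFrame, dict]:
    """Two-subclone segment on a dedicated synthetic chromosome-like contig."""
    spec = dict(config.subclonal)
    state1, state2 = spec["state1"], spec["state2"]
    rho1 = float(spec["rho1"])
    n_mut = int(spec.get("n_mutations", 300))
    models = pk.enumerate_evolution_models(state1, state2)
    which = spec.get("model", 0)
    if isinstance(which, str):
        matches = [m for m in models if m.describe() == which or m.topology == which]
        if not matches:
            raise ValueError(f"no evolution model matching {which!r}")
        model = matches[0]
    else:
        model = models[which]
    expected = pk.subclonal_expected_peaks(model, rho1, 1 - rho1, config.purity)
    chrom = spec.get("chrom", "chrSUB")
    span = int(spec.get("span", 5e7))
    peak_idx = rng.integers(0, len(expected), size=n_mut)
    p = np.array([expected[i].vaf for i in peak_idx])
    dp = np.maximum(rng.poisson(config.coverage, size=n_mut), 1)
    nv = rng.binomial(dp, p)
    pos = np.sort(rng.integers(1, span + 1, size=n_mut))
    detected = nv >= config.min_nv
    pos, nv, dp = pos[detected], nv[detected], dp[detected]
    n_mut = int(detected.sum())
    n_a1, n_b1 = (int(x) for x in model.karyotype1.split(":"))
    n_a2, n_b2 = (int(x) for x in model.karyotype2.split(":"))
    seg = {
        "chrom": chrom,
        "from": 1,
        "to": span,
        "Major": n_a1,
        "minor": n_b1,
        "Major2": n_a2,
        "minor2": n_b2,
        "ccf1": rho1,
    }
    muts = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": rng.choice(_BASES, size=n_mut),
            "alt": rng.choice(_BASES, size=n_mut),
            "NV": nv,
            "DP": dp,
        }
    )
    return muts, seg
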