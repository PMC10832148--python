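"""Peak matching and purity/ploidy quality control.

The QC logic compares, for every pooled karyotype, the theoretical clonal
VAF peaks against peaks detected in the data.  The user states a purity
tolerance ``epsilon`` (in purity units); for each expected peak the
symmetric purity band of total width ``2 * epsilon`` on either side is
propagated to VAF space with the linearized peak equation, which for a
heterozygous diploid pool at purity 0.60 and ``epsilon = 0.025`` accepts
data peaks in [27.5%, 32.5%] VAF.  A further tolerance ``sigma`` widens the
data peak into an interval absorbing peak-detection noise; its default of
0.01 VAF is the image of a 2% purity slack under the diploid reference
state's conversion (dv/dpi = 1/2).  An expected peak is *matched* when the
two intervals overlap.

Signed peak offsets are converted back to purity units and combined into
the sample score ``lambda``, a mutation-weighted mean of per-peak purity
corrections: ``purity + lambda`` is the purity the data actually support.
The sample passes when the mutation mass carried by matched peaks is at
least the mass carried by unmatched ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import peaks as pk
from .detection import DataPeak, count_support, fit_binomial_mixture, kde_peaks
from .genome import classify_segments, map_mutations, validate_segments

__all__ = [
    "PeakMatch",
    "match_peak",
    "matching_halfwidth",
    "qc_karyotype",
    "qc_sample",
    "qc_complex",
    "qc_subclonal",
    "CopyNumberQC",
    "CopyNumberQCResults",
]


@dataclass
class PeakMatch:
    """Pairing of one expected peak with the best candidate data peak."""

    karyotype: str
    multiplicity: int
    expected_vaf: float
    data_vaf: float | None
    offset_vaf: float | None  # data - expected
    offset_purity: float | None  # offset propagated to purity units (signed)
    tolerance_vaf: float  # half-width of the expected-peak interval
    sigma_vaf: float  # half-width of the data-peak interval
    matched: bool
    support: int  # mutations in the 0.01 VAF bin of the matched peak


def matching_halfwidth(
    m: int, p: int, purity: float, epsilon: float, band_factor: float = 2.0
) -> float:
    """VAF half-width of the acceptance band for purity tolerance ``epsilon``.

    With the default ``band_factor`` of 2 the full symmetric purity band
    (total width ``2 * epsilon``) is propagated through the linearized peak
    equation, reproducing the published acceptance intervals (diploid pool
    at purity 0.60, ``epsilon = 0.025`` -> data peaks in [27.5%, 32.5%]).
    ``band_factor=1`` gives the strict single-sided propagation used for
    false-positive-rate calibration.
    """
    return pk.vaf_error_from_purity_error(m, p, purity, band_factor * epsilon)


def match_peak(
    expected: pk.ExpectedPeak,
    data_peaks: list[DataPeak],
    purity: float,
    epsilon: float,
    sigma: float = 0.01,
    strategy: str = "closest",
    vafs=None,
    band_factor: float = 2.0,
) -> PeakMatch:
    """Match one expected clonal peak against detected data peaks.

    ``strategy`` is ``"closest"`` (minimal geometric distance, default) or
    ``"right_only"`` (only candidates to the right of the expectation, used
    to hunt miscalled breakpoints).  ``epsilon`` is in purity units and is
    converted to VAF space with the peak's own multiplicity and ploidy;
    ``sigma`` is a raw VAF half-width around the detected peak, absorbing
    peak-*detection* noise, which lives in VAF space regardless of ploidy.
    """
    n_a, n_b = (int(x) for x in expected.karyotype.split(":"))
    p = n_a + n_b
    m = int(expected.multiplicity)
    tol = matching_halfwidth(m, p, purity, epsilon, band_factor)
    sig = float(sigma)

    candidates = list(data_peaks)
    if strategy == "right_only":
        candidates = [d for d in candidates if d.position > expected.vaf]
    elif strategy != "closest":
        raise ValueError(f"unknown matching strategy {strategy!r}")

    if not candidates:
        import warnings

        warnings.warn(f"no data peak available for {expected.karyotype} m={m}")
        support = count_support(vafs, expected.vaf) if vafs is not None else 0
        return PeakMatch(
            expected.karyotype, m, expected.vaf, None, None, None,
            tol, sig, False, support,
        )

    best = min(candidates, key=lambda d: abs(d.position - expected.vaf))
    offset = best.position - expected.vaf
    matched = abs(offset) <= tol + sig  # interval overlap
    offset_purity = pk.purity_error_from_vaf_error(expected.vaf, offset, m, p)
    support = (
        count_support(vafs, best.position) if vafs is not None else best.support
    )
    return PeakMatch(
        expected.karyotype, m, expected.vaf, best.position, offset,
        offset_purity, tol, sig, matched, support,
    )


def _effective_bandwidth(bandwidth: float, dp) -> float:
    """Floor the KDE bandwidth at one VAF lattice step (1 / median depth).

    Below that step the density estimate resolves individual read-count
    ratios (a comb of spikes at k/DP) instead of mutation clusters, which is
    a numerical degeneracy of low-coverage data, not signal.
    """
    med = float(np.median(np.asarray(dp, dtype=float)))
    return max(float(bandwidth), 1.0 / max(med, 1.0))


def qc_karyotype(
    nv,
    dp,
    karyotype: str,
    purity: float,
    epsilon: float,
    sigma: float = 0.01,
    strategy: str = "closest",
    method: str = "kde",
    bandwidth: float = 0.01,
    min_mutations: int = 20,
    seed: int = 0,
    band_factor: float = 2.0,
) -> dict:
    """QC one pooled simple clonal karyotype.

    Returns the per-multiplicity :class:`PeakMatch` list and the karyotype
    status, decided by the peak carrying the largest number of mutations
    (majority voting weighted by mutation counts).
    """
    nv = np.asarray(nv, dtype=float)
    dp = np.asarray(dp, dtype=float)
    if nv.size < min_mutations:
        return {"karyotype": karyotype, "status": "skipped", "n_mutations": int(nv.size), "matches": []}
    vafs = nv / dp
    if method == "mixture":
        fit = fit_binomial_mixture(nv, dp, seed=seed)
        data_peaks = fit.peaks(vafs)
    else:
        data_peaks = kde_peaks(vafs, bandwidth=_effective_bandwidth(bandwidth, dp))
    n_a, n_b = (int(x) for x in karyotype.split(":"))
    matches = [
        match_peak(e, data_peaks, purity, epsilon, sigma, strategy, vafs, band_factor)
        for e in pk.peaks_for_karyotype(n_a, n_b, purity)
    ]
    top = max(matches, key=lambda m: m.support)
    return {
        "karyotype": karyotype,
        "status": "pass" if top.matched else "fail",
        "n_mutations": int(nv.size),
        "matches": matches,
    }


def qc_sample(
    karyotype_results: list[dict],
    purity: float,
    epsilon: float,
    aggregate: str = "mutations",
    status_rule: str = "mass",
) -> dict:
    """Combine per-karyotype results into the sample score and status.

    Every QC-ed karyotype receives a weight proportional to its mutation
    count (normalized to sum to 1, halved per peak when the karyotype has
    multiple peaks).  The signed sample score ``lambda`` is the weighted sum
    of per-peak purity offsets; pass/fail compares the absolute
    mutation mass of matched vs unmatched peaks (``aggregate="mutations"``,
    default) or their absolute weighted-score mass (``aggregate="score"``).

    ``status_rule="score_threshold"`` replaces the mass comparison with the
    strict criterion ``|lambda| <= epsilon``: the sample passes only when
    the aggregate purity correction itself stays within the stated
    tolerance.  This is the rule used for false-positive-rate calibration,
    where any input purity error beyond ``epsilon`` must fail.
    """
    used = [r for r in karyotype_results if r["status"] in ("pass", "fail")]
    if not used:
        return {
            "status": "cannot_qc",
            "score": None,
            "suggested_purity": None,
            "purity": purity,
            "epsilon": epsilon,
        }
    total = sum(r["n_mutations"] for r in used)
    lam = 0.0
    pass_mass = fail_mass = 0.0
    for r in used:
        w_k = r["n_mutations"] / total
        n_peaks = max(len(r["matches"]), 1)
        for m in r["matches"]:
            w = w_k / n_peaks
            # peaks with no candidate at all: charge the tolerance itself
            dpi = m.offset_purity if m.offset_purity is not None else epsilon
            contrib = w * dpi
            lam += contrib
            if aggregate == "mutations":
                mass = w
            else:
                mass = abs(contrib)
            if m.matched:
                pass_mass += mass
            else:
                fail_mass += mass
    if status_rule == "score_threshold":
        status = "pass" if abs(lam) <= epsilon else "fail"
    elif status_rule == "mass":
        status = "pass" if pass_mass >= fail_mass else "fail"
    else:
        raise ValueError(f"unknown status rule {status_rule!r}")
    return {
        "status": status,
        "score": lam,
        "suggested_purity": float(np.clip(purity + lam, 0.01, 1.0)),
        "pass_mass": pass_mass,
        "fail_mass": fail_mass,
        "purity": purity,
        "epsilon": epsilon,
    }


def qc_complex(
    nv,
    dp,
    karyotype: str,
    purity: float,
    tolerance: float = 0.03,
    bandwidth: float = 0.01,
    min_mutations: int = 150,
) -> dict:
    """QC one pooled complex clonal karyotype.

    Peaks come from the KDE heuristic only; every multiplicity from 1 to the
    larger allele count is tested against the closest data peak with the raw
    ``tolerance`` in VAF space (no purity-unit conversion).  Contributes no
    sample-level score.
    """
    nv = np.asarray(nv, dtype=float)
    dp = np.asarray(dp, dtype=float)
    if nv.size < min_mutations:
        return {"karyotype": karyotype, "status": "skipped", "n_mutations": int(nv.size), "table": None, "fraction_matched": None}
    vafs = nv / dp
    data_peaks = kde_peaks(vafs, bandwidth=bandwidth)
    n_a, n_b = (int(x) for x in karyotype.split(":"))
    rows = []
    for e in pk.peaks_for_karyotype(n_a, n_b, purity):
        if data_peaks:
            best = min(data_peaks, key=lambda d: abs(d.position - e.vaf))
            offset = best.position - e.vaf
            matched = abs(offset) <= tolerance
            data_vaf = best.position
        else:
            data_vaf, offset, matched = None, None, False
        rows.append(
            {
                "multiplicity": int(e.multiplicity),
                "expected_vaf": e.vaf,
                "data_vaf": data_vaf,
                "offset": offset,
                "matched": matched,
            }
        )
    table = pd.DataFrame(rows)
    frac = float(table["matched"].mean()) if len(table) else 0.0
    return {
        "karyotype": karyotype,
        "status": "pass" if frac >= 0.5 else "fail",
        "n_mutations": int(nv.size),
        "table": table,
        "fraction_matched": frac,
    }


def qc_subclonal(
    nv,
    dp,
    state1: str,
    state2: str,
    rho1: float,
    purity: float,
    tolerance: float = 0.03,
    bandwidth: float = 0.01,
    min_mutations: int = 150,
    ancestor: str = "1:1",
) -> dict:
    """Select the evolution model best supported by a two-subclone segment.

    Every enumerated linear/branching model's expected peaks are matched
    (closest strategy, raw VAF tolerance) against KDE-detected peaks; the
    model with the highest fraction of matched peaks wins.  Models
    predicting identical peak sets are reported jointly as
    ``indistinguishable``; distinct models tied on matched fraction yield
    ``ambiguous``; a best fraction below 50% yields ``none``.
    """
    nv = np.asarray(nv, dtype=float)
    dp = np.asarray(dp, dtype=float)

    def _canonical(state: str) -> str:
        a, b = (int(x) for x in state.split(":"))
        return f"{max(a, b)}:{min(a, b)}"

    for state in (state1, state2):
        if _canonical(state) not in pk.SIMPLE_KARYOTYPES:
            return {"status": "skipped", "reason": f"unsupported state {state}"}
    if nv.size < min_mutations:
        return {"status": "skipped", "reason": "too few mutations", "n_mutations": int(nv.size)}
    vafs = nv / dp
    data_peaks = kde_peaks(vafs, bandwidth=bandwidth)
    rho2 = 1.0 - rho1
    models = pk.enumerate_evolution_models(state1, state2, ancestor)
    if not models:
        return {"status": "skipped", "reason": "no admissible evolution model"}
    rows = []
    for model in models:
        expected = pk.subclonal_expected_peaks(model, rho1, rho2, purity)
        n_match = 0
        for e in expected:
            if data_peaks and min(
                abs(d.position - e.vaf) for d in data_peaks
            ) <= tolerance:
                n_match += 1
        frac = n_match / len(expected) if expected else 0.0
        rows.append(
            {
                "model": model,
                "description": model.describe(),
                "topology": model.topology,
                "peaks": pk.peak_positions(expected, 6),
                "fraction_matched": frac,
            }
        )
    best_frac = max(r["fraction_matched"] for r in rows)
    winners = [r for r in rows if r["fraction_matched"] == best_frac]
    if best_frac < 0.5:
        status, chosen = "none", None
    elif len(winners) == 1:
        status, chosen = "pass", winners[0]
    else:
        peak_sets = {tuple(r["peaks"]) for r in winners}
        status = "indistinguishable" if len(peak_sets) == 1 else "ambiguous"
        chosen = winners[0] if len(peak_sets) == 1 else None
    return {
        "status": status,
        "best_model": chosen["description"] if chosen else None,
        "best_topology": chosen["topology"] if chosen else None,
        "fraction_matched": best_frac,
        "models": [
            {k: v for k, v in r.items() if k != "model"} for r in rows
        ],
        "winners": [r["description"] for r in winners],
        "n_mutations": int(nv.size),
    }


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class CopyNumberQC:
    """Quality-control model for allele-specific copy number calls.

    Built from somatic mutations with read counts, allele-specific segments
    and a tumor purity estimate; ``fit()`` runs peak detection, matching and
    scoring and returns a :class:`CopyNumberQCResults`.

    Parameters
    ----------
    mutations : DataFrame
        Columns ``chrom, pos, ref, alt, NV, DP``.
    segments : DataFrame
        Columns ``chrom, from, to, Major, minor`` (plus ``Major2, minor2,
        ccf1`` for two-subclone rows).  1-based closed coordinates.
    purity : float
        Tumor purity in (0, 1].
    build : str
        Genome build tag (GRCh38 or hg19), used for arm coordinates.
    """

    def __init__(
        self,
        mutations: pd.DataFrame,
        segments: pd.DataFrame,
        purity: float,
        build: str = "GRCh38",
        sample_id: str = "sample",
        snvs_only: bool = False,
    ):
        if not 0 < purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        self.segments = validate_segments(segments)
        self.segments["class"] = classify_segments(self.segments)
        self.mutations = map_mutations(mutations, segments)
        if snvs_only:
            self.mutations = self.mutations[~self.mutations["is_indel"]]
        self.purity = float(purity)
        self.build = build
        self.sample_id = sample_id

    @classmethod
    def from_files(
        cls, mutations_path, segments_path, purity, build="GRCh38", **kw
    ) -> "CopyNumberQC":
        from .io import read_mutations, read_segments

        return cls(
            read_mutations(mutations_path),
            read_segments(segments_path),
            purity,
            build,
            **kw,
        )

    def _pooled(self, per_chromosome: bool):
        """Yield (pool label, karyotype, class, nv, dp) for each mutation pool."""
        seg_class = self.segments.set_index("segment_id")["class"]
        muts = self.mutations.dropna(subset=["segment_id"]).copy()
        muts["class"] = muts["segment_id"].map(seg_class)
        clonal = muts[muts["class"].isin(["simple_clonal", "complex_clonal"])]
        keys = ["karyotype"] if not per_chromosome else ["chrom", "karyotype"]
        for key, grp in clonal.groupby(keys):
            if not isinstance(key, tuple):
                key = (key,)
            karyotype = key[-1]
            label = f"{key[0]}:{karyotype}" if per_chromosome else karyotype
            yield (
                label,
                karyotype,
                grp["class"].iloc[0],
                grp["NV"].to_numpy(),
                grp["DP"].to_numpy(),
            )

    def fit(
        self,
        epsilon: float = 0.03,
        sigma: float = 0.01,
        strategy: str = "closest",
        method: str = "kde",
        bandwidth: float = 0.01,
        min_mutations: int = 20,
        min_mutations_complex: int = 150,
        min_mutations_subclonal: int = 150,
        per_chromosome: bool = False,
        aggregate: str = "mutations",
        status_rule: str = "mass",
        band_factor: float = 2.0,
        seed: int = 0,
    ) -> "CopyNumberQCResults":
        simple_res, complex_res, subclonal_res = [], [], []
        for label, karyotype, klass, nv, dp in self._pooled(per_chromosome):
            if klass == "simple_clonal":
                r = qc_karyotype(
                    nv, dp, karyotype, self.purity, epsilon, sigma,
                    strategy, method, bandwidth, min_mutations, seed,
                    band_factor,
                )
                r["pool"] = label
                simple_res.append(r)
            else:
                r = qc_complex(
                    nv, dp, karyotype, self.purity, epsilon,
                    bandwidth, min_mutations_complex,
                )
                r["pool"] = label
                complex_res.append(r)

        # subclonal segments: per segment, never pooled
        sub_rows = self.segments[self.segments["class"] == "subclonal_simple"]
        for _, seg in sub_rows.iterrows():
            sel = self.mutations["segment_id"] == seg["segment_id"]
            r = qc_subclonal(
                self.mutations.loc[sel, "NV"],
                self.mutations.loc[sel, "DP"],
                f"{int(seg['Major'])}:{int(seg['minor'])}",
                f"{int(seg['Major2'])}:{int(seg['minor2'])}",
                float(seg["ccf1"]),
                self.purity,
                tolerance=epsilon,
                bandwidth=bandwidth,
                min_mutations=min_mutations_subclonal,
            )
            r["segment_id"] = seg["segment_id"]
            subclonal_res.append(r)

        sample = qc_sample(simple_res, self.purity, epsilon, aggregate, status_rule)
        config = {
            "epsilon": epsilon,
            "sigma": sigma,
            "strategy": strategy,
            "method": method,
            "bandwidth": bandwidth,
            "min_mutations": min_mutations,
            "min_mutations_complex": min_mutations_complex,
            "per_chromosome": per_chromosome,
            "aggregate": aggregate,
            "status_rule": status_rule,
            "band_factor": band_factor,
            "seed": seed,
            "purity": self.purity,
            "build": self.build,
        }
        return CopyNumberQCResults(
            self, sample, simple_res, complex_res, subclonal_res, config
        )


class CopyNumberQCResults:
    """Fitted QC results: per-peak matches, per-karyotype and sample status."""

    def __init__(self, model, sample, simple, complex_, subclonal, config):
        self.model = model
        self.sample = sample
        self.simple = simple
        self.complex = complex_
        self.subclonal = subclonal
        self.config = config

    # -- convenience accessors -------------------------------------------
    @property
    def status(self) -> str:
        return self.sample["status"]

    @property
    def score(self) -> float | None:
        """Sample score lambda, in purity units (signed)."""
        return self.sample["score"]

    @property
    def suggested_purity(self) -> float | None:
        return self.sample["suggested_purity"]

    def peak_table(self) -> pd.DataFrame:
        rows = []
        for r in self.simple:
            for m in r.get("matches", []):
                d = asdict(m)
                d["pool"] = r["pool"]
                rows.append(d)
        return pd.DataFrame(rows)

    def karyotype_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pool": r["pool"],
                    "karyotype": r["karyotype"],
                    "status": r["status"],
                    "n_mutations": r["n_mutations"],
                }
                for r in self.simple
            ]
        )

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items() if k != "matches"}
            return obj

        return {
            "schema_version": "1.0",
            "sample_id": self.model.sample_id,
            "config": self.config,
            "sample": {
                k: (round(v, 4) if isinstance(v, float) else v)
                for k, v in self.sample.items()
            },
            "simple_clonal": [
                {
                    "pool": r["pool"],
                    "karyotype": r["karyotype"],
                    "status": r["status"],
                    "n_mutations": r["n_mutations"],
                    "peaks": [asdict(m) for m in r.get("matches", [])],
                }
                for r in self.simple
            ],
            "complex_clonal": [
                {
                    "pool": r["pool"],
                    "karyotype": r["karyotype"],
                    "status": r["status"],
                    "n_mutations": r["n_mutations"],
                    "fraction_matched": r["fraction_matched"],
                    "table": r["table"].to_dict("records")
                    if r.get("table") is not None
                    else None,
                }
                for r in self.complex
            ],
            "subclonal": [clean(r) for r in self.subclonal],
        }

    def to_json(self, path=None, **kw) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    def summary(self) -> str:
        lines = [
            "Allele-specific copy number QC",
            "=" * 46,
            f"sample:            {self.model.sample_id}",
            f"input purity:      {self.model.purity:.3f}",
            f"epsilon (purity):  {self.config['epsilon']:.3f}",
            f"status:            {self.status.upper()}",
        ]
        if self.score is not None:
            lines.append(f"score lambda:      {self.score:+.4f} (purity units)")
            lines.append(f"suggested purity:  {self.suggested_purity:.3f}")
        lines.append("-" * 46)
        lines.append("karyotype pools (simple clonal):")
        for r in self.simple:
            lines.append(
                f"  {r['pool']:>12}  n={r['n_mutations']:>6}  {r['status']}"
            )
        for r in self.complex:
            frac = r["fraction_matched"]
            frac_s = f"{frac:.0%}" if frac is not None else "--"
            lines.append(
                f"  {r['pool']:>12}  n={r['n_mutations']:>6}  {r['status']}"
                f" (complex, {frac_s} peaks matched)"
            )
        for r in self.subclonal:
            lines.append(
                f"  {r.get('segment_id', '?'):>12}  subclonal: {r['status']}"
                + (f" [{r['best_model']}]" if r.get("best_model") else "")
            )
        return "\n".join(lines)

    def plot(self, karyotype: str, ax=None):
        """VAF histogram of one pool with expected peaks overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        for r in self.simple:
            if r["pool"] != karyotype or not r.get("matches"):
                continue
            sel = self.model.mutations["karyotype"] == r["karyotype"]
            vafs = self.model.mutations.loc[sel, "VAF"]
            ax.hist(vafs, bins=100, range=(0, 1), color="0.7")
            for m in r["matches"]:
                ax.axvline(m.expected_vaf, ls="--", color="C2" if m.matched else "C3")
            ax.set_xlabel("VAF")
            ax.set_title(f"{karyotype}: {r['status']}")
        return ax
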