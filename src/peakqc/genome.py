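"""Segments, mutations and their genomic bookkeeping.

Tables are plain :class:`pandas.DataFrame` objects using the caller TSV
dialects:

* mutations: columns ``chrom, pos, ref, alt, NV, DP`` (``NV`` = reads
  supporting the variant, ``DP`` = total depth); ``VAF`` is always recomputed
  as ``NV/DP``.  Positions are 1-based.
* segments: columns ``chrom, from, to, Major, minor`` and, for two-subclone
  rows, ``Major2, minor2, ccf1`` (proportion of the first clone).  Spans are
  1-based and fully closed: a mutation at ``pos == to`` belongs to the
  segment.

Karyotypes are classified into *simple clonal* (1:0, 1:1, 2:0, 2:1, 2:2 —
one evolutionary step from diploid), *complex clonal* (everything else
clonal), *subclonal simple* (two clones, both simple) and *unsupported*.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peaks import SIMPLE_KARYOTYPES

__all__ = [
    "KaryotypeClass",
    "validate_mutations",
    "validate_segments",
    "classify_segment",
    "map_mutations",
    "smooth_segments",
    "decompose_fractional_cn",
    "arm_table",
    "assign_arms",
]

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "NV", "DP"]
SEGMENT_COLUMNS = ["chrom", "from", "to", "Major", "minor"]


@dataclass(frozen=True)
class KaryotypeClass:
    """Classification of one segment row."""

    label: str  # simple_clonal | complex_clonal | subclonal_simple | unsupported
    karyotype: str  # "nA:nB" or "nA1:nB1-nA2:nB2"


def validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a mutation table; recompute VAF from counts."""
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table misses columns {missing}")
    df = df.copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["NV"] = df["NV"].astype(np.int64)
    df["DP"] = df["DP"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("mutation positions must be >= 1")
    if (df["DP"] < 1).any():
        raise ValueError("DP must be >= 1")
    bad = df["NV"] > df["DP"]
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"NV > DP in rows {rows}")
    if (df["NV"] < 0).any():
        raise ValueError("NV must be >= 0")
    df["VAF"] = df["NV"] / df["DP"]
    df["is_indel"] = (df["ref"].astype(str).str.len() != 1) | (
        df["alt"].astype(str).str.len() != 1
    )
    return df


def _check_allele_pair(major, minor, where: str) -> None:
    arr = np.asarray([major, minor], dtype=float)
    if np.any(arr != np.floor(arr)) or np.any(arr < 0):
        raise ValueError(f"allele counts must be non-negative integers ({where})")
    if np.any(np.asarray(major) < np.asarray(minor)):
        raise ValueError(f"Major must be >= minor ({where})")


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a segment table; adds ``segment_id`` and ``karyotype``."""
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table misses columns {missing}")
    df = df.copy().reset_index(drop=True)
    for col in ("from", "to"):
        df[col] = df[col].astype(np.int64)
    if (df["from"] > df["to"]).any():
        raise ValueError("segment 'from' must be <= 'to'")
    _check_allele_pair(df["Major"].to_numpy(), df["minor"].to_numpy(), "clonal")
    df["Major"] = df["Major"].astype(np.int64)
    df["minor"] = df["minor"].astype(np.int64)
    subclonal = df.get("Major2")
    if subclonal is not None:
        has2 = df["Major2"].notna()
        if has2.any():
            sub = df.loc[has2]
            _check_allele_pair(
                sub["Major2"].to_numpy(), sub["minor2"].to_numpy(), "subclonal"
            )
            ccf1 = sub["ccf1"].astype(float)
            if ((ccf1 <= 0) | (ccf1 >= 1)).any():
                raise ValueError("ccf1 must be in (0, 1) for subclonal rows")
    df["segment_id"] = [
        f"{c}:{a}-{b}" for c, a, b in zip(df["chrom"], df["from"], df["to"])
    ]
    df["karyotype"] = [
        f"{M}:{m}" for M, m in zip(df["Major"], df["minor"])
    ]
    # reject overlapping segments per chromosome (closed intervals)
    for chrom, grp in df.groupby("chrom"):
        g = grp.sort_values("from")
        overlap = g["from"].to_numpy()[1:] <= g["to"].to_numpy()[:-1]
        if overlap.any():
            raise ValueError(f"overlapping segments on {chrom}")
    return df


def classify_segment(
    major: int,
    minor: int,
    major2: int | None = None,
    minor2: int | None = None,
    ccf1: float | None = None,
) -> KaryotypeClass:
    """Classify one segment into the karyotype taxonomy."""
    _check_allele_pair(major, minor, "clonal")
    k1 = f"{int(major)}:{int(minor)}"
    if major2 is None or (isinstance(major2, float) and np.isnan(major2)):
        label = "simple_clonal" if k1 in SIMPLE_KARYOTYPES else "complex_clonal"
        return KaryotypeClass(label, k1)
    _check_allele_pair(major2, minor2, "subclonal")
    if ccf1 is not None and not (0 < ccf1 < 1):
        raise ValueError("ccf1 must be in (0, 1)")
    k2 = f"{int(major2)}:{int(minor2)}"
    both_simple = k1 in SIMPLE_KARYOTYPES and k2 in SIMPLE_KARYOTYPES
    label = "subclonal_simple" if both_simple else "unsupported"
    return KaryotypeClass(label, f"{k1}-{k2}")


def classify_segments(segments: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`classify_segment` label per row."""
    labels = []
    for _, row in segments.iterrows():
        labels.append(
            classify_segment(
                row["Major"],
                row["minor"],
                row.get("Major2"),
                row.get("minor2"),
                row.get("ccf1"),
            ).label
        )
    return pd.Series(labels, index=segments.index, name="class")


def map_mutations(mutations: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Assign each mutation to the segment whose closed span contains it.

    Adds ``segment_id`` (NA when the mutation lies outside every segment) and
    ``karyotype``.  Overlapping segments are rejected by
    :func:`validate_segments` upstream, so containment is unique.
    """
    mutations = validate_mutations(mutations)
    segments = validate_segments(segments)
    seg_id = pd.Series(pd.NA, index=mutations.index, dtype="object")
    karyo = pd.Series(pd.NA, index=mutations.index, dtype="object")
    for chrom, seg_grp in segments.groupby("chrom"):
        sel = mutations["chrom"] == chrom
        if not sel.any():
            continue
        pos = mutations.loc[sel, "pos"].to_numpy()
        starts = seg_grp["from"].to_numpy()
        ends = seg_grp["to"].to_numpy()
        ids = seg_grp["segment_id"].to_numpy()
        kars = seg_grp["karyotype"].to_numpy()
        order = np.argsort(starts)
        starts, ends, ids, kars = starts[order], ends[order], ids[order], kars[order]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, None)])
        assigned = np.where(ok, ids[np.clip(idx, 0, None)], None)
        assigned_k = np.where(ok, kars[np.clip(idx, 0, None)], None)
        seg_id.loc[sel] = assigned
        karyo.loc[sel] = assigned_k
    out = mutations.copy()
    out["segment_id"] = seg_id
    out["karyotype"] = karyo
    return out


def smooth_segments(segments: pd.DataFrame, max_gap: float = 1e6) -> pd.DataFrame:
    """Merge adjacent clonal segments with identical allele-specific state.

    Two same-chromosome segments are fused when their allele counts are equal
    and the gap between them is at most ``max_gap`` bases (default one
    megabase).  The operation is idempotent and never changes which bases are
    covered by which allele state.
    """
    if "Major2" in segments.columns and segments["Major2"].notna().any():
        raise ValueError("smoothing applies to clonal segments only")
    segments = validate_segments(segments)
    pieces = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        g = grp.sort_values("from").reset_index(drop=True)
        cur = g.iloc[0].copy()
        for _, row in g.iloc[1:].iterrows():
            same_state = (row["Major"] == cur["Major"]) and (
                row["minor"] == cur["minor"]
            )
            gap = row["from"] - cur["to"] - 1
            if same_state and gap <= max_gap:
                cur["to"] = row["to"]
            else:
                pieces.append(cur)
                cur = row.copy()
        pieces.append(cur)
    out = pd.DataFrame(pieces).reset_index(drop=True)
    out = out[[c for c in segments.columns if c not in ("segment_id", "karyotype")]]
    return validate_segments(out)


def decompose_fractional_cn(
    mcnf: float,
    cnf: float,
    maf: float,
    mcn1: int,
    cn1: int,
    purity: float,
    grid_max: int = 10,
    err_tol: float = 0.1,
) -> dict | None:
    """Two-subclone integer decomposition of fractional caller output.

    Some callers report fractional minor (``mcnf``) and total (``cnf``) copy
    numbers plus a minor allele frequency (``maf``) for putatively
    heterogeneous segments.  Assuming two subclones, with the caller's
    integer solution as subclone 1 (``mcn1``/``cn1``), each candidate integer
    minor copy number ``mcn2 != mcn1`` on a grid implies::

        rho1 = (mcnf - mcn1) / (mcn2 - mcn1)
        cn2  = (cnf - (1 - rho1) * cn1) / rho1

    Candidates are kept when ``rho1`` is a proportion, the implied total is
    at least twice the minor (``cn2 >= 2 * mcn2``), and the predicted minor
    allele frequency (mixing the two clones at purity ``purity`` with a 0.5
    normal contamination term) reproduces ``maf`` within ``err_tol``.  The
    surviving candidate with the smallest MAF error is returned, or ``None``.
    """
    if cn1 == 0:
        raise ValueError("CN1 must be positive")
    if grid_max < 1:
        raise ValueError("degenerate candidate grid")
    best = None
    for mcn2 in range(0, grid_max + 1):
        if mcn2 == mcn1:
            continue  # division by zero: clonal in the minor allele
        rho1 = (mcnf - mcn1) / (mcn2 - mcn1)
        if not (0 < rho1 < 1):
            continue
        cn2 = (cnf - (1 - rho1) * cn1) / rho1
        if cn2 < 2 * mcn2 or cn2 <= 0:
            continue
        eta1 = mcn1 / cn1
        eta2 = mcn2 / cn2
        maf_err = abs(
            maf - purity * (rho1 * eta1 + (1 - rho1) * eta2) - (1 - purity) * 0.5
        )
        if maf_err >= err_tol:
            continue
        if best is None or maf_err < best["maf_err"]:
            best = {
                "mCN2": mcn2,
                "CN2": cn2,
                "rho1": rho1,
                "rho2": 1 - rho1,
                "maf_err": maf_err,
            }
    return best


# ---------------------------------------------------------------------------
# Chromosome arms
# ---------------------------------------------------------------------------


def arm_table(build: str = "GRCh38") -> pd.DataFrame:
    """Bundled chromosome length / centromere table for a genome build.

    Columns: ``chrom, length, centromere`` (approximate centromere
    midpoints).  Supported builds: GRCh38, hg19.
    """
    build = build.lower().replace("grch38", "grch38").replace("hg38", "grch38")
    if build not in ("grch38", "hg19"):
        raise ValueError(f"unsupported genome build {build!r}")
    ref = importlib.resources.files("peakqc.data") / f"arms_{build}.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c if c.startswith("chr") else f"chr{c}"


def assign_arms(segments: pd.DataFrame, build: str = "GRCh38") -> pd.DataFrame:
    """Assign each segment to a chromosome arm, splitting at the centromere.

    A segment spanning the centromere is split into its p- and q-arm parts
    before any arm-level statistics are computed.
    """
    segments = validate_segments(segments)
    arms = arm_table(build).set_index("chrom")
    rows = []
    for _, row in segments.iterrows():
        chrom = _norm_chrom(row["chrom"])
        if chrom not in arms.index:
            continue
        cen = int(arms.loc[chrom, "centromere"])
        start, end = int(row["from"]), int(row["to"])
        short = chrom.removeprefix("chr")
        if end <= cen:
            parts = [(f"{short}p", start, end)]
        elif start > cen:
            parts = [(f"{short}q", start, end)]
        else:
            parts = [(f"{short}p", start, cen), (f"{short}q", cen + 1, end)]
        for arm, a, b in parts:
            r = row.copy()
            r["from"], r["to"], r["arm"] = a, b, arm
            rows.append(r)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out


def arm_lengths(build: str = "GRCh38") -> pd.Series:
    """Length of every chromosome arm in bases, indexed by arm name."""
    arms = arm_table(build)
    vals = {}
    for _, row in arms.iterrows():
        short = str(row["chrom"]).removeprefix("chr")
        vals[f"{short}p"] = int(row["centromere"])
        vals[f"{short}q"] = int(row["length"]) - int(row["centromere"])
    return pd.Series(vals, name="arm_length")
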