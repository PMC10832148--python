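"""Readers and writers for the caller-facing formats.

Mutations come either from a VCF (``AD`` or ``NV``/``DP`` FORMAT fields;
multi-allelic records are split per alt allele) or from a TSV with header
``chrom, pos, ref, alt, NV, DP``.  Segments come from a TSV with header
``chrom, from, to, Major, minor`` (optionally ``Major2, minor2, ccf1``).
All coordinates are 1-based and fully closed.  The VAF is always recomputed
from NV/DP on load — read counts are the source of truth even when a VAF
column is present.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import validate_mutations, validate_segments

__all__ = ["read_mutations", "read_segments", "write_report", "write_tumor"]


def _read_vcf(path: str) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        sample = samples[0]
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            call = rec.samples[sample]
            ad = call.get("AD")
            nv_field = call.get("NV")
            dp_field = call.get("DP")
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if ad is not None and ad[0] is not None:
                    nv = ad[i + 1]
                    dp = dp_field if dp_field is not None else sum(
                        a for a in ad if a is not None
                    )
                elif nv_field is not None and dp_field is not None:
                    nv = nv_field[i] if isinstance(nv_field, tuple) else nv_field
                    dp = dp_field
                else:
                    raise ValueError(
                        f"{path}: neither AD nor NV+DP FORMAT fields present "
                        f"at {rec.chrom}:{rec.pos}"
                    )
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "NV": int(nv),
                        "DP": int(dp),
                    }
                )
    return pd.DataFrame(rows)


def _read_mutation_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "pos", "ref", "alt", "NV", "DP") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df["NV"] > df["DP"]
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header and 1-basing
        raise ValueError(f"{path}: NV > DP on lines {lines}")
    return df


def read_mutations(path, fmt: str | None = None) -> pd.DataFrame:
    """Load and validate mutations from VCF or TSV (auto-detected)."""
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    df = _read_vcf(path) if fmt == "vcf" else _read_mutation_tsv(path)
    if df.empty:
        raise ValueError(f"{path}: no usable mutation records")
    return validate_mutations(df)


def read_segments(path) -> pd.DataFrame:
    """Load and validate an allele-specific segment table."""
    df = pd.read_csv(path, sep="\t")
    return validate_segments(df)


def write_tumor(mutations: pd.DataFrame, segments: pd.DataFrame, outdir) -> dict:
    """Write a simulated tumor in the same dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mut_path = outdir / "mutations.tsv"
    seg_path = outdir / "segments.tsv"
    cols = ["chrom", "pos", "ref", "alt", "NV", "DP"]
    mutations[cols].to_csv(mut_path, sep="\t", index=False)
    seg_cols = [
        c
        for c in ("chrom", "from", "to", "Major", "minor", "Major2", "minor2", "ccf1")
        if c in segments.columns
    ]
    segments[seg_cols].to_csv(seg_path, sep="\t", index=False)
    return {"mutations": str(mut_path), "segments": str(seg_path)}


_EXIT_CODE = {"pass": 0, "cannot_qc": 2, "fail": 3}


def write_report(
    results,
    outdir,
    ccf_tables: dict | None = None,
    fragmentation: pd.DataFrame | None = None,
) -> int:
    """Write the JSON QC report (and optional TSV side tables).

    Returns the pipeline exit code: 0 pass, 3 fail, 2 cannot-QC.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_json(outdir / "report.json")
    if ccf_tables:
        for karyotype, table in ccf_tables.items():
            safe = karyotype.replace(":", "_")
            table.to_csv(outdir / f"ccf_{safe}.tsv", sep="\t", index=False)
    if fragmentation is not None:
        fragmentation.to_csv(outdir / "fragmentation.tsv", sep="\t", index=False)
    return _EXIT_CODE.get(results.status, 3)
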