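"""Standard-format I/O: FASTA, BED, TSV, VCF.

Coordinate conventions are centralized here: variants are 1-based (VCF
style) everywhere inside the package; interval files on disk are BED
0-based half-open. :func:`bed_to_intervals` / :func:`intervals_to_bed`
perform the conversion at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Fasta:
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk; 1-based inclusive in memory)

def read_bed(path) -> pd.DataFrame:
    """Read a BED3(+) file into a 1-based inclusive interval table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"{path}: empty/negative interval at line {bad[0] + 1}")
    out = df[["chrom", "start", "end"]].copy()
    if df.shape[1] > 3:
        out["value"] = df[3]
    out["start"] = out["start"] + 1  # to 1-based inclusive
    return out


def write_bed(path, df: pd.DataFrame) -> None:
    """Write a 1-based inclusive interval table as BED (0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"] - 1
    cols = ["chrom", "start", "end"] + [c for c in out.columns
                                        if c not in ("chrom", "start", "end")]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TSV tables with header contracts

def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF 4.2 (via pysam/htslib)

_VCF_INFO = [
    ("STRANDEDNESS", "1", "String", "ds (double-stranded) or ss (single-stranded)"),
    ("STRAND", "1", "String", "variant strand for ss calls (+/-)"),
    ("CELL", "1", "String", "cell identifier"),
    ("VAF", "1", "Float", "single-molecule variant allele fraction"),
    ("CLASS", "1", "String", "variant class (SNV/INS/DEL)"),
]


def _vcf_header(contigs: dict[str, int], filters: tuple[str, ...]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for fid, number, vtype, desc in _VCF_INFO:
        header.info.add(fid, number, vtype, desc)
    for f in filters:
        if f != "PASS":
            header.filters.add(f, None, None, f"failed {f} filter")
    return header


def write_calls_vcf(path, calls: pd.DataFrame, contigs: dict[str, int]) -> None:
    """Write a call table (1-based ``pos``) as uncompressed VCF 4.2.

    Filter flags (semicolon-joined in the ``filters`` column, empty = PASS)
    are carried in the FILTER column; strandedness in INFO.
    """
    flt = set()
    fcol = calls.get("filters")
    if fcol is not None:
        for v in fcol.fillna(""):
            flt.update(f for f in str(v).split(";") if f)
    header = _vcf_header(contigs, tuple(sorted(flt)))
    calls = calls.sort_values(["chrom", "pos"], kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in calls.itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            fl = getattr(row, "filters", "") or ""
            if fl:
                for f in str(fl).split(";"):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            for key, attr in (("STRANDEDNESS", "strandedness"), ("STRAND", "strand"),
                              ("CELL", "cell_id"), ("CLASS", "var_class")):
                val = getattr(row, attr, None)
                if val is not None and not pd.isna(val):
                    rec.info[key] = str(val)
            vaf = getattr(row, "vaf", None)
            if vaf is not None and not pd.isna(vaf):
                rec.info["VAF"] = float(vaf)
            vf.write(rec)


def read_calls_vcf(path) -> pd.DataFrame:
    """Read a VCF of calls back into the package's 1-based table form."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                raise ValueError(f"{path}: record without ALT at "
                                 f"{rec.contig}:{rec.pos}")
            filters = ";".join(f for f in rec.filter.keys() if f != "PASS")
            rows.append({
                "chrom": rec.contig,
                "pos": rec.pos,  # pysam .pos is 1-based
                "ref": rec.ref,
                "alt": rec.alts[0],
                "filters": filters,
                "strandedness": rec.info.get("STRANDEDNESS"),
                "strand": rec.info.get("STRAND"),
                "cell_id": rec.info.get("CELL"),
                "var_class": rec.info.get("CLASS"),
                "vaf": rec.info.get("VAF"),
            })
    return pd.DataFrame(rows)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
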