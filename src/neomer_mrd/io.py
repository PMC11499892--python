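"""Readers for the package's input formats (FASTA, FASTQ, variant tables,
sample sheets).  Variant positions are 1-based in files (VCF convention)
and converted to 0-based half-open coordinates only inside algorithms.
"""

from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from neomer_mrd.errors import FastqParseError

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """All records of a FASTA file as {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase) from a FASTQ(.gz) file.

    Malformed records raise :class:`FastqParseError` naming the record
    number (1-based).
    """
    path = Path(path)
    n = 0
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                n += 1
                yield str(rec.seq).upper()
        except ValueError as exc:
            raise FastqParseError(
                f"{path}: malformed FASTQ at record {n + 1}: {exc}"
            ) from exc


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a variant table from TSV or VCF.

    Returns columns chrom, pos (1-based int), ref, alt plus any extra
    columns present (``count`` for recurrent lists, ``af`` for
    population lists; a VCF's INFO AF is extracted when present).
    Multi-allelic and non-SNV (indel) records are skipped with a
    warning: the catalog is defined over single-nucleotide variants.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz")):
        df = _read_vcf(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant table missing columns {missing}")
    bad = df[
        (df["ref"].str.len() != 1)
        | (df["alt"].str.len() != 1)
        | ~df["ref"].str.upper().isin(list("ACGT"))
        | ~df["alt"].str.upper().isin(list("ACGT"))
    ]
    if len(bad):
        warnings.warn(
            f"{path}: skipping {len(bad)} non-SNV/multi-allelic record(s)",
            stacklevel=2,
        )
        df = df.drop(bad.index)
    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    return df


def _read_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                warnings.warn(
                    f"{path}: skipping multi-allelic record at {rec.chrom}:{rec.pos}",
                    stacklevel=2,
                )
                continue
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,  # pysam exposes the 1-based VCF POS here
                "ref": rec.ref,
                "alt": alts[0],
            }
            af = rec.info.get("AF") if "AF" in rec.info else None
            if af is not None:
                row["af"] = float(af[0] if isinstance(af, tuple) else af)
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).dropna(
        axis=1, how="all"
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample/patient ids, time point, FASTQ path, PFS
    outcome, and binary labels (stored as 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    required = {"sample_id", "patient_id", "timepoint", "pfs_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    for col in ("event", "true_mrd", "ctdna_mutation_positive"):
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    if (df["pfs_time"] <= 0).any():
        raise ValueError(f"{path}: PFS times must be > 0")
    dup = df.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        raise ValueError(
            f"{path}: more than one sample per patient/time point: "
            f"{df.loc[dup, 'sample_id'].tolist()}"
        )
    return df
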