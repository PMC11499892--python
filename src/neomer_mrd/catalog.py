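"""Neomer catalog construction.

A neomer is a k-mer (default 16 bp) that spans a recurrent SNV's
alternate allele and is absent from the reference genome on either
strand.  The catalog is built in three stages: enumerate all k windows
covering each SNV with the alternate base substituted, discard any
window present in the reference (forward or reverse complement), then
discard windows attributable to population variants.  Surviving
sequences are stored in canonical form (lexicographic min of sequence
and reverse complement), deduplicated across source SNVs, and ordered
lexicographically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from neomer_mrd.dna import canonical, is_acgt, reverse_complement
from neomer_mrd.errors import DataIntegrityError


@dataclass(frozen=True)
class SourceVariant:
    """Provenance of one candidate: which SNV and window produced it."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    offset: int  # 0-based position of the alt base within the k-mer
    strand: str  # '+' if the canonical sequence is the genomic orientation


@dataclass
class Neomer:
    sequence: str  # canonical form
    source_variants: list[SourceVariant] = field(default_factory=list)


@dataclass
class NeomerCatalog:
    k: int
    neomers: list[Neomer]
    provenance: dict

    @property
    def sequences(self) -> list[str]:
        return [n.sequence for n in self.neomers]

    def __len__(self) -> int:
        return len(self.neomers)


def _as_reference_dict(reference: str | dict[str, str]) -> dict[str, str]:
    if isinstance(reference, str):
        return {"chr1": reference}
    return reference


def build_reference_index(reference: str | dict[str, str], k: int) -> frozenset[str]:
    """Exact forward-strand k-mer membership set over all contigs.

    Windows containing non-ACGT characters (e.g. N) are never members.
    A contig shorter than k contributes nothing.
    """
    kmers: set[str] = set()
    for seq in _as_reference_dict(reference).values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if is_acgt(w):
                kmers.add(w)
    return frozenset(kmers)


def enumerate_candidates(
    variant, reference: str | dict[str, str], k: int
) -> list[tuple[str, int]]:
    """All k-length windows covering the variant with the alt substituted.

    ``variant`` is any mapping with chrom/pos/ref/alt (1-based pos).
    Returns (candidate sequence, offset of the alt base) pairs — up to k
    of them, fewer near contig ends.  Raises
    :class:`DataIntegrityError` when the variant's ref base does not
    match the reference.
    """
    ref_dict = _as_reference_dict(reference)
    chrom, pos, ref_base, alt = (
        variant["chrom"],
        int(variant["pos"]),
        variant["ref"].upper(),
        variant["alt"].upper(),
    )
    if chrom not in ref_dict:
        raise DataIntegrityError(f"variant {chrom}:{pos}: unknown contig {chrom!r}")
    seq = ref_dict[chrom].upper()
    p = pos - 1  # to 0-based
    if not 0 <= p < len(seq):
        raise DataIntegrityError(
            f"variant {chrom}:{pos}{ref_base}>{alt}: position outside contig "
            f"(length {len(seq)})"
        )
    if seq[p] != ref_base:
        raise DataIntegrityError(
            f"variant {chrom}:{pos}{ref_base}>{alt}: reference has {seq[p]!r} "
            f"at that position"
        )
    out: list[tuple[str, int]] = []
    for start in range(max(0, p - k + 1), min(len(seq) - k, p) + 1):
        window = seq[start : start + k]
        offset = p - start
        cand = window[:offset] + alt + window[offset + 1 :]
        if is_acgt(cand):
            out.append((cand, offset))
    return out


def filter_reference_absent(
    candidates: list[tuple[str, int]], index: frozenset[str]
) -> list[tuple[str, int]]:
    """Keep candidates absent from the reference on both strands."""
    return [
        (seq, off)
        for seq, off in candidates
        if seq not in index and reverse_complement(seq) not in index
    ]


def population_kmers(
    population_variants: pd.DataFrame,
    reference: str | dict[str, str],
    k: int,
    af_threshold: float = 0.0,
) -> frozenset[str]:
    """Canonical k-mers generatable from population variants at or above
    the allele-frequency threshold (all listed variants when the table
    has no ``af`` column or the threshold is 0)."""
    kmers: set[str] = set()
    for _, row in population_variants.iterrows():
        if "af" in population_variants.columns and row["af"] < af_threshold:
            continue
        for seq, _ in enumerate_candidates(row, reference, k):
            kmers.add(canonical(seq))
    return frozenset(kmers)


def filter_population(
    candidates: list[tuple[str, int]],
    population_variants: pd.DataFrame,
    reference: str | dict[str, str],
    k: int,
    af_threshold: float = 0.0,
) -> list[tuple[str, int]]:
    """Remove candidates identical (either strand) to a population-variant k-mer."""
    pop = population_kmers(population_variants, reference, k, af_threshold)
    return [(seq, off) for seq, off in candidates if canonical(seq) not in pop]


def build_catalog(
    recurrent_snvs: pd.DataFrame,
    population_variants: pd.DataFrame,
    reference: str | dict[str, str],
    k: int = 16,
    af_threshold: float = 0.0,
) -> NeomerCatalog:
    """Full catalog pipeline: enumerate, reference-absence filter,
    population filter, canonical dedup, lexicographic order.

    Provenance records the candidate count before and after
    deduplication and after each filter (non-increasing).
    """
    index = build_reference_index(reference, k)
    pop = population_kmers(population_variants, reference, k, af_threshold)

    per_variant: list[tuple[dict, list[tuple[str, int]]]] = []
    n_candidates_raw = 0
    for _, row in recurrent_snvs.iterrows():
        cands = enumerate_candidates(row, reference, k)
        n_candidates_raw += len(cands)
        per_variant.append((row.to_dict(), cands))

    unique_candidates = {
        canonical(seq) for _, cands in per_variant for seq, _ in cands
    }

    merged: dict[str, Neomer] = {}
    n_absent_raw = 0
    for var, cands in per_variant:
        absent = filter_reference_absent(cands, index)
        n_absent_raw += len(absent)
        for seq, off in absent:
            canon = canonical(seq)
            if canon in pop:
                continue
            strand = "+" if canon == seq else "-"
            src = SourceVariant(
                chrom=str(var["chrom"]),
                pos=int(var["pos"]),
                ref=str(var["ref"]).upper(),
                alt=str(var["alt"]).upper(),
                offset=off,
                strand=strand,
            )
            if canon not in merged:
                merged[canon] = Neomer(sequence=canon)
            if src not in merged[canon].source_variants:
                merged[canon].source_variants.append(src)

    unique_absent = {
        canonical(seq)
        for _, cands in per_variant
        for seq, _ in filter_reference_absent(cands, index)
    }
    neomers = [merged[s] for s in sorted(merged)]
    provenance = {
        "k": k,
        "af_threshold": af_threshold,
        "recurrent_snvs": int(len(recurrent_snvs)),
        "candidates": int(n_candidates_raw),
        "candidates_unique": int(len(unique_candidates)),
        "reference_absent": int(n_absent_raw),
        "reference_absent_unique": int(len(unique_absent)),
        "final": int(len(neomers)),
    }
    return NeomerCatalog(k=k, neomers=neomers, provenance=provenance)


def write_catalog(catalog: NeomerCatalog, path: str | Path) -> None:
    """Catalog TSV (one row per neomer x source variant) plus a JSON
    provenance sidecar at ``<path>.provenance.json``."""
    path = Path(path)
    rows = []
    for n in catalog.neomers:
        for s in n.source_variants:
            rows.append(
                {
                    "sequence": n.sequence,
                    "orientation": s.strand,
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "offset": s.offset,
                }
            )
    pd.DataFrame(
        rows,
        columns=["sequence", "orientation", "chrom", "pos", "ref", "alt", "offset"],
    ).to_csv(path, sep="\t", index=False)
    with open(path.with_name(path.name + ".provenance.json"), "w") as fh:
        json.dump(catalog.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_catalog(path: str | Path) -> NeomerCatalog:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"sequence": str, "chrom": str, "ref": str, "alt": str}
    )
    sidecar = path.with_name(path.name + ".provenance.json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    merged: dict[str, Neomer] = {}
    for _, row in df.iterrows():
        seq = row["sequence"]
        if seq not in merged:
            merged[seq] = Neomer(sequence=seq)
        merged[seq].source_variants.append(
            SourceVariant(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                offset=int(row["offset"]),
                strand=row["orientation"],
            )
        )
    k = provenance.get("k") or (len(df["sequence"].iloc[0]) if len(df) else 16)
    neomers = [merged[s] for s in sorted(merged)]
    return NeomerCatalog(k=int(k), neomers=neomers, provenance=provenance)
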