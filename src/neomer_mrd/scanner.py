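"""Exact-match scanning of FASTQ reads against a neomer catalog.

Matching is read-level and strand-aware: a catalog entry matches a read
when either orientation of the neomer occurs as an exact substring of
the read (equivalently, the canonical sequence occurs in the read or
its reverse complement).  A read counts once toward the
neomer-detecting-read total regardless of how many catalog entries or
occurrences it contains; per-neomer counts record, for each catalog
entry, the number of reads containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from neomer_mrd.catalog import NeomerCatalog
from neomer_mrd.dna import reverse_complement
from neomer_mrd.io import iter_fastq


class CatalogMatcher:
    """Pre-built lookup from k-mer (either orientation) to catalog indices."""

    def __init__(self, catalog: NeomerCatalog):
        self.k = catalog.k
        self.size = len(catalog)
        self._lookup: dict[str, tuple[int, ...]] = {}
        tmp: dict[str, set[int]] = {}
        for i, n in enumerate(catalog.neomers):
            for seq in (n.sequence, reverse_complement(n.sequence)):
                tmp.setdefault(seq, set()).add(i)
        self._lookup = {s: tuple(sorted(ix)) for s, ix in tmp.items()}

    def scan(self, read: str) -> set[int]:
        """Indices of catalog entries occurring exactly in the read (either
        strand).  Reads shorter than k match nothing; windows containing
        non-ACGT characters never match."""
        k = self.k
        read = read.upper()
        hits: set[int] = set()
        lookup = self._lookup
        for i in range(len(read) - k + 1):
            ix = lookup.get(read[i : i + k])
            if ix:
                hits.update(ix)
        return hits


def scan_read(read: str, catalog: NeomerCatalog | CatalogMatcher) -> set[int]:
    """One-shot scan of a single read (builds the matcher if needed)."""
    matcher = catalog if isinstance(catalog, CatalogMatcher) else CatalogMatcher(catalog)
    return matcher.scan(read)


@dataclass
class SampleNeomerProfile:
    """Per-sample feature profile: the neomer-detecting-read ratio plus a
    read count per catalog neomer (aligned to catalog order)."""

    sample_id: str
    total_reads: int
    neomer_reads: int
    counts: np.ndarray
    reads_subsampled_to: Optional[int] = None

    @property
    def ratio(self) -> float:
        return self.neomer_reads / self.total_reads if self.total_reads else 0.0


def profile_reads(
    sample_id: str,
    reads: Iterable[str],
    matcher: CatalogMatcher,
    subsample_to: Optional[int] = None,
    seed: int = 0,
) -> SampleNeomerProfile:
    """Profile an in-memory read collection (see :func:`profile_sample`)."""
    reads = list(reads)
    if subsample_to is not None:
        if subsample_to > len(reads):
            raise ValueError(
                f"{sample_id}: subsample_to={subsample_to} exceeds "
                f"{len(reads)} available reads"
            )
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=subsample_to, replace=False)
        reads = [reads[i] for i in np.sort(idx)]
    counts = np.zeros(matcher.size, dtype=np.int64)
    neomer_reads = 0
    for read in reads:
        hits = matcher.scan(read)
        if hits:
            neomer_reads += 1
            for i in hits:
                counts[i] += 1
    return SampleNeomerProfile(
        sample_id=sample_id,
        total_reads=len(reads),
        neomer_reads=neomer_reads,
        counts=counts,
        reads_subsampled_to=subsample_to,
    )


def profile_sample(
    fastq_path: str | Path,
    catalog: NeomerCatalog | CatalogMatcher,
    sample_id: Optional[str] = None,
    subsample_to: Optional[int] = None,
    seed: int = 0,
) -> SampleNeomerProfile:
    """Scan one FASTQ(.gz) file against the catalog.

    When ``subsample_to`` is set, a seeded uniform draw without
    replacement is applied before counting (the stand-in for coverage
    down-sampling in a pipeline that never aligns reads).
    """
    matcher = catalog if isinstance(catalog, CatalogMatcher) else CatalogMatcher(catalog)
    fastq_path = Path(fastq_path)
    if sample_id is None:
        sample_id = fastq_path.name.split(".")[0]
    return profile_reads(
        sample_id, iter_fastq(fastq_path), matcher, subsample_to=subsample_to, seed=seed
    )


def build_feature_matrix(
    profiles: Sequence[SampleNeomerProfile], catalog: NeomerCatalog
) -> pd.DataFrame:
    """Feature matrix of shape (samples, 1 + catalog size).

    Column 0 is the neomer-read ratio; the remaining columns are
    per-neomer read counts normalized to counts per million total reads
    (CPM) so samples of different depth are comparable.  Rows follow the
    input profile order, columns the catalog order.
    """
    ncat = len(catalog)
    for p in profiles:
        if len(p.counts) != ncat:
            raise ValueError(
                f"profile {p.sample_id} has {len(p.counts)} counts but the "
                f"catalog has {ncat} entries"
            )
    data = np.zeros((len(profiles), 1 + ncat))
    index = []
    for r, p in enumerate(profiles):
        index.append(p.sample_id)
        data[r, 0] = p.ratio
        if p.total_reads:
            data[r, 1:] = p.counts * (1e6 / p.total_reads)
    columns = ["ratio"] + list(catalog.sequences)
    return pd.DataFrame(data, index=pd.Index(index, name="sample_id"), columns=columns)


def write_profiles(profiles: Sequence[SampleNeomerProfile], path: str | Path) -> None:
    """Raw per-sample profile TSV (one row per sample; counts as a
    comma-joined vector in catalog order)."""
    rows = [
        {
            "sample_id": p.sample_id,
            "total_reads": p.total_reads,
            "neomer_reads": p.neomer_reads,
            "ratio": p.ratio,
            "reads_subsampled_to": p.reads_subsampled_to,
            "counts": ",".join(map(str, p.counts.tolist())),
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
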