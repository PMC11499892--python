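"""Synthetic cohort generator.

Emulates the full input surface of a neomer MRD study on a toy genome:
a random reference FASTA, recurrent-SNV and population-variant tables,
per-sample plasma FASTQ files in which a controlled fraction of reads
carries a tumor alternate allele, and patient survival outcomes drawn
with a controlled hazard ratio between MRD-positive and MRD-negative
patients.  Everything is deterministic given the configuration seed;
each sample's reads use a sub-seed derived from (seed, sample id) so
adding samples never perturbs existing ones.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from neomer_mrd.config import TIMEPOINTS, SimulationConfig
from neomer_mrd.dna import reverse_complement
from neomer_mrd.errors import ConfigError

BASES = np.array(list("ACGT"))

# stage tags mixed into the seed so stages draw independent streams
_STAGE_REFERENCE = 1
_STAGE_VARIANTS = 2
_STAGE_SURVIVAL = 3
_STAGE_SHEET = 4


@dataclass
class SyntheticCohort:
    """All artifacts of one simulated study, with their on-disk paths."""

    reference_path: Path
    reference: str
    recurrent_snvs: pd.DataFrame
    population_variants: pd.DataFrame
    sample_sheet: pd.DataFrame
    outdir: Path


def _sample_subseed(seed: int, sample_id: str) -> int:
    """Stable per-sample sub-seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def write_fasta(path: Path, name: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def generate_reference(config: SimulationConfig, path: Path | None = None) -> str:
    """Uniform-random A/C/G/T sequence of genome_length bases (one contig)."""
    if config.genome_length < 10 * config.k:
        raise ConfigError(
            f"genome_length {config.genome_length} < 10*k = {10 * config.k}"
        )
    rng = np.random.default_rng([config.seed, _STAGE_REFERENCE])
    seq = "".join(BASES[rng.integers(0, 4, size=config.genome_length)])
    if path is not None:
        write_fasta(Path(path), "chr1", seq)
    return seq


def generate_variants(
    reference: str, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recurrent-SNV and population-variant tables on the toy genome.

    Positions are pairwise >= k apart (one block per variant, random
    offset within the block) so each neomer traces to a single SNV.  A
    fraction ``overlap_fraction`` of recurrent SNVs is copied verbatim
    into the population list to exercise the population filter.
    """
    n_total = config.n_recurrent_snvs + config.n_population_variants
    L = len(reference)
    if n_total > L / (2 * config.k):
        raise ConfigError(
            f"{n_total} variants do not fit {L} bp at spacing 2k={2 * config.k}"
        )
    rng = np.random.default_rng([config.seed, _STAGE_VARIANTS])
    stride = L // n_total
    offsets = rng.integers(0, stride - config.k + 1, size=n_total)
    pos0 = np.arange(n_total) * stride + offsets  # 0-based
    rng.shuffle(pos0)

    def _table(positions: np.ndarray) -> pd.DataFrame:
        positions = np.sort(positions)
        refs = [reference[p] for p in positions]
        alts = []
        for r in refs:
            choices = [b for b in "ACGT" if b != r]
            alts.append(choices[rng.integers(0, 3)])
        return pd.DataFrame(
            {"chrom": "chr1", "pos": positions + 1, "ref": refs, "alt": alts}
        )

    rec = _table(pos0[: config.n_recurrent_snvs])
    pop = _table(pos0[config.n_recurrent_snvs :])
    rec["count"] = rng.integers(2, 50, size=len(rec))
    pop["af"] = np.round(rng.uniform(0.01, 0.5, size=len(pop)), 4)

    n_overlap = int(round(config.overlap_fraction * len(rec)))
    if n_overlap > 0:
        dup_idx = rng.choice(len(rec), size=n_overlap, replace=False)
        dup = rec.iloc[np.sort(dup_idx)][["chrom", "pos", "ref", "alt"]].copy()
        dup["af"] = np.round(rng.uniform(0.01, 0.5, size=len(dup)), 4)
        pop = (
            pd.concat([pop, dup], ignore_index=True)
            .sort_values("pos", kind="stable")
            .reset_index(drop=True)
        )
    return rec, pop


def generate_reads(
    reference: str,
    recurrent_snvs: pd.DataFrame,
    sample_id: str,
    tumor_fraction: float,
    config: SimulationConfig,
    path: Path | None = None,
    forward_only: bool = False,
) -> list[str]:
    """Simulate one sample's reads; write 4-line FASTQ when a path is given.

    Each read is a read_length window of the genome on a random strand.
    With probability ``tumor_fraction`` the window is forced to span a
    randomly chosen recurrent SNV and carries its alternate base;
    otherwise the window is reference-identical.  Quality strings are
    constant (the scanner ignores quality).
    """
    L = len(reference)
    if config.read_length > L:
        raise ConfigError(f"read_length {config.read_length} > genome length {L}")
    rng = np.random.default_rng(_sample_subseed(config.seed, sample_id))
    pos0 = recurrent_snvs["pos"].to_numpy() - 1
    alts = recurrent_snvs["alt"].to_numpy()
    rlen = config.read_length
    reads: list[str] = []
    for _ in range(config.reads_per_sample):
        if len(pos0) > 0 and rng.random() < tumor_fraction:
            j = rng.integers(0, len(pos0))
            p = int(pos0[j])
            lo = max(0, p - rlen + 1)
            hi = min(L - rlen, p)
            start = int(rng.integers(lo, hi + 1))
            seq = reference[start : start + rlen]
            seq = seq[: p - start] + alts[j] + seq[p - start + 1 :]
        else:
            start = int(rng.integers(0, L - rlen + 1))
            seq = reference[start : start + rlen]
        if not forward_only and rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(seq)
    if path is not None:
        write_fastq(Path(path), sample_id, reads)
    return reads


def write_fastq(path: Path, sample_id: str, reads: list[str]) -> None:
    """Write 4-line FASTQ records; .gz paths are gzipped reproducibly."""
    path = Path(path)
    if path.suffix == ".gz":
        fh = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
        close = True
    else:
        fh = open(path, "wb")
        close = True
    try:
        for i, seq in enumerate(reads):
            rec = f"@{sample_id}:read{i}\n{seq}\n+\n{'I' * len(seq)}\n"
            fh.write(rec.encode())
    finally:
        if close:
            fh.close()


# relative half-width of the follow-up window: censoring times are drawn
# uniformly on [0.7 T, 1.3 T] around the calibrated central follow-up T,
# emulating administrative censoring with staggered accrual
_FOLLOWUP_SPREAD = 0.3


def _followup_midpoint(rates: np.ndarray, censoring_rate: float) -> float:
    """Central follow-up time T of the Uniform(0.7 T, 1.3 T) censoring law
    giving the target marginal censored fraction for a mixture of
    exponential event times.

    For C ~ U(a, b), P(T_event > C) = (e^{-la} - e^{-lb}) / (l (b - a)).
    """
    lo, hi = 1.0 - _FOLLOWUP_SPREAD, 1.0 + _FOLLOWUP_SPREAD

    def frac_censored(t: float) -> float:
        a, b = rates * lo * t, rates * hi * t
        p = (np.exp(-a) - np.exp(-b)) / (b - a)
        return float(np.mean(p)) - censoring_rate

    # decreases from 1 (t -> 0) toward 0 (t -> inf)
    return brentq(frac_censored, 1e-9, 1e9)


def generate_survival(
    config: SimulationConfig,
    true_mrd_labels: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """PFS times, event flags and assay-observed mutation status per patient.

    Event times are exponential with rate ``baseline_event_rate`` for
    MRD-negative and ``baseline_event_rate * true_hr`` for MRD-positive
    patients.  Censoring is administrative: each patient's follow-up
    ends at an independent Uniform(0.7 T, 1.3 T) time, with the central
    follow-up T calibrated so the marginal censored fraction equals
    ``censoring_rate`` — so, as in a prospective cohort, high-hazard
    patients almost always progress within follow-up and censored
    patients are predominantly low-hazard.  The binary ctDNA mutation
    status is sampled per patient from the true MRD label through the
    configured assay sensitivity/specificity.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _STAGE_SURVIVAL])
    labels = np.asarray(true_mrd_labels, dtype=bool)
    n = len(labels)
    rates = np.where(labels, config.baseline_event_rate * config.true_hr,
                     config.baseline_event_rate)
    event_times = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        t_mid = _followup_midpoint(rates, config.censoring_rate)
        censor_times = rng.uniform(
            (1.0 - _FOLLOWUP_SPREAD) * t_mid, (1.0 + _FOLLOWUP_SPREAD) * t_mid, size=n
        )
    else:
        censor_times = np.full(n, np.inf)
    pfs = np.minimum(event_times, censor_times)
    event = event_times <= censor_times
    p_positive = np.where(labels, config.mutation_assay_sensitivity,
                          1.0 - config.mutation_assay_specificity)
    mutation = rng.random(n) < p_positive
    return pd.DataFrame(
        {
            "true_mrd": labels,
            "pfs_time": pfs,
            "event": event,
            "ctdna_mutation_positive": mutation,
        }
    )


def generate_cohort(config: SimulationConfig, outdir: str | Path) -> SyntheticCohort:
    """Generate and write the complete synthetic study into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)

    ref_path = outdir / "reference.fa"
    reference = generate_reference(config, ref_path)
    rec, pop = generate_variants(reference, config)
    rec.to_csv(outdir / "recurrent_snvs.tsv", sep="\t", index=False)
    pop.to_csv(outdir / "population_variants.tsv", sep="\t", index=False)

    rng = np.random.default_rng([config.seed, _STAGE_SHEET])
    n = config.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    true_mrd = rng.random(n) < config.mrd_positive_rate
    survival = generate_survival(config, true_mrd)
    survival.insert(0, "patient_id", patient_ids)

    rows = []
    for tp, n_tp in zip(TIMEPOINTS, config.samples_per_timepoint):
        if n_tp == 0:
            continue
        chosen = np.sort(rng.choice(n, size=n_tp, replace=False))
        for idx in chosen:
            pid = patient_ids[idx]
            sample_id = f"{pid}_{tp}"
            tf = (
                config.tumor_fraction_positive
                if true_mrd[idx]
                else config.tumor_fraction_negative
            )
            fastq = reads_dir / f"{sample_id}.fastq"
            generate_reads(reference, rec, sample_id, tf, config, path=fastq)
            rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": pid,
                    "timepoint": tp,
                    "fastq": str(fastq),
                    "pfs_time": survival.loc[idx, "pfs_time"],
                    "event": int(survival.loc[idx, "event"]),
                    "true_mrd": int(true_mrd[idx]),
                    "ctdna_mutation_positive": int(
                        survival.loc[idx, "ctdna_mutation_positive"]
                    ),
                }
            )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    return SyntheticCohort(
        reference_path=ref_path,
        reference=reference,
        recurrent_snvs=rec,
        population_variants=pop,
        sample_sheet=sheet,
        outdir=outdir,
    )
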