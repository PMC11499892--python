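"""Repeatable in-silico experiments over the full pipeline.

These drive the synthetic cohort generator through catalog building,
scanning and LOOCV risk modelling entirely in memory, and are used both
by the analysis drivers and by the acceptance checks: Cox hazard-ratio
recovery (CI coverage of the generator's true hazard ratio) and
MRD-label recovery by the risk model at the 0.90-specificity anchor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from neomer_mrd.catalog import build_catalog
from neomer_mrd.config import ModelConfig, SimulationConfig
from neomer_mrd.risk import loocv_predict
from neomer_mrd.scanner import CatalogMatcher, build_feature_matrix, profile_reads
from neomer_mrd.simulate import generate_reads, generate_reference, generate_survival, generate_variants
from neomer_mrd.stats import km_cox_hr


def cox_hr_coverage(
    true_hr: float = 4.0,
    n_patients: int = 200,
    n_replicates: int = 100,
    censoring_rate: float = 0.2,
    seed: int = 0,
) -> dict:
    """Wald 95% CI coverage of the true hazard ratio over replicated
    synthetic cohorts (survival layer only)."""
    covered = 0
    hrs = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(true_hr=true_hr, censoring_rate=censoring_rate,
                               seed=seed)
        rng = np.random.default_rng([seed, rep])
        labels = rng.random(n_patients) < cfg.mrd_positive_rate
        df = generate_survival(cfg, labels, rng)
        res, _ = km_cox_hr(df["pfs_time"], df["event"], df["true_mrd"])
        hrs.append(res.hr)
        if res.ci_low <= true_hr <= res.ci_high:
            covered += 1
    return {
        "true_hr": true_hr,
        "n_patients": n_patients,
        "n_replicates": n_replicates,
        "covered": covered,
        "coverage": covered / n_replicates,
        "median_hr": float(np.median(hrs)),
    }


def recovery_cohort_config(seed: int, tumor_fraction: float = 0.05) -> SimulationConfig:
    """Scaled-down single-time-point 40-patient cohort used for the
    MRD-label recovery experiment (sizes documented in the methods note)."""
    return SimulationConfig(
        genome_length=100_000,
        n_recurrent_snvs=60,
        n_population_variants=30,
        n_patients=40,
        samples_per_timepoint=(40, 0, 0),
        reads_per_sample=2000,
        tumor_fraction_positive=tumor_fraction,
        overlap_fraction=0.1,
        seed=seed,
    )


def simulate_profiles(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run simulate -> catalog -> scan in memory for one time point.

    Returns (feature matrix, records frame with outcomes and true MRD
    labels).  Only the first time point's sample count is used.
    """
    reference = generate_reference(config)
    rec, pop = generate_variants(reference, config)
    catalog = build_catalog(rec, pop, reference, k=config.k)
    matcher = CatalogMatcher(catalog)
    rng = np.random.default_rng([config.seed, 4])
    n = config.n_patients
    labels = rng.random(n) < config.mrd_positive_rate
    survival = generate_survival(config, labels)
    n_tp1 = config.samples_per_timepoint[0]
    chosen = np.sort(rng.choice(n, size=n_tp1, replace=False))
    profiles = []
    rows = []
    for idx in chosen:
        sample_id = f"P{idx + 1:03d}_TP1"
        tf = (
            config.tumor_fraction_positive
            if labels[idx]
            else config.tumor_fraction_negative
        )
        reads = generate_reads(reference, rec, sample_id, tf, config)
        profiles.append(profile_reads(sample_id, reads, matcher))
        rows.append(
            {
                "sample_id": sample_id,
                "patient_id": f"P{idx + 1:03d}",
                "timepoint": "TP1",
                "pfs_time": survival.loc[idx, "pfs_time"],
                "event": bool(survival.loc[idx, "event"]),
                "true_mrd": bool(labels[idx]),
                "ctdna_mutation_positive": bool(
                    survival.loc[idx, "ctdna_mutation_positive"]
                ),
            }
        )
    features = build_feature_matrix(profiles, catalog)
    return features, pd.DataFrame(rows)


def mrd_label_recovery(
    n_seeds: int = 20,
    tumor_fraction: float = 0.05,
    target_specificity: float = 0.90,
    seed: int = 0,
) -> dict:
    """Sensitivity of pooled-LOOCV high-risk calls against the generator's
    true MRD labels, across seeded cohort replicates."""
    sensitivities = []
    specificities = []
    for s in range(n_seeds):
        cfg = recovery_cohort_config(seed=(seed * 1000 + s) % (2**31),
                                     tumor_fraction=tumor_fraction)
        features, records = simulate_profiles(cfg)
        preds, _ = loocv_predict(
            features, records, ModelConfig(target_specificity=target_specificity)
        )
        merged = preds.merge(records, on="sample_id")
        truth = merged["true_mrd"].to_numpy(dtype=bool)
        calls = merged["high_risk"].to_numpy(dtype=bool)
        sensitivities.append((calls & truth).sum() / truth.sum())
        neg = ~truth
        specificities.append((~calls[neg]).sum() / neg.sum())
    return {
        "n_seeds": n_seeds,
        "tumor_fraction": tumor_fraction,
        "sensitivities": sensitivities,
        "median_sensitivity": float(np.median(sensitivities)),
        "median_specificity_vs_true_mrd": float(np.median(specificities)),
    }
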