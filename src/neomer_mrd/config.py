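"""Validated configuration objects for simulation, modelling and runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from neomer_mrd.errors import ConfigError

TIMEPOINTS = ("TP1", "TP2", "TP3")


@dataclass
class SimulationConfig:
    """Parameters of the fully in-silico cohort.

    Defaults mirror the study design this package emulates: a 44-patient
    cohort sampled at three time points (39/33/25 plasma samples), 16-bp
    neomers, 150-bp reads.  Sizes the study does not fix (genome length,
    variant counts, read depth) default to a scaled-down but structurally
    faithful demo; see docs/methods.md.
    """

    genome_length: int = 1_000_000
    n_recurrent_snvs: int = 200
    n_population_variants: int = 100
    k: int = 16
    n_patients: int = 44
    samples_per_timepoint: tuple[int, int, int] = (39, 33, 25)
    read_length: int = 150
    reads_per_sample: int = 2000
    tumor_fraction_positive: float = 0.05
    tumor_fraction_negative: float = 0.0
    true_hr: float = 4.0
    censoring_rate: float = 0.2  # implied by ~26-month follow-up at the default rates
    mrd_positive_rate: float = 0.5
    baseline_event_rate: float = 1.0 / 24.0  # events per month, MRD-negative
    mutation_assay_sensitivity: float = 0.8
    mutation_assay_specificity: float = 0.9
    overlap_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ConfigError(f"k must be >= 4, got {self.k}")
        if self.genome_length < 10 * self.k:
            raise ConfigError(
                f"genome_length must be >= 10*k ({10 * self.k}), got {self.genome_length}"
            )
        if not (0.0 <= self.tumor_fraction_negative < self.tumor_fraction_positive <= 1.0):
            raise ConfigError(
                "need 0 <= tumor_fraction_negative < tumor_fraction_positive <= 1, got "
                f"{self.tumor_fraction_negative} / {self.tumor_fraction_positive}"
            )
        if self.true_hr <= 0:
            raise ConfigError(f"true_hr must be > 0, got {self.true_hr}")
        for name in ("n_recurrent_snvs", "n_population_variants", "n_patients",
                     "read_length", "reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        self.samples_per_timepoint = tuple(self.samples_per_timepoint)
        if len(self.samples_per_timepoint) != 3:
            raise ConfigError("samples_per_timepoint needs one count per TP1/TP2/TP3")
        if any(n < 0 or n > self.n_patients for n in self.samples_per_timepoint):
            raise ConfigError(
                f"each samples_per_timepoint count must be in [0, n_patients], "
                f"got {self.samples_per_timepoint}"
            )
        if sum(self.samples_per_timepoint) == 0:
            raise ConfigError("at least one time point needs samples")
        n_variants = self.n_recurrent_snvs + self.n_population_variants
        if n_variants > self.genome_length / (2 * self.k):
            raise ConfigError(
                f"{n_variants} variants do not fit a {self.genome_length}-bp genome "
                f"at spacing 2k={2 * self.k}"
            )
        if self.read_length > self.genome_length:
            raise ConfigError("read_length exceeds genome_length")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError(f"censoring_rate must be in [0, 1), got {self.censoring_rate}")
        for name in ("mrd_positive_rate", "mutation_assay_sensitivity",
                     "mutation_assay_specificity", "overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_event_rate <= 0:
            raise ConfigError("baseline_event_rate must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["samples_per_timepoint"] = list(self.samples_per_timepoint)
        return d


@dataclass
class ModelConfig:
    """Survival-SVM and cutoff settings for one time point.

    gamma weighs the comparable-pair hinge loss against the L2 penalty;
    the cutoff on pooled out-of-fold scores is anchored at
    target_specificity (default 0.90) among non-progressors.
    """

    gamma: float = 1.0
    target_specificity: float = 0.90
    standardize: bool = True
    cutoff_mode: str = "pooled"  # "pooled" | "per_fold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ConfigError(f"gamma must be > 0, got {self.gamma}")
        if not 0.0 < self.target_specificity < 1.0:
            raise ConfigError(
                f"target_specificity must be in (0, 1), got {self.target_specificity}"
            )
        if self.cutoff_mode not in ("pooled", "per_fold"):
            raise ConfigError(f"unknown cutoff_mode {self.cutoff_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """Configuration of a full simulate -> catalog -> scan -> fit -> evaluate run."""

    outdir: Path
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    # external inputs, used when simulation is disabled
    reference: Optional[Path] = None
    recurrent_snvs: Optional[Path] = None
    population_variants: Optional[Path] = None
    sample_sheet: Optional[Path] = None
    af_threshold: float = 0.0
    model: ModelConfig = field(default_factory=ModelConfig)
    subsample_to: Optional[int] = None
    kappa_bootstrap: int = 2000
    accuracy_bootstrap: int = 1000
    longitudinal_source: str = "combined"  # "combined" | "neomer"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulation is None:
            missing = [n for n in ("reference", "recurrent_snvs",
                                   "population_variants", "sample_sheet")
                       if getattr(self, n) is None]
            if missing:
                raise ConfigError(
                    "either enable simulation or provide inputs: " + ", ".join(missing)
                )
            for n in ("reference", "recurrent_snvs", "population_variants", "sample_sheet"):
                setattr(self, n, Path(getattr(self, n)))
        if self.af_threshold < 0:
            raise ConfigError("af_threshold must be >= 0")
        if self.longitudinal_source not in ("combined", "neomer"):
            raise ConfigError(f"unknown longitudinal_source {self.longitudinal_source!r}")
        for n in ("kappa_bootstrap", "accuracy_bootstrap"):
            if getattr(self, n) < 1:
                raise ConfigError(f"{n} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        model = raw.pop("model", None)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulation"] = SimulationConfig(**sim)
        if model is not None:
            kwargs["model"] = ModelConfig(**model)
        try:
            return cls(**kwargs)
        except TypeError as exc:  # unknown keys -> config error, not traceback
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "af_threshold": self.af_threshold,
            "subsample_to": self.subsample_to,
            "kappa_bootstrap": self.kappa_bootstrap,
            "accuracy_bootstrap": self.accuracy_bootstrap,
            "longitudinal_source": self.longitudinal_source,
            "log_level": self.log_level,
            "model": self.model.to_dict(),
            "simulation": self.simulation.to_dict() if self.simulation else None,
        }
        for n in ("reference", "recurrent_snvs", "population_variants", "sample_sheet"):
            v = getattr(self, n)
            d[n] = str(v) if v is not None else None
        return d
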