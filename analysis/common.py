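"""Shared paths and the demo study configuration for the numbered
analysis drivers.  Bulky pipeline artifacts (FASTQs, feature matrices)
go under scratch/; small summary tables go under results/."""

from pathlib import Path

from neomer_mrd.config import ModelConfig, SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RUN = ROOT / "scratch" / "run"
COHORT = RUN / "cohort"
RESULTS.mkdir(parents=True, exist_ok=True)

SEED = 0

# the demo study: 1 Mb genome, 200 recurrent SNVs, a 40-patient cohort
# sampled at three time points (36/30/24 plasma samples)
SIM_CONFIG = SimulationConfig(
    genome_length=1_000_000,
    n_recurrent_snvs=200,
    n_population_variants=100,
    n_patients=40,
    samples_per_timepoint=(36, 30, 24),
    reads_per_sample=2000,
    seed=SEED,
)

MODEL_CONFIG = ModelConfig(seed=SEED)
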