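"""Shared study-scale synthetic cohort for the analysis scripts.

One deterministic two-arm cohort emulating the study: 36 baseline and 34
post-intervention skin-swab samples, read depths drawn from the truncated
log-normal law fitted to the study's printed depth summary (min 63,892,
max 975,103, mean ~326,333), 60 species-level taxa, and a post arm whose
true association network is three times denser than baseline.
"""

from miconet import CohortDesign, PipelineConfig, two_arm_dataset

SEED = 20240901
N_TAXA = 60
# densities chosen to keep the true mean degrees (~1.5 baseline, ~4.4 post)
# in the sparse regime typical of microbiome co-occurrence networks
DENSITY_BASELINE = 0.025
DENSITY_POST = 0.075


def study_design() -> CohortDesign:
    return CohortDesign(n_baseline=36, n_post=34, seed=SEED)


def study_cohort():
    """(CountTable, TrueModel_baseline, TrueModel_post), deterministic."""
    return two_arm_dataset(
        N_TAXA, DENSITY_BASELINE, DENSITY_POST, study_design()
    )


def study_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, out_dir="results")
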