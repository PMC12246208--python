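"""Shared configuration for the numbered analysis scripts.

One top-level seed drives every stage; outputs accumulate under
``results/analysis/``.  The simulated sample follows the reference-sample
composition (12 cold / 29 temperate / 18 warm specimens) with a configured
monotone ecogeographic size gradient, and two fossils masked to the
Ohalo II H2 and Nazlet Khater 2 preservation patterns.
"""

from pathlib import Path

from thoraxgm import PipelineConfig
from thoraxgm.experiments import END_TO_END_SIZE_MEANS

SEED = 1
RESULTS_DIR = Path(__file__).resolve().parent.parent / "results" / "analysis"


def make_config() -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        output_dir=str(RESULTS_DIR),
        thorax={"group_size_means": dict(END_TO_END_SIZE_MEANS)},
        patterns=["ohalo_2", "nazlet_khater_2"],
        kyphosis={"intercept": 10.0, "slope": 30.0},
        n_permutations=10_000,
    )
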