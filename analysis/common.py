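"""Shared settings for the numbered analysis drivers."""

import os

from neurocycle.synthetic_data import SimulationConfig

SEED = 1
OUT_DIR = os.path.join(os.path.dirname(os.path.dirname(os.path.abspath(__file__))),
                       "results")

#: Study-design conditions used throughout the analysis: 2,000 genes, 10%
#: cyclers at amplitude fold 4, per-timepoint CV ~ 0.2, 20% group-restricted
#: genes, 10% below the enrichment expression filter.
SIM_CONFIG = SimulationConfig(
    n_genes=2000,
    frac_cyclers=0.1,
    amplitude_fold=4.0,
    dispersion=0.04,
    frac_group_restricted=0.2,
    frac_low_expression=0.1,
    seed=SEED,
)
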