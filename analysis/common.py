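"""Shared study configuration for the analysis scripts.

The study panel emulates a decade of county-level hospital-bed records:
a 15x15 rook-contiguity lattice (225 counties) partitioned into 9
contiguous provinces, observed 2002-2011, with three standardized
covariates whose effects vary over space (ICAR fields, SD 0.5) and time
(RW2 paths, SD 0.3) around global levels (1.0, 0.5, -0.5), and
log-Gaussian noise (SD 0.2).
"""

from pathlib import Path

import geotriad as gt

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 2002


def study_config(seed: int = SEED) -> gt.SimulationConfig:
    return gt.SimulationConfig(
        grid_rows=15,
        grid_cols=15,
        n_years=10,
        n_covariates=3,
        region_blocks=3,
        sd_mu=(0.5, 0.5, 0.5),
        sd_gamma=(0.3, 0.3, 0.3),
        beta=(1.0, 0.5, -0.5),
        sd_eps=0.2,
        seed=seed,
    )


def study_panel(seed: int = SEED):
    """Deterministic study panel (regenerated on demand; < 1 s)."""
    return gt.simulate_panel(study_config(seed))
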