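"""Shared run configuration for the numbered analysis drivers.

A desk-scale study: 800 individuals, 1,500 variants, 27 lifestyle
variables, the reduced 3000/500/5 Gibbs schedule, and a relatedness
threshold matched to the variant count (the study's 0.025 presupposes
hundreds of thousands of variants).

Bulky intermediates (genotypes, kernels, adjusted matrices) live under
``scratch/workspace``; each driver copies its small summary tables into
``results/``.
"""

import shutil
from pathlib import Path

_ROOT = Path(__file__).resolve().parent.parent
WORKDIR = _ROOT / "scratch" / "workspace"
RESULTS = _ROOT / "results"

CONFIG = {
    "simulate": {"n_individuals": 800, "n_variants": 1500, "seed": 2024},
    "qc": {"maf_min": 0.01, "mac_min": 5, "miss_max": 0.1, "hwe_p_min": 1e-10},
    "relatedness_threshold": 0.2,
    "mcmc": {"n_iter": 3000, "burn_in": 500, "thin": 5},
    "models": ["M0", "M1", "M11", "M13", "M23", "M02"],
    "traits": ["SP", "DP", "PP"],
    "split": "Y-O",
    "standardize_adjusted": True,
    "truncated_rank": 20,
    "seed": 2024,
}


def publish(*names):
    """Copy small workspace tables into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        shutil.copy(WORKDIR / name, RESULTS / name)
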