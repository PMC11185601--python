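#!/usr/bin/env python
"""Decompose each lifestyle variable into cohort, genetic, cross-lifestyle
and residual parts, and build the adjusted E (residual) and L (predicted)
matrices plus the eigen-summaries of the three lifestyle kernels."""

from _config import CONFIG, WORKDIR, publish

import pandas as pd

from polylife.pipeline import stage_adjust

stage_adjust(CONFIG, WORKDIR)
var = pd.read_csv(WORKDIR / "lifestyle_variance.tsv", sep="\t")
print("mean variance fractions across the 27 lifestyle variables:")
print(var[["frac_cohort", "frac_lifestyle", "frac_genetic",
           "frac_residual"]].mean().round(3).to_string())
es = pd.read_csv(WORKDIR / "kernel_eigen_summary.tsv", sep="\t")
lead = es[es["component"] == 2].set_index("kernel")["cumulative_proportion"]
print("\ncumulative variance at component 2 per kernel "
      "(LL should dominate):")
print(lead.round(3).to_string())
publish("lifestyle_variance.tsv", "kernel_eigen_summary.tsv")
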