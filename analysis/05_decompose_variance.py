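#!/usr/bin/env python
"""Fit the model suite on the full data and decompose phenotypic variance
into cohort, lifestyle, genetic, interaction and residual components."""

from _config import CONFIG, WORKDIR, publish

import pandas as pd

from polylife.pipeline import stage_decompose

stage_decompose(CONFIG, WORKDIR)
tab = pd.read_csv(WORKDIR / "variance_table.tsv", sep="\t")
wide = tab.pivot_table(index=["trait", "model"], columns="component",
                       values="mean").round(1)
print("posterior-mean variance explained (response variance = 100):")
print(wide.to_string())
publish("variance_table.tsv")
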