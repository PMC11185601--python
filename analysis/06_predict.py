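#!/usr/bin/env python
"""Young-to-old prediction: train on the two younger age groups, validate
on the two older ones, and report accuracy r and bias (beta0, beta1)."""

from _config import CONFIG, WORKDIR, publish

import pandas as pd

from polylife.pipeline import stage_predict

stage_predict(CONFIG, WORKDIR)
tab = pd.read_csv(WORKDIR / "prediction_table.tsv", sep="\t")
print(tab.round(3).to_string(index=False))
best = tab.loc[tab.groupby("trait")["r"].idxmax()]
print("\nbest model per trait:")
print(best[["trait", "model", "r"]].round(3).to_string(index=False))
publish("prediction_table.tsv")
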