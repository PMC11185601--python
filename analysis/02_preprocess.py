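#!/usr/bin/env python
"""Variant QC, medication adjustment, pulse-pressure derivation, cohort and
RND group assignment, and relatedness pruning."""

from _config import CONFIG, WORKDIR, publish

import pandas as pd

from polylife.pipeline import stage_preprocess

stage_preprocess(CONFIG, WORKDIR)
qc = pd.read_csv(WORKDIR / "variant_qc.tsv", sep="\t")
pheno = pd.read_csv(WORKDIR / "phenotypes.tsv", sep="\t")
print(f"variant QC: {qc['retained'].sum()}/{len(qc)} variants retained")
print(f"{len(pheno)} individuals after relatedness pruning")
print("cohort sizes:")
print(pheno["cohort"].value_counts().sort_index().to_string())
summary = qc[["pass_maf", "pass_mac", "pass_missing", "pass_hwe",
              "retained"]].sum().rename("n_variants").to_frame()
summary.to_csv(WORKDIR / "variant_qc_summary.tsv", sep="\t")
publish("variant_qc_summary.tsv")
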