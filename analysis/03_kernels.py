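#!/usr/bin/env python
"""Build the genomic relationship matrix (with GCTA-format export) and the
truncated-PC structure kernel."""

from _config import CONFIG, WORKDIR, publish

import numpy as np

from polylife.pipeline import stage_kernels

stage_kernels(CONFIG, WORKDIR)
grm = np.load(WORKDIR / "grm.npz")["matrix"]
off = grm[~np.eye(grm.shape[0], dtype=bool)]
print(f"GRM: {grm.shape[0]} individuals, diagonal mean {grm.diagonal().mean():.3f}, "
      f"off-diagonal sd {off.std():.4f}")
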