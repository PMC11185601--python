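"""Compiled inner loop for single-site Gibbs coordinate updates."""

import numpy as np
from numba import njit


@njit(cache=True)
def scalar_coord_update(delta, zt, vv, prior_var, resid, sig2_e, z):
    """Sequential scalar Gibbs update of regression coordinates in-place.

    delta : (m,) current coordinates, updated in-place.
    zt : (m, n_obs) transposed design on observed rows (row-contiguous).
    vv : (m,) column sums of squares of the design.
    prior_var : (m,) prior variance per coordinate.
    resid : (n_obs,) residual vector y - X b - all effects, updated in-place.
    z : (m,) standard normal draws.
    """
    m = delta.shape[0]
    n = resid.shape[0]
    for j in range(m):
        old = delta[j]
        cj = vv[j] * old
        for i in range(n):
            cj += zt[j, i] * resid[i]
        prec = vv[j] / sig2_e + 1.0 / prior_var[j]
        mu = (cj / sig2_e) / prec
        new = mu + z[j] / np.sqrt(prec)
        diff = new - old
        for i in range(n):
            resid[i] -= zt[j, i] * diff
        delta[j] = new
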