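"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own numerics: the steady state of the
cylindrical diffusion-decay problem is written with Bessel functions, and the
partial rank correlation is computed from the inverse of the full rank
correlation matrix.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import k0, k1
from scipy.stats import rankdata


def bessel_steady_state(solute, root, dp, k_eff_hr, r):
    """Analytic equilibrium profile for diffusion + first-order decay.

    Solves (1/r)(r De C')' = k C on r > r0 with the passive-efflux boundary
    condition A*P*(Ccyto - C(r0)) = -2*pi*r0*De*C'(r0) and C -> 0 far away
    (valid when q*R_outer >> 1), with constant De (no sorption/retardation).
    The decaying solution is C(r) = B*K0(q*r), q = sqrt(k/De).
    """
    De_hr = solute.D_inf * 3600.0 * dp.eps / dp.tau**2  # cm^2 hr^-1
    q = math.sqrt(k_eff_hr / De_hr)
    AP = root.A * solute.P
    x0 = q * root.r0
    B = AP * solute.Ccyto / (
        2.0 * math.pi * root.r0 * De_hr * q * k1(x0) + AP * k0(x0)
    )
    return B * k0(q * np.asarray(r, dtype=float))


def prcc_matrix_oracle(table, parameters, response):
    """Partial rank correlations from the inverse rank-correlation matrix.

    For jointly considered columns, the partial correlation of x_i and y
    given all the others is -Om_ij / sqrt(Om_ii * Om_jj) with Om the inverse
    of the correlation matrix of the rank-transformed columns.
    """
    cols = list(parameters) + [response]
    R = np.column_stack([rankdata(np.asarray(table[c], dtype=float)) for c in cols])
    om = np.linalg.inv(np.corrcoef(R, rowvar=False))
    k = len(parameters)
    return {
        p: -om[i, k] / math.sqrt(om[i, i] * om[k, k])
        for i, p in enumerate(parameters)
    }
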