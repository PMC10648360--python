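"""Internal design-matrix orthogonalisation for the likelihood optimisers.

Raw FACT-L designs mix columns of wildly different magnitude and near-
collinear pairs (a domain score and its square correlate at ~0.99),
which cripples quasi-Newton steps and raises the attainable gradient
floor.  Optimisation therefore runs in the orthonormal column basis of
a thin QR decomposition — the Hessian is then well conditioned — and
coefficients are mapped back through the triangular factor afterwards.
The linear predictor is identical in both bases, so log-likelihoods,
cutpoints and link-scale quantities need no adjustment.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg


def orthonormalize(X: np.ndarray):
    """Return (Z, R) with Z = X @ inv(R), Z's columns orthonormal.

    Requires full column rank; callers validate that beforehand.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return X, np.empty((0, 0))
    Q, R = np.linalg.qr(X)
    if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(np.diag(R)))):
        raise ValueError("design matrix is numerically rank deficient")
    return Q, R


def coef_to_raw(beta_z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Map coefficients on the orthonormal basis back to the raw design.

    ``Q @ beta_z == X @ coef_to_raw(beta_z, R)``.
    """
    if R.shape[0] == 0:
        return np.asarray(beta_z, dtype=float)
    return linalg.solve_triangular(R, np.asarray(beta_z, dtype=float))
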