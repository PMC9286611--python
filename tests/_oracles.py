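"""Independent oracles used by the test suite.

The enumeration oracle computes the exact posterior over population size N
for a tiny discretized SCR instance (binomial detections of fully identified
individuals) by exhaustive summation: activity centers over a finite grid,
sigma and p0 over finite grids with uniform priors, inclusion indicators for
the augmented slots enumerated through the binomial identity, and the
Beta(1,1) prior on psi integrated analytically.  It shares no code with the
sampler it validates.
"""

import numpy as np
from scipy.special import betaln, comb
from scipy.stats import binom


def enumerate_posterior_N(y, det_xy, s_grid, sigma_grid, p0_grid, M, K):
    """Exact posterior P(N = n) for the discretized binomial-SCR instance.

    Parameters
    ----------
    y : (n_det, J) observed detection counts (0..K) of the detected individuals.
    det_xy : (J, 2) detector coordinates.
    s_grid : (Ns, 2) admissible activity-center locations (uniform prior).
    sigma_grid, p0_grid : admissible parameter values (uniform priors).
    M : augmentation size; detected individuals have z = 1 fixed.
    K : number of binomial occasions.

    Returns
    -------
    dict n -> probability, for n = n_det .. M.
    """
    y = np.asarray(y)
    n_det = y.shape[0]
    n_aug = M - n_det
    post = {n: 0.0 for n in range(n_det, M + 1)}
    d2 = ((s_grid[:, None, :] - det_xy[None, :, :]) ** 2).sum(axis=2)  # (Ns, J)
    for sig in sigma_grid:
        kern = np.exp(-d2 / (2.0 * sig**2))
        for p0 in p0_grid:
            p = p0 * kern  # (Ns, J)
            # per detected individual: likelihood averaged over the s grid
            L_det = 1.0
            for i in range(n_det):
                L_i = binom.pmf(y[i][None, :], K, p).prod(axis=1).mean()
                L_det *= L_i
            # all-zero history, averaged over the s grid
            L0 = binom.pmf(0, K, p).prod(axis=1).mean()
            for m in range(n_aug + 1):
                w = (
                    comb(n_aug, m)
                    * np.exp(betaln(n_det + m + 1, M - n_det - m + 1))
                    * L_det
                    * L0**m
                )
                post[n_det + m] += w
    total = sum(post.values())
    return {n: v / total for n, v in post.items()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
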