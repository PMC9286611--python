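"""Half-normal detection kernels and covariate/link machinery.

Every model variant shares the same spatial detection structure: the
probability (or rate) of detecting an individual at a detector decays with
the Euclidean distance d between the detector and the individual's activity
center as exp(-d^2 / (2 sigma^2)), where sigma is a spatial scale parameter
proportional to home-range size.  Detection parameters may vary by a latent
or observed group (sex, or resident/transient behavioral status).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def halfnormal_p(p0, sigma, d):
    """Detection probability p0 * exp(-d^2 / (2 sigma^2)).

    p0 is the baseline probability when the detector sits exactly at the
    activity center; the kernel is strictly decreasing in d and reaches
    p0/2 at d = sigma * sqrt(2 ln 2).
    """
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 <= 0) or np.any(p0 >= 1):
        raise ValueError("p0 must lie in (0, 1)")
    return halfnormal_lambda(p0, sigma, d)


def halfnormal_lambda(lambda0, sigma, d):
    """Expected encounter rate lambda0 * exp(-d^2 / (2 sigma^2))."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return np.asarray(lambda0, dtype=float) * np.exp(-(d**2) / (2.0 * sigma**2))


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def effort_logit_p0(alpha0, alpha1, effort_km):
    """Baseline detection probability under a logit-linear survey-effort model.

    p0_j = logit^{-1}(alpha0 + alpha1 * effort_j); with alpha1 = 0 this
    reduces to a constant baseline across cells.  Output is always in (0, 1);
    zero-effort cells get the intercept-only probability unless masked
    upstream.
    """
    effort_km = np.asarray(effort_km, dtype=float)
    if np.any(effort_km < 0):
        raise ValueError("effort must be nonnegative")
    return inv_logit(alpha0 + alpha1 * effort_km)


@dataclass
class DetectionParams:
    """Per-group detection parameters shared across model components.

    All group vectors have equal length G (1 = no group structure, 2 = sex or
    behavioral status).  sigma is in meters and is shared across detection
    methods within a group; rates are per occasion and are multiplied by the
    fractional trap-operation matrix, never folded into sigma.
    """

    sigma: np.ndarray  # (G,) meters
    lambda0_resight: np.ndarray | None = None  # (G,) per occasion
    p0_marking: np.ndarray | None = None  # (G,) binomial marking probability
    lambda0_marking: np.ndarray | None = None  # (G,) Poisson marking rate
    alpha0: np.ndarray | None = None  # (G,) genetic logit intercept
    alpha1: float = 0.0  # effort slope (shared across groups)
    p0: np.ndarray | None = None  # (G,) presence-absence detection probability

    def __post_init__(self):
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        G = self.sigma.shape[0]
        for name in ("lambda0_resight", "p0_marking", "lambda0_marking", "alpha0", "p0"):
            v = getattr(self, name)
            if v is not None:
                v = np.atleast_1d(np.asarray(v, dtype=float))
                if v.shape[0] != G:
                    raise ValueError(f"{name} must have one entry per group")
                setattr(self, name, v)
        if self.p0 is not None and (np.any(self.p0 <= 0) or np.any(self.p0 >= 1)):
            raise ValueError("p0 must lie in (0, 1)")
        if self.p0_marking is not None and (
            np.any(self.p0_marking <= 0) or np.any(self.p0_marking >= 1)
        ):
            raise ValueError("p0_marking must lie in (0, 1)")
        for name in ("lambda0_resight", "lambda0_marking"):
            v = getattr(self, name)
            if v is not None and np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_groups(self) -> int:
        return self.sigma.shape[0]

    def genetic_p0(self, effort_km) -> np.ndarray:
        """(G, J) baseline genetic detection probability per group and cell."""
        if self.alpha0 is None:
            raise ValueError("genetic parameters (alpha0) not set")
        return effort_logit_p0(self.alpha0[:, None], self.alpha1, np.asarray(effort_km)[None, :])


def group_lookup(params: DetectionParams, group_index: int, which: str = "lambda0_resight"):
    """Return the (rate-or-probability, sigma) pair for one group.

    For augmented individuals whose group is latent, callers pass the
    currently sampled group label.  With a single group this reduces to the
    base model.
    """
    if not 0 <= group_index < params.n_groups:
        raise IndexError(f"group index {group_index} out of range")
    v = getattr(params, which)
    if v is None:
        raise ValueError(f"parameter {which!r} not set")
    return float(v[group_index]), float(params.sigma[group_index])
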