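"""Posterior summarization, model comparison and adequacy diagnostics.

Summaries follow the reporting conventions of the density-estimation
workflow: posterior mode (reported in text), mean, median, sd, 95% highest
posterior density interval (shortest interval containing 95% of draws), 95%
equal-tailed Bayesian credible interval, coefficient of variation
(posterior sd / posterior mean), and split-chain R-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class ParameterSummary:
    mode: float
    mean: float
    median: float
    sd: float
    hpdi95: tuple[float, float]
    bci95: tuple[float, float]
    cv: float
    rhat: float | None = None

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode, "mean": self.mean, "median": self.median, "sd": self.sd,
            "hpdi_lo": self.hpdi95[0], "hpdi_hi": self.hpdi95[1],
            "bci_lo": self.bci95[0], "bci_hi": self.bci95[1], "cv": self.cv,
        }
        if self.rhat is not None:
            d["rhat"] = self.rhat
        return d


def hpdi(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ceil(prob * n) of the sorted draws."""
    x = np.sort(np.asarray(draws).ravel())
    n = x.shape[0]
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def posterior_mode(draws: np.ndarray, discrete: bool = False) -> float:
    """Posterior mode estimator.

    Continuous parameters: Gaussian KDE (Scott plug-in bandwidth) maximized
    on a 512-point grid over the draw range.  Discrete parameters (N): the
    modal integer, ties broken toward the smaller value.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if discrete:
        vals, counts = np.unique(np.round(x).astype(np.int64), return_counts=True)
        return float(vals[np.argmax(counts)])  # first max = smallest on ties
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize(draws, parameter: str | None = None, discrete: bool = False) -> ParameterSummary:
    """Full summary of one parameter's posterior draws.

    ``draws`` may be a PosteriorDraws object (with ``parameter`` naming the
    quantity) or a plain array; chains are pooled.
    """
    rhat = None
    if parameter is not None and hasattr(draws, "get"):
        from .mcmc import gelman_rubin

        x = draws.get(parameter)
        if x.shape[1] >= 100:
            rhat = gelman_rubin(draws, parameter)
        x = x.ravel()
        if parameter == "N":
            discrete = True
    else:
        x = np.asarray(draws, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draws")
    if x.size < 100:
        raise ValueError("need >= 100 post-burn-in draws")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return ParameterSummary(
        mode=posterior_mode(x, discrete=discrete),
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        hpdi95=hpdi(x),
        bci95=(float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))),
        cv=sd / mean if mean != 0 else float("nan"),
        rhat=rhat,
    )


def density_summary(N_draws: np.ndarray, area_km2: float) -> ParameterSummary:
    """Summary of density D = N / A, scaled to animals per 100 km^2."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    D = np.asarray(N_draws, dtype=float) / area_km2 * 100.0
    return summarize(D.ravel())


def percent_difference(mode_a: float, mode_b: float) -> float:
    """100 * (mode_a - mode_b) / mode_b."""
    if mode_b == 0:
        raise ZeroDivisionError("reference mode must be nonzero")
    return 100.0 * (mode_a - mode_b) / mode_b


def augmentation_checks(
    draws, M: int, buffer_m: float | None = None, sigma_parameter: str = "sigma"
) -> list[str]:
    """Adequacy warnings for the data-augmentation and state-space setup.

    Flags: the posterior 97.5th percentile of N approaching the augmentation
    limit M; the 97.5th percentile of psi approaching 1; and a state-space
    buffer not exceeding 2.5 times the posterior median sigma.
    """
    warnings: list[str] = []
    N = np.asarray(draws.get("N") if hasattr(draws, "get") else draws["N"]).ravel()
    if np.percentile(N, 97.5) > 0.9 * M:
        warnings.append(
            f"augmentation limit: 97.5% of N ({np.percentile(N, 97.5):.0f}) exceeds 0.9*M ({0.9 * M:.0f}); increase M"
        )
    try:
        psi = np.asarray(draws.get("psi") if hasattr(draws, "get") else draws["psi"]).ravel()
        if np.percentile(psi, 97.5) > 0.9:
            warnings.append(
                f"inclusion probability: 97.5% of psi = {np.percentile(psi, 97.5):.3f} > 0.9; increase M"
            )
    except KeyError:
        pass
    if buffer_m is not None:
        sigs = []
        params = draws.params if hasattr(draws, "params") else draws
        for name in params:
            if name == sigma_parameter or name.startswith(sigma_parameter + "_"):
                sigs.append(float(np.median(np.asarray(params[name]).ravel())))
        for sig in sigs:
            if buffer_m <= 2.5 * sig:
                warnings.append(
                    f"state-space buffer {buffer_m:.0f} m is not > 2.5 * posterior median sigma ({sig:.0f} m)"
                )
    return warnings


def genetic_dataset_summary(attempted: int, succeeded: int, records=None) -> dict:
    """Genotyping-dataset bookkeeping.

    Success percent is rounded to the nearest integer (half away from zero).
    ``records`` may be a GeneticHistory or an iterable of (individual, cell)
    pairs; unique individuals and post-deduplication detections are counted
    from it.
    """
    if succeeded > attempted:
        raise ValueError("succeeded cannot exceed attempted")
    pct = 0 if attempted == 0 else int(math.floor(100.0 * succeeded / attempted + 0.5))
    out = {"attempted": attempted, "succeeded": succeeded, "success_pct": pct}
    if records is not None:
        if hasattr(records, "y"):
            out["unique_individuals"] = int((np.asarray(records.y).sum(axis=1) > 0).sum())
            out["detections"] = int((np.asarray(records.y) > 0).sum())
        else:
            pairs = {(str(a), str(b)) for a, b in records}
            out["unique_individuals"] = len({a for a, _ in pairs})
            out["detections"] = len(pairs)
    return out


def comparison_table(summaries: dict[str, ParameterSummary], reference: str) -> "pd.DataFrame":
    """Cross-model table of modes, percent differences from a reference, and CVs."""
    import pandas as pd

    ref_mode = summaries[reference].mode
    rows = []
    for name, s in summaries.items():
        rows.append(
            {
                "model": name,
                "mode": s.mode,
                "pct_diff_vs_" + reference: percent_difference(s.mode, ref_mode),
                "cv": s.cv,
                "bci_lo": s.bci95[0],
                "bci_hi": s.bci95[1],
            }
        )
    return pd.DataFrame(rows)
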