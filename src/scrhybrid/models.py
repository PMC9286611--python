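"""Log-likelihood and log-prior assembly for the SCR model family.

Variants
--------
``SC``            counts of unidentified animals (marginal Poisson)
``SPA``           binary detections of unidentified animals (Bernoulli per occasion)
``SMR``           identified resights of marked animals + marginal unmarked counts
``gSMR``          SMR + an SCR submodel for the physical marking process
``SCR``           binary genetic detections of fully identified individuals
``SCR+marking``   genetic SCR + marking process
``hybrid``        marking + camera resight/count + genetic SCR jointly

All variants share the latent structure of data augmentation: M pseudo-
individuals with inclusion indicators z_i ~ Bernoulli(psi), uniform activity
centers s_i over a rectangular state space, and half-normal detection kernels
governed by a spatial scale sigma shared across detection methods.  Telemetry
fixes enter any variant as bivariate-normal observations centered on s_i with
standard deviation sigma per axis and zero covariance.

Individuals are linked across streams by id string equality: an animal that
was live-trapped, genotyped and collared must carry the same id in the
marking history, the genetic history and the telemetry set.  Known
individuals not encountered by a given method contribute explicit all-zero
histories to that component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import logistic, norm

from .data import (
    AvailabilityMatrix,
    Detector,
    GeneticHistory,
    MarkedResightHistory,
    MarkingHistory,
    OperationMatrix,
    StateSpace,
    TelemetrySet,
    UnmarkedCountMatrix,
    detector_coords,
)
from .detection import DetectionParams, effort_logit_p0

VARIANTS = ("SC", "SPA", "SMR", "gSMR", "SCR", "SCR+marking", "hybrid")
GROUP_MODES = ("none", "sex", "status")

_NEGINF = -np.inf


@dataclass
class PriorSpec:
    """Prior hyperparameters (defaults follow the hybrid joint posterior).

    psi ~ Beta(1,1); sigma ~ Uniform(0, sigma_max); p0 ~ Beta(1,1);
    lambda0 ~ Uniform(0, lambda_max); s ~ Uniform(state space);
    alpha0 ~ Logistic(0,1) (equivalent to Beta(1,1) on its inverse-logit);
    alpha1 ~ Normal(0, alpha1_sd).
    """

    sigma_max: float = 20000.0
    lambda_max: float = 5.0
    alpha1_sd: float = 2.0

    def __post_init__(self):
        if self.sigma_max <= 0 or self.lambda_max <= 0 or self.alpha1_sd <= 0:
            raise ValueError("prior bounds must be positive and finite")


@dataclass
class ModelSpec:
    """Which variant to fit, with what augmentation size and priors."""

    variant: str
    M: int
    use_telemetry: bool = False
    group_mode: str = "none"
    marking_poisson: bool = False  # Poisson marking submodel instead of binomial
    effort_on_p0: bool = True  # logit-linear survey-effort covariate on genetic p0
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.group_mode not in GROUP_MODES:
            raise ValueError(f"unknown group mode {self.group_mode!r}")
        if self.M < 1:
            raise ValueError("augmentation size M must be >= 1")

    @property
    def n_groups(self) -> int:
        return 1 if self.group_mode == "none" else 2

    @property
    def needs(self) -> set[str]:
        return {
            "SC": {"counts"},
            "SPA": {"counts"},
            "SMR": {"resights", "counts"},
            "gSMR": {"resights", "counts", "marking"},
            "SCR": {"genetic"},
            "SCR+marking": {"genetic", "marking"},
            "hybrid": {"resights", "counts", "marking", "genetic"},
        }[self.variant]


@dataclass
class LatentState:
    """Augmented latent population state."""

    z: np.ndarray  # (M,) 0/1 inclusion
    s: np.ndarray  # (M, 2) activity centers, meters
    g: np.ndarray  # (M,) group labels in 0..G-1
    psi: float
    pi_group: float = 0.5

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=float)
        self.g = np.asarray(self.g, dtype=np.int64)

    @property
    def N(self) -> int:
        return int(self.z.sum())


@dataclass
class DataBundle:
    """All observed streams for one fit, linked by shared individual ids."""

    state_space: StateSpace
    cameras: list[Detector] | None = None
    resights: MarkedResightHistory | None = None
    counts: UnmarkedCountMatrix | None = None
    operation: OperationMatrix | None = None
    availability: AvailabilityMatrix | None = None
    traps: list[Detector] | None = None
    marking: MarkingHistory | None = None
    genetic: GeneticHistory | None = None
    telemetry: TelemetrySet | None = None
    groups: dict[str, int] | None = None  # observed labels (sex / status) by id

    def validate(self, spec: ModelSpec) -> None:
        present = {
            "counts": self.counts is not None,
            "resights": self.resights is not None,
            "marking": self.marking is not None and self.traps is not None,
            "genetic": self.genetic is not None,
        }
        missing = [k for k in spec.needs if not present[k]]
        if missing:
            raise ValueError(f"variant {spec.variant!r} missing required stream(s): {missing}")
        if spec.use_telemetry and self.telemetry is None:
            raise ValueError("use_telemetry=True but no telemetry stream supplied")
        if self.resights is not None and self.operation is not None:
            op = self.operation.values
            avail = (
                self.availability.values
                if self.availability is not None
                else np.ones((self.resights.y.shape[0], op.shape[1]), dtype=np.int8)
            )
            exposure = op[None, :, :] * avail[:, None, :]
            if np.any((self.resights.y > 0) & (exposure <= 0)):
                raise ValueError("positive resight count with zero effective exposure")
        if self.counts is not None and self.operation is not None:
            if np.any((self.counts.n > 0) & (self.operation.values <= 0)):
                raise ValueError("positive count at a detector-occasion with zero operation")


@dataclass
class Alignment:
    """Slot layout of known individuals inside the augmented vector.

    Slots 0..n_known-1 hold observed individuals (marked first, then
    genotype-only, then telemetry-only); the remainder are augmented
    pseudo-individuals with all-zero histories.
    """

    ids: list[str]
    n_marked: int
    z_fixed: np.ndarray  # (M,) bool
    marked_mask: np.ndarray  # (M,) bool; excluded from the marginal count sum
    genetic_slots: np.ndarray | None  # slot per genetic-history row
    marking_slots: np.ndarray | None
    resight_slots: np.ndarray | None
    telemetry_slots: dict[str, int]
    g_obs: np.ndarray  # (M,) observed group label, -1 if latent


def align_bundle(bundle: DataBundle, spec: ModelSpec) -> Alignment:
    """Assign augmented-vector slots to the individuals observed in each stream."""
    bundle.validate(spec)
    marked_ids: list[str] = []
    if spec.variant in ("SMR", "gSMR", "hybrid"):
        if bundle.marking is not None and spec.variant in ("gSMR", "hybrid"):
            marked_ids = list(bundle.marking.individual_ids)
        elif bundle.resights is not None:
            marked_ids = list(bundle.resights.individual_ids)
        if bundle.resights is not None:
            extra = [i for i in bundle.resights.individual_ids if i not in marked_ids]
            marked_ids += extra
    elif spec.variant == "SCR+marking" and bundle.marking is not None:
        marked_ids = list(bundle.marking.individual_ids)

    ids = list(marked_ids)
    if spec.variant in ("SCR", "SCR+marking", "hybrid") and bundle.genetic is not None:
        ids += [i for i in bundle.genetic.individual_ids if i not in ids]
    if spec.use_telemetry and bundle.telemetry is not None:
        ids += [i for i in bundle.telemetry.fixes if i not in ids]

    M = spec.M
    if M < len(ids):
        raise ValueError(f"M={M} smaller than the {len(ids)} known individuals")
    slot = {ind: i for i, ind in enumerate(ids)}

    z_fixed = np.zeros(M, dtype=bool)
    z_fixed[: len(ids)] = True
    marked_mask = np.zeros(M, dtype=bool)
    for ind in marked_ids:
        marked_mask[slot[ind]] = True

    def slots_of(idlist):
        return np.array([slot[i] for i in idlist], dtype=np.int64)

    genetic_slots = (
        slots_of(bundle.genetic.individual_ids)
        if (bundle.genetic is not None and "genetic" in spec.needs)
        else None
    )
    marking_slots = (
        slots_of(bundle.marking.individual_ids)
        if (bundle.marking is not None and "marking" in spec.needs)
        else None
    )
    resight_slots = (
        slots_of(bundle.resights.individual_ids)
        if (bundle.resights is not None and "resights" in spec.needs)
        else None
    )
    telemetry_slots = (
        {i: slot[i] for i in bundle.telemetry.fixes}
        if (spec.use_telemetry and bundle.telemetry is not None)
        else {}
    )

    g_obs = np.full(M, -1, dtype=np.int64)
    if spec.n_groups > 1 and bundle.groups:
        for ind, lab in bundle.groups.items():
            if ind in slot:
                g_obs[slot[ind]] = int(lab)
    elif spec.n_groups == 1:
        g_obs[:] = 0
    return Alignment(
        ids, len(marked_ids), z_fixed, marked_mask,
        genetic_slots, marking_slots, resight_slots, telemetry_slots, g_obs,
    )


# ---------------------------------------------------------------------------
# Likelihood components
# ---------------------------------------------------------------------------


def _kernel(s, xy, sigma_i):
    """(n_slots, J) half-normal kernel exp(-d^2 / 2 sigma_i^2)."""
    d2 = ((s[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma_i[:, None] ** 2))


def _xlogy(x, y):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x > 0, x * np.log(np.where(y > 0, y, 1.0)), 0.0)
    out = np.where((x > 0) & (y <= 0), _NEGINF, out)
    return out


def loglik_genetic_scr(
    state: LatentState,
    params: DetectionParams,
    genetic: GeneticHistory,
    slots: np.ndarray | None = None,
) -> float:
    """Binomial (Bernoulli when n_occasions=1) genetic-detection log-likelihood.

    Success probability per individual and survey cell is the logit-linear
    effort baseline times the half-normal kernel, gated by z_i.  Augmented
    individuals contribute their all-zero histories when included.
    """
    M = state.z.shape[0]
    n_rows = genetic.y.shape[0]
    if slots is None:
        slots = np.arange(n_rows)
    y = np.zeros((M, genetic.y.shape[1]), dtype=np.int64)
    y[slots] = genetic.y
    if np.any((y[state.z == 0].sum(axis=1)) > 0):
        return _NEGINF
    K = genetic.n_occasions
    sig = params.sigma[state.g]
    p0 = params.genetic_p0(genetic.effort)[state.g]  # (M, J)
    p = p0 * _kernel(state.s, genetic.cell_xy, sig)
    inc = state.z == 1
    yi, pi = y[inc], p[inc]
    ll = (
        _xlogy(yi, pi)
        + _xlogy(K - yi, 1.0 - pi)
        + gammaln(K + 1) - gammaln(yi + 1) - gammaln(K - yi + 1)
    )
    return float(ll.sum())


def loglik_marking(
    state: LatentState,
    params: DetectionParams,
    marking: MarkingHistory,
    traps: list[Detector],
    slots: np.ndarray | None = None,
    poisson: bool = False,
) -> float:
    """Marking-process (live capture) SCR log-likelihood.

    Binomial(K_marking, p0.marking * kernel) per individual x trap by
    default; the Poisson-rate form (lambda0.marking * kernel * K) is used
    when ``poisson=True``.  Augmented individuals contribute all-zero rows
    when included; z=0 individuals contribute nothing.
    """
    xy = detector_coords(traps)
    M = state.z.shape[0]
    if slots is None:
        slots = np.arange(marking.y.shape[0])
    y = np.zeros((M, len(traps)), dtype=np.int64)
    y[slots] = marking.y.sum(axis=2)
    if np.any((y[state.z == 0].sum(axis=1)) > 0):
        return _NEGINF
    K = marking.K_marking
    sig = params.sigma[state.g]
    kern = _kernel(state.s, xy, sig)
    inc = state.z == 1
    yi = y[inc]
    if poisson:
        lam = params.lambda0_marking[state.g][inc, None] * kern[inc] * K
        ll = _xlogy(yi, lam) - lam - gammaln(yi + 1)
    else:
        p = params.p0_marking[state.g][inc, None] * kern[inc]
        ll = (
            _xlogy(yi, p)
            + _xlogy(K - yi, 1.0 - p)
            + gammaln(K + 1) - gammaln(yi + 1) - gammaln(K - yi + 1)
        )
    return float(ll.sum())


def loglik_resight_marked(
    state: LatentState,
    params: DetectionParams,
    resights: MarkedResightHistory,
    cameras: list[Detector],
    operation: OperationMatrix,
    availability: AvailabilityMatrix | None = None,
    slots: np.ndarray | None = None,
) -> float:
    """Poisson resight log-likelihood for identified marked individuals.

    The per-occasion mean is lambda0.resight * kernel * operation * availability;
    occasions in which an animal was not collared or alive, or a camera was not
    functional, contribute nothing when the count is zero and raise when it is
    not (such data are impossible under the design).
    """
    xy = detector_coords(cameras)
    n_marked = resights.y.shape[0]
    if slots is None:
        slots = np.arange(n_marked)
    avail = (
        availability.values
        if availability is not None
        else np.ones((n_marked, operation.values.shape[1]), dtype=np.int8)
    )
    exposure = operation.values[None, :, :] * avail[:, None, :]  # (n_marked, J, K)
    if np.any((resights.y > 0) & (exposure <= 0)):
        raise ValueError("positive resight count with zero effective exposure")
    sig = params.sigma[state.g[slots]]
    lam0 = params.lambda0_resight[state.g[slots]]
    kern = _kernel(state.s[slots], xy, sig)  # (n_marked, J)
    mu = lam0[:, None, None] * kern[:, :, None] * exposure
    ll = _xlogy(resights.y, mu) - mu - gammaln(resights.y + 1)
    return float(ll.sum())


def loglik_unmarked_counts(
    state: LatentState,
    params: DetectionParams,
    counts: UnmarkedCountMatrix,
    cameras: list[Detector],
    operation: OperationMatrix,
    marked_mask: np.ndarray | None = None,
) -> float:
    """Marginal Poisson log-likelihood of unidentified counts.

    Counts at detector j, occasion k have mean
    operation[j,k] * sum_{i not marked} z_i * lambda0[g_i] * kernel(d_ij),
    the superposition of all included unmarked individuals' encounter rates.
    """
    xy = detector_coords(cameras)
    M = state.z.shape[0]
    pool = np.ones(M, dtype=bool) if marked_mask is None else ~np.asarray(marked_mask, bool)
    w = state.z.astype(float) * params.lambda0_resight[state.g] * pool
    kern = _kernel(state.s, xy, params.sigma[state.g])
    T = (w[:, None] * kern).sum(axis=0)  # (J,)
    mu = T[:, None] * operation.values
    ll = _xlogy(counts.n, mu) - mu - gammaln(counts.n + 1)
    return float(ll.sum())


def loglik_spa(
    state: LatentState,
    params: DetectionParams,
    detections: UnmarkedCountMatrix,
    cameras: list[Detector],
    operation: OperationMatrix,
) -> float:
    """Bernoulli presence-absence log-likelihood.

    P[j,k] = 1 - prod_i (1 - p_ij * op_jk * z_i), the probability at least one
    included individual is detected at detector j in occasion k.
    """
    if not np.isin(detections.n, (0, 1)).all():
        raise ValueError("presence-absence input must be binary")
    xy = detector_coords(cameras)
    p = params.p0[state.g][:, None] * _kernel(state.s, xy, params.sigma[state.g])
    pz = p * state.z[:, None]  # (M, J)
    with np.errstate(divide="ignore"):
        log1m = np.log1p(-pz[:, :, None] * operation.values[None, :, :])
    logQ = log1m.sum(axis=0)  # (J, K) log prob nobody detected
    P = -np.expm1(logQ)
    ll = _xlogy(detections.n, P) + (1 - detections.n) * logQ
    return float(ll.sum())


def loglik_telemetry(
    state: LatentState,
    params: DetectionParams,
    telemetry: TelemetrySet,
    slots: dict[str, int],
) -> float:
    """Bivariate-normal log-density of GPS fixes around activity centers.

    Fixes of individual i are iid Normal(s_i, sigma^2 I) with the same sigma
    as the detection kernel (group-specific where applicable); no truncation
    at the state-space boundary.
    """
    ll = 0.0
    for ind, xy in telemetry.fixes.items():
        i = slots[ind]
        sig2 = float(params.sigma[state.g[i]]) ** 2
        r2 = ((xy - state.s[i]) ** 2).sum()
        ll += -xy.shape[0] * np.log(2.0 * np.pi * sig2) - r2 / (2.0 * sig2)
    return float(ll)


# ---------------------------------------------------------------------------
# Priors and joint density
# ---------------------------------------------------------------------------


def log_prior(
    spec: ModelSpec, state: LatentState, params: DetectionParams, bundle: DataBundle
) -> float:
    """Log prior density of (z, psi, s, g, pi) and all detection parameters."""
    pr = spec.priors
    ss = bundle.state_space
    if not (0.0 < state.psi < 1.0):
        return _NEGINF
    if not np.all(ss.contains(state.s)):
        return _NEGINF
    lp = float(state.z.sum()) * np.log(state.psi) + float(
        (1 - state.z).sum()
    ) * np.log1p(-state.psi)
    # psi ~ Beta(1,1): density 1
    area_m2 = (ss.xmax - ss.xmin) * (ss.ymax - ss.ymin)
    lp += -state.s.shape[0] * np.log(area_m2)
    if np.any(params.sigma >= pr.sigma_max):
        return _NEGINF
    lp += -params.n_groups * np.log(pr.sigma_max)
    needs = spec.needs
    active_lams = []
    if ("counts" in needs and spec.variant != "SPA") or "resights" in needs:
        active_lams.append(params.lambda0_resight)
    if "marking" in needs and spec.marking_poisson:
        active_lams.append(params.lambda0_marking)
    for lam in active_lams:
        if lam is not None:
            if np.any(lam >= pr.lambda_max) or np.any(lam <= 0):
                return _NEGINF
            lp += -lam.shape[0] * np.log(pr.lambda_max)
    # p0, p0_marking ~ Beta(1,1): density 1 on (0,1)
    if "genetic" in needs and params.alpha0 is not None:
        lp += float(logistic.logpdf(params.alpha0).sum())
        if spec.effort_on_p0:
            lp += float(norm.logpdf(params.alpha1, scale=pr.alpha1_sd))
    if spec.n_groups > 1:
        if not (0.0 < state.pi_group < 1.0):
            return _NEGINF
        g = state.g
        lp += float(g.sum()) * np.log(state.pi_group) + float(
            (1 - g).sum()
        ) * np.log1p(-state.pi_group)
    return float(lp)


def log_joint(
    spec: ModelSpec,
    state: LatentState,
    params: DetectionParams,
    bundle: DataBundle,
    alignment: Alignment | None = None,
) -> float:
    """Joint log-density: the variant's likelihood components plus all priors."""
    aln = alignment if alignment is not None else align_bundle(bundle, spec)
    if np.any(state.z[aln.z_fixed] == 0):
        return _NEGINF
    lp = log_prior(spec, state, params, bundle)
    if not np.isfinite(lp):
        return lp
    ll = lp
    needs = spec.needs
    op = bundle.operation
    if op is None and (bundle.counts is not None or bundle.resights is not None):
        J = len(bundle.cameras)
        K = (bundle.counts.n.shape[1] if bundle.counts is not None else bundle.resights.y.shape[2])
        op = OperationMatrix.fully_operational([d.id for d in bundle.cameras], K)
    if "genetic" in needs:
        ll += loglik_genetic_scr(state, params, bundle.genetic, aln.genetic_slots)
    if "marking" in needs:
        ll += loglik_marking(
            state, params, bundle.marking, bundle.traps, aln.marking_slots,
            poisson=spec.marking_poisson,
        )
    if "resights" in needs:
        ll += loglik_resight_marked(
            state, params, bundle.resights, bundle.cameras, op,
            bundle.availability, aln.resight_slots,
        )
    if "counts" in needs:
        if spec.variant == "SPA":
            ll += loglik_spa(state, params, bundle.counts, bundle.cameras, op)
        else:
            ll += loglik_unmarked_counts(
                state, params, bundle.counts, bundle.cameras, op, aln.marked_mask
            )
    if spec.use_telemetry and bundle.telemetry is not None:
        ll += loglik_telemetry(state, params, bundle.telemetry, aln.telemetry_slots)
    return float(ll)
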