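"""Data-augmentation MCMC: chain management, initialization and diagnostics.

:func:`fit` runs independent Metropolis-within-Gibbs chains (the compiled
kernel in :mod:`scrhybrid._engine`) from dispersed initial states and returns
post-burn-in draws with split-chain Gelman-Rubin diagnostics.  The sampler is
fully reproducible under the config seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .data import OperationMatrix
from .detection import DetectionParams, inv_logit
from .models import Alignment, DataBundle, LatentState, ModelSpec, align_bundle, log_joint

logger = logging.getLogger(__name__)


@dataclass
class MCMCConfig:
    """Chain settings.  Defaults follow the reference workflow:
    3 chains of 50,000 iterations with the first 15,000 discarded."""

    n_chains: int = 3
    n_iter: int = 50000
    n_burn: int = 15000
    thin: int = 1
    seed: int = 0
    s_scale: float | None = None  # initial activity-center RW sd (m); None = auto

    def __post_init__(self):
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


@dataclass
class PosteriorDraws:
    """Post-burn-in posterior draws, one row-block per chain."""

    params: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    area_km2: float
    M: int
    n_known: int
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    accept_s: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    config: MCMCConfig | None = None
    final_states: list[dict] = field(default_factory=list)  # per-chain z, s, g, data ll

    def get(self, parameter: str) -> np.ndarray:
        return self.params[parameter]

    def flat(self, parameter: str) -> np.ndarray:
        return self.params[parameter].reshape(-1)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.params)

    def save(self, outdir) -> None:
        """Delimited-text draws per chain plus a JSON run manifest."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n_chains = next(iter(self.params.values())).shape[0]
        for c in range(n_chains):
            pd.DataFrame({k: v[c] for k, v in self.params.items()}).to_csv(
                outdir / f"chain{c + 1}.csv", index=False
            )
        manifest = {
            "area_km2": self.area_km2,
            "M": self.M,
            "n_known": self.n_known,
            "rhat": self.rhat,
            "converged": self.converged,
            "accept_s": self.accept_s,
            "seeds": self.seeds,
            "config": None
            if self.config is None
            else {k: getattr(self.config, k) for k in ("n_chains", "n_iter", "n_burn", "thin", "seed")},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def gelman_rubin(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    Each chain is split in half; R-hat = sqrt(((n-1)/n * W + B/n) / W) over
    the resulting 2C sequences.  Values >= 1.1 flag non-convergence.
    Constant chains (zero within-sequence variance) are reported as 1.0 with
    a degenerate-variance warning.
    """
    x = draws.get(parameter) if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    if x.shape[1] < 100:
        raise ValueError("need >= 100 post-burn-in draws per chain")
    half = x.shape[1] // 2
    seqs = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    n = seqs.shape[1]
    W = seqs.var(axis=1, ddof=1).mean()
    B = n * seqs.mean(axis=1).var(ddof=1)
    if W <= 0:
        warnings.warn("degenerate (constant) chains: R-hat undefined, reporting 1.0")
        return 1.0
    V = (n - 1) / n * W + B / n
    return float(np.sqrt(V / W))


# ---------------------------------------------------------------------------
# Packing and initialization
# ---------------------------------------------------------------------------


def _empty_f(n=0):
    return np.zeros(n, dtype=np.float64)


def _pack(spec: ModelSpec, bundle: DataBundle, aln: Alignment):
    """Convert the bundle into the flat arrays the compiled kernel consumes."""
    M, G = spec.M, spec.n_groups
    d: dict = {"M": M, "G": G}
    ss = bundle.state_space
    d.update(xmin=ss.xmin, xmax=ss.xmax, ymin=ss.ymin, ymax=ss.ymax)

    needs = spec.needs
    # genetic
    if "genetic" in needs:
        gen = bundle.genetic
        ygen = np.zeros((M, len(gen.cell_ids)), dtype=np.int64)
        ygen[aln.genetic_slots] = gen.y
        d.update(
            has_gen=True, gx=gen.cell_xy[:, 0].copy(), gy=gen.cell_xy[:, 1].copy(),
            geff=gen.effort.astype(np.float64), ygen=ygen, Kgen=int(gen.n_occasions),
        )
    else:
        d.update(has_gen=False, gx=_empty_f(), gy=_empty_f(), geff=_empty_f(),
                 ygen=np.zeros((M, 0), dtype=np.int64), Kgen=1)
    # marking
    if "marking" in needs:
        mk = bundle.marking
        txy = np.array([[t.x, t.y] for t in bundle.traps])
        ymark = np.zeros((M, len(bundle.traps)), dtype=np.int64)
        ymark[aln.marking_slots] = mk.y.sum(axis=2)
        d.update(has_mark=True, mx=txy[:, 0].copy(), my=txy[:, 1].copy(),
                 ymark=ymark, Kmark=int(mk.K_marking))
    else:
        d.update(has_mark=False, mx=_empty_f(), my=_empty_f(),
                 ymark=np.zeros((M, 0), dtype=np.int64), Kmark=1)

    # cameras / occasions
    if bundle.cameras is not None and ("counts" in needs or "resights" in needs):
        cxy = np.array([[c.x, c.y] for c in bundle.cameras])
        cx, cy = cxy[:, 0].copy(), cxy[:, 1].copy()
        if bundle.counts is not None:
            K = bundle.counts.n.shape[1]
        else:
            K = bundle.resights.y.shape[2]
        op = (
            bundle.operation.values
            if bundle.operation is not None
            else np.ones((len(bundle.cameras), K))
        )
    else:
        cx = cy = _empty_f()
        op = np.ones((0, 1))
        K = 1
    d.update(cx=cx, cy=cy)

    # resight
    if "resights" in needs:
        res = bundle.resights
        Yres = np.zeros((M, cx.shape[0]))
        Eres = np.zeros((M, cx.shape[0]))
        avail = (
            bundle.availability.values
            if bundle.availability is not None
            else np.ones((res.y.shape[0], K), dtype=np.int8)
        )
        Yres[aln.resight_slots] = res.y.sum(axis=2)
        Eres[aln.resight_slots] = (op[None, :, :] * avail[:, None, :]).sum(axis=2)
        res_mask = np.zeros(M, dtype=np.bool_)
        res_mask[aln.resight_slots] = True
        d.update(has_res=True, Yres=Yres, Eres=Eres, res_mask=res_mask)
    else:
        d.update(has_res=False, Yres=np.zeros((M, cx.shape[0])),
                 Eres=np.zeros((M, cx.shape[0])), res_mask=np.zeros(M, dtype=np.bool_))

    # counts / presence-absence
    if "counts" in needs and spec.variant != "SPA":
        d.update(has_cnt=True, has_spa=False,
                 ncnt=bundle.counts.n.sum(axis=1).astype(np.float64),
                 Opj=op.sum(axis=1).astype(np.float64),
                 yspa=np.zeros((0, 1), dtype=np.int64), opmat=np.ones((0, 1)))
    elif spec.variant == "SPA":
        yspa = bundle.counts.n
        if not np.isin(yspa, (0, 1)).all():
            raise ValueError("SPA requires binary detection input")
        d.update(has_cnt=False, has_spa=True, ncnt=_empty_f(cx.shape[0]),
                 Opj=_empty_f(cx.shape[0]),
                 yspa=yspa.astype(np.int64), opmat=op.astype(np.float64))
    else:
        d.update(has_cnt=False, has_spa=False, ncnt=_empty_f(), Opj=_empty_f(),
                 yspa=np.zeros((0, 1), dtype=np.int64), opmat=np.ones((0, 1)))

    # telemetry sufficient statistics
    tn = np.zeros(M)
    tsx = np.zeros(M)
    tsy = np.zeros(M)
    tss = np.zeros(M)
    if spec.use_telemetry and bundle.telemetry is not None:
        for ind, xy in bundle.telemetry.fixes.items():
            i = aln.telemetry_slots[ind]
            tn[i] = xy.shape[0]
            tsx[i] = xy[:, 0].sum()
            tsy[i] = xy[:, 1].sum()
            tss[i] = (xy**2).sum()
    d.update(has_tel=bool(spec.use_telemetry and bundle.telemetry is not None),
             tn=tn, tsx=tsx, tsy=tsy, tss=tss)

    d.update(
        in_pool=(~aln.marked_mask).astype(np.bool_),
        z_fixed=aln.z_fixed.astype(np.bool_),
        g_obs=aln.g_obs.astype(np.int64),
    )
    return d


def _detection_centroid(i, aln, bundle, spec, rng, ss):
    """Initial activity center: telemetry mean, else detection centroid, else uniform."""
    pts = []
    if spec.use_telemetry and bundle.telemetry is not None:
        ind = aln.ids[i] if i < len(aln.ids) else None
        if ind is not None and ind in bundle.telemetry.fixes:
            return bundle.telemetry.fixes[ind].mean(axis=0)
    if i < len(aln.ids):
        ind = aln.ids[i]
        if bundle.genetic is not None and "genetic" in spec.needs and ind in bundle.genetic.individual_ids:
            r = bundle.genetic.individual_ids.index(ind)
            hit = bundle.genetic.y[r] > 0
            pts += list(bundle.genetic.cell_xy[hit])
        if bundle.marking is not None and "marking" in spec.needs and ind in bundle.marking.individual_ids:
            r = bundle.marking.individual_ids.index(ind)
            hit = bundle.marking.y[r].sum(axis=1) > 0
            pts += [[t.x, t.y] for t, h in zip(bundle.traps, hit) if h]
        if bundle.resights is not None and "resights" in spec.needs and ind in bundle.resights.individual_ids:
            r = bundle.resights.individual_ids.index(ind)
            hit = bundle.resights.y[r].sum(axis=1) > 0
            pts += [[c.x, c.y] for c, h in zip(bundle.cameras, hit) if h]
    if pts:
        xy = np.mean(np.array(pts, dtype=float), axis=0)
    else:
        xy = np.array([rng.uniform(ss.xmin, ss.xmax), rng.uniform(ss.ymin, ss.ymax)])
    return np.clip(xy, [ss.xmin, ss.ymin], [ss.xmax, ss.ymax])


def _nn_spacing(bundle: DataBundle) -> float:
    for dets in (bundle.cameras, bundle.traps):
        if dets is not None and len(dets) >= 2:
            xy = np.array([[d.x, d.y] for d in dets])
            d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            return float(np.sqrt(d2.min(axis=1)).mean())
    if bundle.genetic is not None and len(bundle.genetic.cell_ids) >= 2:
        xy = bundle.genetic.cell_xy
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min(axis=1)).mean())
    return 1000.0


def _initial_state(spec, bundle, aln, rng, chain):
    """Dispersed, data-informed initial values for one chain."""
    ss = bundle.state_space
    M, G = spec.M, spec.n_groups
    z = np.where(aln.z_fixed, 1, rng.random(M) < 0.5).astype(np.int8)
    s = np.array([_detection_centroid(i, aln, bundle, spec, rng, ss) for i in range(M)])
    g = np.where(aln.g_obs >= 0, np.maximum(aln.g_obs, 0), rng.integers(0, G, M)).astype(np.int64)

    jit = lambda lo, hi: float(np.exp(rng.uniform(lo, hi)))
    base_sig = max(_nn_spacing(bundle), 1.0)
    sigma = np.full(G, np.clip(base_sig * jit(-0.4, 0.6), 1.0, 0.9 * spec.priors.sigma_max))
    if G > 1:
        sigma[1] = np.clip(sigma[1] * jit(-0.2, 0.8), 1.0, 0.9 * spec.priors.sigma_max)
    lamr = np.full(G, np.clip(0.3 * jit(-0.7, 0.7), 1e-3, 0.9 * spec.priors.lambda_max))
    markp0 = 0.3 if spec.marking_poisson else 0.15
    markp = np.full(G, np.clip(markp0 * jit(-0.7, 0.7), 1e-3,
                               0.9 * (spec.priors.lambda_max if spec.marking_poisson else 1.0)))
    a0 = np.full(G, np.log(0.15 / 0.85) + rng.normal(0, 0.4))
    a1 = 0.1 * float(rng.normal()) if (spec.effort_on_p0 and "genetic" in spec.needs) else 0.0
    p0spa = np.full(G, np.clip(0.2 * jit(-0.7, 0.7), 1e-3, 0.95))
    psi = float(np.clip(rng.uniform(0.3, 0.7), 0.05, 0.95))
    return z, s, g, psi, sigma, lamr, markp, a0, a1, p0spa, 0.5


def _params_from(spec, sigma, lamr, markp, a0, a1, p0spa):
    return DetectionParams(
        sigma=sigma,
        lambda0_resight=lamr if ("counts" in spec.needs or "resights" in spec.needs) else None,
        p0_marking=None if spec.marking_poisson else (markp if "marking" in spec.needs else None),
        lambda0_marking=markp if (spec.marking_poisson and "marking" in spec.needs) else None,
        alpha0=a0 if "genetic" in spec.needs else None,
        alpha1=a1,
        p0=p0spa if spec.variant == "SPA" else None,
    )


def fit(
    spec: ModelSpec,
    bundle: DataBundle,
    config: MCMCConfig,
    s_grid: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
    p0_grid: np.ndarray | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of the requested model variant.

    Each chain starts from its own dispersed, data-informed initial state
    (redrawn up to 100 times if the joint density is not finite) and runs the
    compiled kernel.  The optional grids switch the corresponding updates to
    independence proposals over a finite set of values, which makes the
    sampled model exactly enumerable for validation.
    """
    aln = align_bundle(bundle, spec)
    packed = _pack(spec, bundle, aln)
    G = spec.n_groups
    pr = spec.priors

    s_grid = np.zeros((0, 2)) if s_grid is None else np.asarray(s_grid, dtype=float)
    sigma_grid = _empty_f() if sigma_grid is None else np.asarray(sigma_grid, dtype=float)
    a0_grid = (
        _empty_f()
        if p0_grid is None
        else np.log(np.asarray(p0_grid, dtype=float) / (1.0 - np.asarray(p0_grid, dtype=float)))
    )

    needs = spec.needs
    upd_lamr = ("counts" in needs and spec.variant != "SPA") or "resights" in needs
    upd_mark = "marking" in needs
    upd_gen = "genetic" in needs
    upd_a1 = upd_gen and spec.effort_on_p0 and p0_grid is None
    upd_spa = spec.variant == "SPA"
    upd_g = G > 1

    n_kept = (config.n_iter - config.n_burn) // config.thin
    chains: list[np.ndarray] = []
    accept_s: list[float] = []
    final_states: list[dict] = []
    seeds: list[int] = []
    names = _param_names(spec)

    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c, 20405])
        ok = False
        for attempt in range(100):
            init = _initial_state(spec, bundle, aln, rng, c)
            z, s, g, psi, sigma, lamr, markp, a0, a1, p0spa, pi = init
            params = _params_from(spec, sigma, lamr, markp, a0, a1, p0spa)
            state = LatentState(z=z, s=s, g=g, psi=psi, pi_group=pi)
            lj = log_joint(spec, state, params, bundle, aln)
            if np.isfinite(lj):
                ok = True
                break
        if not ok:
            raise RuntimeError("non-finite initial log-joint after 100 re-draws")
        if p0_grid is not None:
            a0 = np.full(G, a0_grid[0])
        if sigma_grid.shape[0] > 0:
            sigma = np.full(G, sigma_grid[0])

        base_scale = config.s_scale if config.s_scale is not None else max(_nn_spacing(bundle), 50.0)
        s_scales = np.full(spec.M, float(base_scale))
        seed_c = int((config.seed * 1000003 + c * 7919 + 17) % (2**31 - 1))
        seeds.append(seed_c)
        out, rate, z_f, s_f, g_f, final_ll = _engine.run_chain(
            seed_c, config.n_iter, config.n_burn,
            spec.M, G,
            z.astype(np.int8).copy(), s.astype(np.float64).copy(), g.copy(),
            packed["z_fixed"], packed["g_obs"], packed["in_pool"], packed["res_mask"],
            packed["xmin"], packed["xmax"], packed["ymin"], packed["ymax"],
            packed["has_gen"], packed["gx"], packed["gy"], packed["geff"],
            packed["ygen"], packed["Kgen"],
            packed["has_mark"], spec.marking_poisson, packed["mx"], packed["my"],
            packed["ymark"], packed["Kmark"],
            packed["has_res"], packed["cx"], packed["cy"], packed["Yres"], packed["Eres"],
            packed["has_cnt"], packed["ncnt"], packed["Opj"],
            packed["has_spa"], packed["yspa"], packed["opmat"],
            packed["has_tel"], packed["tn"], packed["tsx"], packed["tsy"], packed["tss"],
            float(psi), sigma.astype(np.float64).copy(), lamr.astype(np.float64).copy(),
            markp.astype(np.float64).copy(), a0.astype(np.float64).copy(), float(a1),
            p0spa.astype(np.float64).copy(), 0.5,
            pr.sigma_max, pr.lambda_max, pr.alpha1_sd,
            upd_lamr, upd_mark, upd_gen, upd_a1, upd_spa, upd_g,
            s_grid, sigma_grid, a0_grid,
            s_scales,
            np.full(G, 0.15), np.full(G, 0.3), np.full(G, 0.4),
            np.full(G, 0.4), 0.3, np.full(G, 0.4),
        )
        chains.append(out[config.n_burn :: config.thin][:n_kept])
        accept_s.append(float(rate))
        final_states.append({"z": z_f, "s": s_f, "g": g_f, "data_ll": float(final_ll)})

    area = bundle.state_space.area_km2
    params_out: dict[str, np.ndarray] = {}
    for name, col in names.items():
        params_out[name] = np.stack([ch[:, col] for ch in chains])
    params_out["D"] = params_out["N"] / area

    draws = PosteriorDraws(
        params=params_out, area_km2=area, M=spec.M, n_known=len(aln.ids),
        accept_s=accept_s, seeds=seeds, config=config, final_states=final_states,
    )
    monitored = [n for n in params_out if n != "D"]
    draws.rhat = {n: gelman_rubin(draws, n) for n in monitored}
    bad = [n for n, r in draws.rhat.items() if r >= 1.1]
    draws.converged = not bad
    if bad:
        logger.warning("parameters failed R-hat < 1.1: %s", bad)
    return draws


def _param_names(spec: ModelSpec) -> dict[str, int]:
    """Map stored parameter names to engine draw-matrix columns."""
    G = spec.n_groups
    names: dict[str, int] = {"psi": 0}

    def grp(base, start):
        if G == 1:
            names[base] = start
        else:
            for gg in range(G):
                names[f"{base}_{gg}"] = start + gg

    grp("sigma", 1)
    needs = spec.needs
    if ("counts" in needs and spec.variant != "SPA") or "resights" in needs:
        grp("lambda0_resight", 1 + G)
    if "marking" in needs:
        grp("lambda0_marking" if spec.marking_poisson else "p0_marking", 1 + 2 * G)
    if "genetic" in needs:
        grp("alpha0", 1 + 3 * G)
        if spec.effort_on_p0:
            names["alpha1"] = 1 + 4 * G
    if spec.variant == "SPA":
        grp("p0", 2 + 4 * G)
    if G > 1:
        names["pi_group"] = 2 + 5 * G
    names["N"] = 3 + 5 * G
    return names


def extend_until_converged(
    spec: ModelSpec,
    bundle: DataBundle,
    config: MCMCConfig,
    max_extensions: int = 2,
) -> PosteriorDraws:
    """Refit with doubled chain length until all monitored R-hat < 1.1.

    Returns the first converged run, or the last run flagged
    ``converged=False`` once the extension budget is exhausted.  Deterministic
    under the config seed.
    """
    if max_extensions < 0:
        raise ValueError("max_extensions must be >= 0")
    draws = fit(spec, bundle, config)
    ext = 0
    while not draws.converged and ext < max_extensions:
        ext += 1
        config = replace(config, n_iter=config.n_iter * 2, n_burn=config.n_burn * 2)
        logger.info("extending run %d: n_iter=%d", ext, config.n_iter)
        draws = fit(spec, bundle, config)
    return draws
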