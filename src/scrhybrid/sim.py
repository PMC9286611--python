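"""Synthetic-data generator for all five observation streams.

The generative model matches the estimation model: activity centers uniform
over the state space (a homogeneous point process), half-normal detection
kernels, Poisson camera encounters, binomial live-trapping, Bernoulli
genetic detection with a logit-linear survey-effort covariate and
genotyping dropout applied per scat before deduplication, and bivariate
normal GPS fixes centered on activity centers.

The default scenario emulates the carnivore study design at validation
scale: a 1-km camera grid inside a much larger state space, a marking-trap
grid, 1-km scat survey cells with recorded search effort, ten 14-day camera
occasions and one scat survey pass, and 100 GPS fixes per collared animal.
Behavioral heterogeneity (e.g., transient animals with home ranges an order
of magnitude larger than residents) is expressed as a second group with its
own sigma and detection parameters; activity centers do not drift.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

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
)
from .detection import inv_logit
from .models import DataBundle


@dataclass
class SimulationScenario:
    """Generating conditions for one synthetic data set."""

    N: int = 60
    state_space: StateSpace = field(default_factory=lambda: StateSpace(0.0, 20000.0, 0.0, 20000.0))
    group_props: tuple = (1.0,)
    sigma: tuple = (1500.0,)
    lambda0_resight: tuple = (0.3,)
    p0_marking: tuple = (0.2,)
    camera_nx: int = 8
    camera_ny: int = 8
    camera_spacing: float = 1000.0
    n_occasions: int = 10
    occasion_days: float = 14.0
    trap_nx: int = 5
    trap_ny: int = 5
    trap_spacing: float = 1000.0
    K_marking: int = 5
    cell_nx: int = 10
    cell_ny: int = 10
    cell_m: float = 1000.0
    effort_range: tuple = (1.5, 2.0)
    alpha0: tuple = (-2.0,)
    alpha1: float = 0.5
    genotyping_success: float = 0.9
    n_fixes: int = 100
    start_date: str = "2017-04-15"
    species: str = "coyote"

    @property
    def n_groups(self) -> int:
        return len(self.group_props)

    @property
    def density_per_100km2(self) -> float:
        return self.N / self.state_space.area_km2 * 100.0


def reference_scenario() -> SimulationScenario:
    """Hybrid validation scenario: N=60 in a 400-km^2 state space, sigma=1500 m,
    lambda0.resight=0.3, an 8x8 1-km camera grid, 10 occasions, a 25-trap
    marking grid with K=5, a 10x10 grid of 1-km scat cells with effort, and
    100 GPS fixes per marked individual."""
    return SimulationScenario()


def study_scenario() -> SimulationScenario:
    """Scenario mirroring the field design more closely: ~224 km^2 surveyed
    area with a 1-km camera grid, 4-km^2 scat cells searched 6-8 km each, and
    a transient group with a home-range scale an order of magnitude larger
    than residents (sigma multiplier ~12)."""
    return SimulationScenario(
        N=80,
        state_space=StateSpace(0.0, 26000.0, 0.0, 26000.0),
        group_props=(0.8, 0.2),
        sigma=(1200.0, 14400.0),
        lambda0_resight=(0.3, 0.3),
        p0_marking=(0.2, 0.2),
        camera_nx=10,
        camera_ny=9,
        cell_nx=7,
        cell_ny=8,
        cell_m=2000.0,
        effort_range=(6.0, 8.0),
        alpha0=(-2.0, -2.0),
    )


@dataclass
class TruthRecord:
    """Generating parameters and realized latent state, for recovery scoring."""

    scenario: dict
    N: int
    density_per_100km2: float
    centers: np.ndarray
    groups: np.ndarray
    ids: list[str]
    marked_ids: list[str]
    genotyped_ids: list[str]

    def to_json(self) -> str:
        d = dict(
            scenario={k: v for k, v in self.scenario.items() if k != "state_space"},
            state_space=[
                self.scenario["state_space"].xmin, self.scenario["state_space"].xmax,
                self.scenario["state_space"].ymin, self.scenario["state_space"].ymax,
            ]
            if hasattr(self.scenario.get("state_space"), "xmin")
            else self.scenario.get("state_space"),
            N=self.N,
            density_per_100km2=self.density_per_100km2,
            centers=self.centers.tolist(),
            groups=self.groups.tolist(),
            ids=self.ids,
            marked_ids=self.marked_ids,
            genotyped_ids=self.genotyped_ids,
        )
        return json.dumps(d, indent=2)


def _grid(nx, ny, spacing, ss: StateSpace, kind, prefix) -> list[Detector]:
    """Detector grid centered in the state space."""
    cx = (ss.xmin + ss.xmax) / 2.0
    cy = (ss.ymin + ss.ymax) / 2.0
    xs = cx + (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = cy + (np.arange(ny) - (ny - 1) / 2.0) * spacing
    out = []
    k = 0
    for y in ys:
        for x in xs:
            k += 1
            out.append(Detector(f"{prefix}{k:03d}", float(x), float(y), kind))
    return out


def camera_grid(sc: SimulationScenario) -> list[Detector]:
    return _grid(sc.camera_nx, sc.camera_ny, sc.camera_spacing, sc.state_space, "camera", "cam")


def trap_grid(sc: SimulationScenario) -> list[Detector]:
    return _grid(sc.trap_nx, sc.trap_ny, sc.trap_spacing, sc.state_space, "live_trap", "trap")


def scat_cells(sc: SimulationScenario) -> list[Detector]:
    return _grid(sc.cell_nx, sc.cell_ny, sc.cell_m, sc.state_space, "scat_cell", "cell")


def _kernel(centers, groups, xy, sigma):
    sig = np.asarray(sigma, dtype=float)[np.asarray(groups)]
    d2 = ((centers[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sig[:, None] ** 2))


def simulate_population(sc: SimulationScenario, seed=None):
    """N activity centers uniform over the state space, with group labels."""
    rng = np.random.default_rng(seed)
    ss = sc.state_space
    centers = np.column_stack(
        [rng.uniform(ss.xmin, ss.xmax, sc.N), rng.uniform(ss.ymin, ss.ymax, sc.N)]
    )
    groups = rng.choice(sc.n_groups, size=sc.N, p=np.asarray(sc.group_props))
    return centers, groups


def simulate_marking(centers, groups, traps, p0_marking, sigma, K_marking, seed=None):
    """Binomial(K, p0.marking * kernel) captures; >=1 capture => marked."""
    rng = np.random.default_rng(seed)
    xy = np.array([[t.x, t.y] for t in traps])
    p = np.asarray(p0_marking, dtype=float)[np.asarray(groups)][:, None] * _kernel(
        centers, groups, xy, sigma
    )
    y3 = rng.binomial(1, p[:, :, None], size=(centers.shape[0], xy.shape[0], K_marking))
    marked_idx = np.where(y3.sum(axis=(1, 2)) > 0)[0]
    return y3, marked_idx


def simulate_camera(
    centers, groups, marked_idx, cameras, lambda0, sigma, operation: np.ndarray, seed=None
):
    """Poisson counts with mean lambda0 * kernel * operation.

    Marked individuals' counts keep identity; unmarked counts are summed per
    detector x occasion.
    """
    rng = np.random.default_rng(seed)
    xy = np.array([[c.x, c.y] for c in cameras])
    lam0 = np.asarray(lambda0, dtype=float)[np.asarray(groups)]
    mu = lam0[:, None, None] * _kernel(centers, groups, xy, sigma)[:, :, None] * operation[None, :, :]
    y = rng.poisson(mu)
    marked_mask = np.zeros(centers.shape[0], dtype=bool)
    marked_mask[marked_idx] = True
    y_marked = y[marked_idx]
    n_unmarked = y[~marked_mask].sum(axis=0)
    return y_marked, n_unmarked


def simulate_genetic(
    centers, groups, cells, effort, alpha0, alpha1, sigma, genotyping_success, seed=None
):
    """Bernoulli detection per individual x cell, thinned by genotyping dropout.

    Detection probability is the logit-linear effort baseline times the
    half-normal kernel; dropout is applied per scat before deduplication
    (one scat per detected individual-cell pair under the binary model).
    """
    rng = np.random.default_rng(seed)
    xy = np.array([[c.x, c.y] for c in cells])
    a0 = np.asarray(alpha0, dtype=float)[np.asarray(groups)]
    base = inv_logit(a0[:, None] + alpha1 * np.asarray(effort)[None, :])
    p = base * _kernel(centers, groups, xy, sigma)
    y = rng.binomial(1, p)
    keep = rng.random(y.shape) < genotyping_success
    return (y * keep).astype(np.int64)


def simulate_telemetry(centers, groups, marked_idx, ids, sigma, n_fixes, seed=None):
    """n_fixes iid bivariate-normal fixes per marked individual (sd sigma per axis)."""
    if n_fixes < 1:
        raise ValueError("n_fixes must be >= 1")
    rng = np.random.default_rng(seed)
    sig = np.asarray(sigma, dtype=float)
    fixes = {}
    for i in marked_idx:
        s = sig[groups[i]]
        fixes[ids[i]] = centers[i] + rng.normal(0.0, s, size=(n_fixes, 2))
    return TelemetrySet(fixes)


def simulate(sc: SimulationScenario, seed: int = 0) -> tuple[DataBundle, TruthRecord]:
    """Generate one complete data set as a model-ready bundle plus its truth."""
    root = np.random.SeedSequence([int(seed), 20405])
    seeds = root.spawn(5)
    centers, groups = simulate_population(sc, seeds[0])
    ids = [f"ind{i + 1:03d}" for i in range(sc.N)]

    traps = trap_grid(sc)
    y_mark3, marked_idx = simulate_marking(
        centers, groups, traps, sc.p0_marking, sc.sigma, sc.K_marking, seeds[1]
    )
    marked_ids = [ids[i] for i in marked_idx]
    marking = MarkingHistory(marked_ids, [t.id for t in traps], y_mark3[marked_idx])

    cameras = camera_grid(sc)
    operation = np.ones((len(cameras), sc.n_occasions))
    y_res, n_unm = simulate_camera(
        centers, groups, marked_idx, cameras, sc.lambda0_resight, sc.sigma, operation, seeds[2]
    )
    resights = MarkedResightHistory(marked_ids, [c.id for c in cameras], y_res)
    counts = UnmarkedCountMatrix([c.id for c in cameras], n_unm)

    cells = scat_cells(sc)
    rng_e = np.random.default_rng(seeds[3])
    effort = rng_e.uniform(sc.effort_range[0], sc.effort_range[1], len(cells))
    y_gen = simulate_genetic(
        centers, groups, cells, effort, sc.alpha0, sc.alpha1, sc.sigma,
        sc.genotyping_success, seeds[3],
    )
    detected = np.where(y_gen.sum(axis=1) > 0)[0]
    genetic = GeneticHistory(
        [ids[i] for i in detected],
        [c.id for c in cells],
        np.array([[c.x, c.y] for c in cells]),
        effort,
        y_gen[detected],
    )

    telemetry = simulate_telemetry(centers, groups, marked_idx, ids, sc.sigma, sc.n_fixes, seeds[4])

    bundle = DataBundle(
        state_space=sc.state_space,
        cameras=cameras,
        resights=resights,
        counts=counts,
        operation=OperationMatrix([c.id for c in cameras], operation),
        availability=AvailabilityMatrix.always_available(marked_ids, sc.n_occasions),
        traps=traps,
        marking=marking,
        genetic=genetic,
        telemetry=telemetry,
        groups={ids[i]: int(groups[i]) for i in marked_idx} if sc.n_groups > 1 else None,
    )
    truth = TruthRecord(
        scenario=asdict(sc) | {"state_space": sc.state_space},
        N=sc.N,
        density_per_100km2=sc.density_per_100km2,
        centers=centers,
        groups=groups,
        ids=ids,
        marked_ids=marked_ids,
        genotyped_ids=[ids[i] for i in detected],
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Event-level tables (CSV schemas consumed by scrhybrid.data)
# ---------------------------------------------------------------------------


def simulate_tables(sc: SimulationScenario, seed: int = 0):
    """Generate the five delimited-text streams plus the truth record.

    Event-level camera and scat tables are constructed so that the
    preprocessing pipeline (independent sequences, occasion binning, cell
    aggregation) reproduces the same model inputs as :func:`simulate` —
    events at one station are spaced more than the 30-minute independence
    window apart.
    """
    bundle, truth = simulate(sc, seed)
    rng = np.random.default_rng([int(seed), 7, 20405])
    start = pd.Timestamp(sc.start_date)

    det_rows = []
    for d in bundle.cameras + bundle.traps:
        det_rows.append({"id": d.id, "x": d.x, "y": d.y, "kind": d.kind})
    for c, eff in zip(scat_cells(sc), bundle.genetic.effort):
        det_rows.append({"id": c.id, "x": c.x, "y": c.y, "kind": c.kind})
    detectors = pd.DataFrame(det_rows)

    # camera events: one row per detection, >=1 h apart within a station
    ev_rows = []
    slot = {}  # station -> next hour slot per occasion
    occ_hours = int(sc.occasion_days * 24)

    def add_event(j, k, mark_id):
        key = (j, k)
        h = slot.get(key, 0)
        slot[key] = h + 1
        t = start + pd.Timedelta(days=k * sc.occasion_days) + pd.Timedelta(hours=min(h, occ_hours - 1))
        ev_rows.append(
            {"timestamp": t.isoformat(), "station": bundle.cameras[j].id,
             "species": sc.species, "mark_id": mark_id}
        )

    y = bundle.resights.y
    for i in range(y.shape[0]):
        for j in range(y.shape[1]):
            for k in range(y.shape[2]):
                for _ in range(y[i, j, k]):
                    add_event(j, k, bundle.resights.individual_ids[i])
    n = bundle.counts.n
    for j in range(n.shape[0]):
        for k in range(n.shape[1]):
            for _ in range(n[j, k]):
                add_event(j, k, None)
    events = pd.DataFrame(ev_rows, columns=["timestamp", "station", "species", "mark_id"])

    # scats: one point uniform inside the detected cell
    scat_rows = []
    gen = bundle.genetic
    half = sc.cell_m / 2.0
    for r, ind in enumerate(gen.individual_ids):
        for j in np.where(gen.y[r] > 0)[0]:
            scat_rows.append(
                {"x": gen.cell_xy[j, 0] + rng.uniform(-half, half),
                 "y": gen.cell_xy[j, 1] + rng.uniform(-half, half),
                 "genotype_id": ind}
            )
    scats = pd.DataFrame(scat_rows, columns=["x", "y", "genotype_id"])
    effort = pd.DataFrame(
        {"cell_id": gen.cell_ids, "x": gen.cell_xy[:, 0], "y": gen.cell_xy[:, 1],
         "km_walked": gen.effort}
    )

    cap_rows = []
    mk = bundle.marking
    for r, ind in enumerate(mk.individual_ids):
        for j in range(mk.y.shape[1]):
            for k in range(mk.y.shape[2]):
                if mk.y[r, j, k]:
                    cap_rows.append({"individual": ind, "trap_id": mk.trap_ids[j], "occasion": k + 1})
    captures = pd.DataFrame(cap_rows, columns=["individual", "trap_id", "occasion"])

    gps_rows = []
    for ind, xy in bundle.telemetry.fixes.items():
        for l, (x_, y_) in enumerate(xy):
            t = start + pd.Timedelta(hours=2 * l)
            gps_rows.append({"individual": ind, "x": x_, "y": y_, "timestamp": t.isoformat()})
    gps = pd.DataFrame(gps_rows, columns=["individual", "x", "y", "timestamp"])

    tables = {
        "detectors": detectors, "events": events, "scats": scats,
        "effort": effort, "captures": captures, "gps": gps,
    }
    return tables, bundle, truth
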