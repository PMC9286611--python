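"""Domain types and preprocessing for spatially referenced encounter data.

Raw field data arrive as event tables (camera photo sequences, genotyped
scats, live-trap captures, GPS fixes) plus detector coordinates.  This module
converts them into the model-ready encounter structures used by
:mod:`scrhybrid.models`:

* photo events -> independent sequences -> marked resight histories and
  unmarked count matrices binned into sampling occasions;
* genotyped scat locations -> single-occasion binary detection histories on a
  grid of survey cells, with within-cell duplicates of the same individual
  collapsed to one detection;
* GPS fixes -> per-individual telemetry sets subsampled to a fixed number of
  locations.

All coordinates are planar metric (meters).  Geographic-to-planar projection
is the caller's responsibility; Euclidean distances are computed directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTOR_KINDS = ("camera", "scat_cell", "live_trap")


@dataclass(frozen=True)
class Detector:
    """A single detection device or survey cell.

    Parameters
    ----------
    id : str
        Unique token within an array.
    x, y : float
        Planar coordinates in meters.
    kind : str
        One of ``camera``, ``scat_cell`` or ``live_trap``.
    """

    id: str
    x: float
    y: float
    kind: str = "camera"

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"detector {self.id!r}: coordinates must be finite")
        if self.kind not in DETECTOR_KINDS:
            raise ValueError(f"detector {self.id!r}: unknown kind {self.kind!r}")


def detector_coords(detectors: list[Detector]) -> np.ndarray:
    """(J, 2) array of detector coordinates."""
    ids = [d.id for d in detectors]
    if len(set(ids)) != len(ids):
        raise ValueError("detector ids must be unique within an array")
    return np.array([[d.x, d.y] for d in detectors], dtype=float).reshape(len(detectors), 2)


@dataclass(frozen=True)
class StateSpace:
    """Rectangular region over which activity centers are uniformly distributed."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self):
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("state space must have positive extent")

    @property
    def area_km2(self) -> float:
        """Area in square kilometers: (xmax-xmin)*(ymax-ymin)/1e6."""
        return (self.xmax - self.xmin) * (self.ymax - self.ymin) / 1e6

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )


def build_state_space(detectors: list[Detector], buffer_m: float) -> StateSpace:
    """Bounding box of the detector array expanded by ``buffer_m`` on all sides.

    The buffer must be generous relative to the detection scale sigma (the
    adequacy rule of thumb is buffer > 2.5 sigma, checked post hoc by
    :func:`scrhybrid.summary.augmentation_checks`).
    """
    if not detectors:
        raise ValueError("cannot build a state space from an empty detector list")
    if buffer_m < 0:
        raise ValueError("buffer_m must be >= 0")
    xy = detector_coords(detectors)
    return StateSpace(
        xmin=float(xy[:, 0].min() - buffer_m),
        xmax=float(xy[:, 0].max() + buffer_m),
        ymin=float(xy[:, 1].min() - buffer_m),
        ymax=float(xy[:, 1].max() + buffer_m),
    )


@dataclass
class OperationMatrix:
    """Fraction of each occasion that each detector was functional, in [0, 1]."""

    detector_ids: list[str]
    values: np.ndarray  # (J, K)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.detector_ids):
            raise ValueError("operation matrix must be (n_detectors, n_occasions)")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("operation fractions must lie in [0, 1]")

    @classmethod
    def fully_operational(cls, detector_ids: list[str], n_occasions: int) -> "OperationMatrix":
        return cls(list(detector_ids), np.ones((len(detector_ids), n_occasions)))


@dataclass
class AvailabilityMatrix:
    """0/1 indicator that each marked individual was collared and alive per occasion."""

    individual_ids: list[str]
    values: np.ndarray  # (n_marked, K)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("availability must be binary")
        self.values = self.values.astype(np.int8)
        if self.values.shape[0] != len(self.individual_ids):
            raise ValueError("one availability row per marked individual")

    @classmethod
    def always_available(cls, individual_ids: list[str], n_occasions: int) -> "AvailabilityMatrix":
        return cls(list(individual_ids), np.ones((len(individual_ids), n_occasions), dtype=np.int8))


@dataclass
class MarkedResightHistory:
    """Counts of each marked individual at each camera in each occasion."""

    individual_ids: list[str]
    detector_ids: list[str]
    y: np.ndarray  # (n_marked, J, K) nonnegative int

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        if np.any(self.y < 0):
            raise ValueError("resight counts must be nonnegative")
        if self.y.shape[:2] != (len(self.individual_ids), len(self.detector_ids)):
            raise ValueError("resight history shape mismatch")


@dataclass
class UnmarkedCountMatrix:
    """Counts of unmarked (or identity-ignored) detections per detector x occasion."""

    detector_ids: list[str]
    n: np.ndarray  # (J, K)

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        if np.any(self.n < 0):
            raise ValueError("counts must be nonnegative")
        if self.n.shape[0] != len(self.detector_ids):
            raise ValueError("count matrix shape mismatch")

    def to_binary(self) -> "UnmarkedCountMatrix":
        """Collapse counts to detection/nondetection (spatial presence-absence input)."""
        return UnmarkedCountMatrix(list(self.detector_ids), (self.n > 0).astype(np.int64))


@dataclass
class GeneticHistory:
    """Detections of genotyped individuals in scat survey cells.

    The field design is a single survey pass per cell (``n_occasions=1``) with
    binary detections after same-cell deduplication; the generic binomial form
    with more occasions is supported for model validation.
    """

    individual_ids: list[str]
    cell_ids: list[str]
    cell_xy: np.ndarray  # (J, 2) cell centers, meters
    effort: np.ndarray  # (J,) km walked per cell
    y: np.ndarray  # (n_ind, J) counts in 0..n_occasions
    n_occasions: int = 1

    def __post_init__(self):
        self.cell_xy = np.asarray(self.cell_xy, dtype=float)
        self.effort = np.asarray(self.effort, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.shape != (len(self.individual_ids), len(self.cell_ids)):
            raise ValueError("genetic history shape mismatch")
        if np.any(self.y < 0) or np.any(self.y > self.n_occasions):
            raise ValueError("genetic detections must lie in 0..n_occasions")


@dataclass
class MarkingHistory:
    """Live-capture (marking process) encounter history; defines the marked set."""

    individual_ids: list[str]
    trap_ids: list[str]
    y: np.ndarray  # (n_marked, J, K_marking) 0/1 capture indicators
    K_marking: int = field(init=False)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        if np.any(self.y < 0):
            raise ValueError("capture indicators must be nonnegative")
        if self.y.shape[:2] != (len(self.individual_ids), len(self.trap_ids)):
            raise ValueError("marking history shape mismatch")
        self.K_marking = self.y.shape[2]


@dataclass
class TelemetrySet:
    """GPS fixes per marked individual (subsampled to at most n_max per animal)."""

    fixes: dict[str, np.ndarray]  # id -> (n_i, 2) meters

    def __post_init__(self):
        self.fixes = {k: np.asarray(v, dtype=float).reshape(-1, 2) for k, v in self.fixes.items()}

    def n_fixes(self) -> dict[str, int]:
        return {k: v.shape[0] for k, v in self.fixes.items()}


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def independent_sequences(events: pd.DataFrame, window_minutes: float = 30.0) -> pd.DataFrame:
    """Collapse photo events into independent photo sequences.

    Within each station x species stream, consecutive events no more than
    ``window_minutes`` apart are chained into a single sequence, timestamped
    at the first event of the chain.  A photo more than the window after the
    previous same-species detection at that station starts a new sequence.

    Parameters
    ----------
    events : DataFrame
        Columns ``timestamp`` (ISO-8601 or datetime), ``station``, ``species``
        and optionally ``mark_id`` (NA for unmarked animals).

    Returns
    -------
    DataFrame with the same columns, one row per independent sequence,
    preserving chronological order within streams.
    """
    if events.empty:
        return events.copy()
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    if ev["timestamp"].isna().any():
        raise ValueError("unparseable timestamps in events table")
    ev = ev.sort_values(["station", "species", "timestamp"], kind="stable")
    gap = ev.groupby(["station", "species"], sort=False)["timestamp"].diff()
    new_seq = gap.isna() | (gap > pd.Timedelta(minutes=window_minutes))
    keep = ev[new_seq].reset_index(drop=True)
    return keep


def bin_occasions(
    sequences: pd.DataFrame,
    start_date,
    occasion_days: float,
    n_occasions: int,
    marks: dict[str, str] | None,
    availability: AvailabilityMatrix | None,
    detector_ids: list[str],
    unavailable_to_unmarked: bool = False,
) -> tuple[MarkedResightHistory, UnmarkedCountMatrix]:
    """Bin independent sequences into sampling occasions.

    Occasions are half-open intervals [start + k*d, start + (k+1)*d); an event
    exactly on a boundary belongs to the later occasion.  Sequences with a
    resolvable mark id increment the marked resight history; all others
    increment the unmarked count matrix.  Sequences outside the sampling
    window are dropped with a logged count.  A marked individual's detections
    during occasions in which it was unavailable (not yet collared, or dead)
    are discarded by default; with ``unavailable_to_unmarked=True`` they are
    added to the unmarked count matrix instead (the animal carried no legible
    mark at the time).

    Parameters
    ----------
    marks : dict
        Map from mark-id tokens appearing in the events to individual ids.
        ``None`` treats every sequence as unmarked (spatial count input).
    """
    if occasion_days <= 0:
        raise ValueError("occasion_days must be positive")
    marks = marks or {}
    marked_ids = list(availability.individual_ids) if availability is not None else sorted(set(marks.values()))
    row_of = {ind: i for i, ind in enumerate(marked_ids)}
    col_of = {d: j for j, d in enumerate(detector_ids)}
    J = len(detector_ids)
    y = np.zeros((len(marked_ids), J, n_occasions), dtype=np.int64)
    n = np.zeros((J, n_occasions), dtype=np.int64)

    start = pd.Timestamp(start_date)
    dropped = 0
    for _, row in sequences.iterrows():
        t = pd.Timestamp(row["timestamp"])
        k = int(np.floor((t - start) / pd.Timedelta(days=occasion_days)))
        if k < 0 or k >= n_occasions:
            dropped += 1
            continue
        if row["station"] not in col_of:
            dropped += 1
            continue
        j = col_of[row["station"]]
        mark = row.get("mark_id")
        if mark is not None and not pd.isna(mark):
            if mark not in marks:
                raise KeyError(f"mark id {mark!r} present in events but absent from mark map")
            ind = marks[mark]
            i = row_of[ind]
            if availability is not None and availability.values[i, k] == 0:
                if unavailable_to_unmarked:
                    n[j, k] += 1
                else:
                    dropped += 1  # pre-collaring or post-mortality detection
                continue
            y[i, j, k] += 1
        else:
            n[j, k] += 1
    if dropped:
        logger.info("bin_occasions: dropped %d sequences outside window/availability", dropped)
    return (
        MarkedResightHistory(marked_ids, list(detector_ids), y),
        UnmarkedCountMatrix(list(detector_ids), n),
    )


def aggregate_genetic(
    scats: pd.DataFrame,
    effort: pd.DataFrame,
    cell_m: float = 1000.0,
    grid_origin: tuple[float, float] | None = None,
) -> GeneticHistory:
    """Aggregate genotyped scats onto survey grid cells.

    Scat locations are attributed to the center of the ``cell_m`` x ``cell_m``
    grid cell containing them; duplicate (individual, cell) pairs collapse to
    a single detection, which enforces independence of samples where animals
    scent-mark repeatedly in one place.  Scats falling in cells without survey
    effort are logged and dropped.

    Parameters
    ----------
    scats : DataFrame with columns ``x``, ``y``, ``genotype_id``.
    effort : DataFrame with columns ``cell_id``, ``x``, ``y``, ``km_walked``
        (cell centers and distance surveyed).
    grid_origin : optional (x0, y0)
        Lower-left corner of the cell grid; defaults to the effort-cell
        centers' implied origin (center minus half a cell).
    """
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    if scats["genotype_id"].isna().any():
        raise ValueError("genotype ids must be non-null")
    cell_ids = [str(c) for c in effort["cell_id"]]
    cell_xy = effort[["x", "y"]].to_numpy(dtype=float)
    km = effort["km_walked"].to_numpy(dtype=float)
    if grid_origin is None:
        grid_origin = (float(cell_xy[:, 0].min() - cell_m / 2), float(cell_xy[:, 1].min() - cell_m / 2))

    # map cell grid index -> column
    def cell_index(xy):
        return (
            int(np.floor((xy[0] - grid_origin[0]) / cell_m)),
            int(np.floor((xy[1] - grid_origin[1]) / cell_m)),
        )

    col_of = {cell_index(cell_xy[j]): j for j in range(len(cell_ids))}
    individuals = sorted(pd.unique(scats["genotype_id"]).astype(str))
    row_of = {g: i for i, g in enumerate(individuals)}
    y = np.zeros((len(individuals), len(cell_ids)), dtype=np.int64)
    dropped = 0
    for _, row in scats.iterrows():
        idx = cell_index((row["x"], row["y"]))
        j = col_of.get(idx)
        if j is None:
            dropped += 1
            continue
        y[row_of[str(row["genotype_id"])], j] = 1  # dedup: repeated pairs stay 1
    if dropped:
        logger.info("aggregate_genetic: dropped %d scats outside surveyed cells", dropped)
    # individuals never landing in a surveyed cell keep all-zero rows; drop them
    seen = y.sum(axis=1) > 0
    return GeneticHistory(
        [g for g, s in zip(individuals, seen) if s],
        cell_ids,
        cell_xy,
        km,
        y[seen],
        n_occasions=1,
    )


def subsample_telemetry(
    fixes: pd.DataFrame, n_per_individual: int = 100, seed: int | None = None
) -> TelemetrySet:
    """Uniform random subsample of GPS fixes, without replacement, per individual.

    Thinning to ``n_per_individual`` locations alleviates the temporal
    autocorrelation of raw GPS tracks; individuals with fewer fixes keep all
    of them.  Reproducible under ``seed``.
    """
    if n_per_individual < 1:
        raise ValueError("n_per_individual must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for ind, grp in fixes.groupby("individual", sort=True):
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        if xy.shape[0] > n_per_individual:
            idx = np.sort(rng.choice(xy.shape[0], size=n_per_individual, replace=False))
            xy = xy[idx]
        out[str(ind)] = xy
    return TelemetrySet(out)


# ---------------------------------------------------------------------------
# Delimited-text I/O (CSV, header row, UTF-8)
# ---------------------------------------------------------------------------


def read_detectors(path) -> list[Detector]:
    df = pd.read_csv(path)
    return [Detector(str(r.id), float(r.x), float(r.y), str(r.kind)) for r in df.itertuples()]


def write_detectors(detectors: list[Detector], path) -> None:
    pd.DataFrame(
        {"id": [d.id for d in detectors], "x": [d.x for d in detectors],
         "y": [d.y for d in detectors], "kind": [d.kind for d in detectors]}
    ).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_scats(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"genotype_id": str})


def read_effort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cell_id": str})


def read_gps(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"individual": str})


def read_captures(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"individual": str, "trap_id": str})


def captures_to_marking(
    captures: pd.DataFrame, trap_ids: list[str], n_occasions: int
) -> MarkingHistory:
    """Build a marking history from a (individual, trap_id, occasion) capture table."""
    individuals = sorted(pd.unique(captures["individual"]).astype(str))
    row = {g: i for i, g in enumerate(individuals)}
    col = {t: j for j, t in enumerate(trap_ids)}
    y = np.zeros((len(individuals), len(trap_ids), n_occasions), dtype=np.int64)
    for r in captures.itertuples():
        y[row[str(r.individual)], col[str(r.trap_id)], int(r.occasion) - 1] = 1
    return MarkingHistory(individuals, list(trap_ids), y)


def read_matrix_csv(path) -> tuple[list[str], np.ndarray]:
    """Read a row-labelled matrix (first column = id, remaining columns = occasions)."""
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    return ids, df.iloc[:, 1:].to_numpy(dtype=float)


def write_matrix_csv(ids: list[str], values: np.ndarray, path, id_name: str = "id") -> None:
    values = np.asarray(values)
    cols = {id_name: ids}
    for k in range(values.shape[1]):
        cols[f"occ{k + 1}"] = values[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)
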