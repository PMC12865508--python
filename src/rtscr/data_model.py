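"""Domain types and I/O for camera-trap capture-recapture data.

The analysis operates on three core containers:

* :class:`TrapArray` — detector locations (projected planar meters) plus a
  detector × occasion binary operation matrix encoding survey effort.
* :class:`CaptureData` — identified counts ``y_id`` (individual × trap ×
  occasion) and unidentified counts ``n_noid`` (trap × occasion), the two
  matrices a random-thinning SCR model consumes.
* :class:`StateSpace` — the buffered region over which activity centers are
  assumed uniformly distributed; its area converts abundance to density.

All distances are meters, all areas km². Paired cameras at a station are a
single detector: pairing serves photo-identification, not effort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

UNIDENTIFIED = "UNIDENTIFIED"

__all__ = [
    "UNIDENTIFIED",
    "TrapArray",
    "DetectionRecord",
    "CaptureData",
    "StateSpace",
    "Dataset",
    "read_traps",
    "read_records",
    "build_capture_data",
    "build_state_space",
    "write_traps",
    "write_captures",
    "read_captures",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class TrapArray:
    """Detector array with per-occasion operation (effort) matrix.

    Parameters
    ----------
    station_id
        Unique label per detector, length J.
    xy
        (J, 2) projected planar coordinates in meters.
    operation
        (J, K) binary matrix; 1 = detector active that occasion.
    """

    station_id: np.ndarray
    xy: np.ndarray
    operation: np.ndarray

    def __post_init__(self) -> None:
        self.station_id = np.asarray(self.station_id, dtype=object)
        self.xy = np.asarray(self.xy, dtype=float)
        self.operation = np.asarray(self.operation, dtype=np.int8)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be (J, 2)")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("trap coordinates must be finite")
        if len(set(self.station_id)) != len(self.station_id):
            raise ValueError("station ids must be unique")
        if self.operation.shape[0] != self.xy.shape[0]:
            raise ValueError("operation rows must match number of traps")
        if not np.isin(self.operation, (0, 1)).all():
            raise ValueError("operation entries must be 0/1")
        if self.operation.sum() <= 0:
            raise ValueError("total survey effort must be positive")

    @property
    def n_traps(self) -> int:
        return self.xy.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.operation.shape[1]

    @property
    def effort(self) -> np.ndarray:
        """Per-trap effort E_j = number of active occasions."""
        return self.operation.sum(axis=1).astype(float)

    @property
    def total_effort(self) -> float:
        """Total trap-days (occasions) of effort."""
        return float(self.operation.sum())

    def station_index(self) -> dict:
        return {sid: j for j, sid in enumerate(self.station_id)}


@dataclass(frozen=True)
class DetectionRecord:
    """One photographic detection: station, time, individual (or unidentified)."""

    station_id: str
    timestamp: datetime
    individual_id: str = UNIDENTIFIED

    @property
    def identified(self) -> bool:
        return self.individual_id != UNIDENTIFIED


@dataclass
class CaptureData:
    """Identified and unidentified detection counts.

    ``y_id`` is individuals × traps × occasions; ``n_noid`` is traps ×
    occasions. Only individuals with at least one identified detection
    appear in ``y_id`` — that is what the observation process yields.
    """

    y_id: np.ndarray
    n_noid: np.ndarray
    individual_ids: list

    def __post_init__(self) -> None:
        self.y_id = np.asarray(self.y_id, dtype=np.int64)
        self.n_noid = np.asarray(self.n_noid, dtype=np.int64)
        self.individual_ids = list(self.individual_ids)
        if self.y_id.ndim != 3:
            raise ValueError("y_id must be (n_individuals, J, K)")
        if self.n_noid.shape != self.y_id.shape[1:]:
            raise ValueError("n_noid must be (J, K) matching y_id")
        if (self.y_id < 0).any() or (self.n_noid < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.y_id.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length must match y_id")
        if self.y_id.shape[0] and (self.y_id.sum(axis=(1, 2)) == 0).any():
            raise ValueError("every identified individual needs >= 1 detection")

    @property
    def n_individuals(self) -> int:
        return self.y_id.shape[0]

    @property
    def n_detections(self) -> int:
        """All deduplicated detection events, identified + unidentified."""
        return int(self.y_id.sum() + self.n_noid.sum())

    def validate_against(self, traps: TrapArray) -> None:
        """Check no counts fall on inactive station-occasions."""
        inactive = traps.operation == 0
        if self.y_id.shape[0] and self.y_id.sum(axis=0)[inactive].sum() > 0:
            raise ValueError("identified counts at inactive station-occasions")
        if self.n_noid[inactive].sum() > 0:
            raise ValueError("unidentified counts at inactive station-occasions")


@dataclass
class StateSpace:
    """Region S over which activity centers are uniformly distributed.

    Default geometry is the trap bounding box buffered on all sides; an
    explicit polygon mask may replace it (habitat-restricted state space).
    The uniform prior over a mask is enforced by rejection sampling.
    """

    geometry: Polygon
    buffer_width: float
    area_km2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.buffer_width < 0:
            raise ValueError("buffer_width must be >= 0")
        self.area_km2 = self.geometry.area / 1e6
        if self.area_km2 <= 0:
            raise ValueError("state space area must be positive")
        xmin, ymin, xmax, ymax = self.geometry.bounds
        self.bounds = (xmin, ymin, xmax, ymax)
        # rectangle fast path: bbox area equals polygon area
        self._is_rectangle = abs(
            (xmax - xmin) * (ymax - ymin) - self.geometry.area
        ) < 1e-6 * max(self.geometry.area, 1.0)

    @property
    def is_rectangle(self) -> bool:
        return self._is_rectangle

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized membership test for points (meters)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._is_rectangle:
            xmin, ymin, xmax, ymax = self.bounds
            return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        return shapely.contains_xy(self.geometry, x, y)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly over the geometry (rejection for masks)."""
        xmin, ymin, xmax, ymax = self.bounds
        if self._is_rectangle:
            pts = rng.random((n, 2))
            pts[:, 0] = xmin + pts[:, 0] * (xmax - xmin)
            pts[:, 1] = ymin + pts[:, 1] * (ymax - ymin)
            return pts
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = rng.random((m, 2))
            cand[:, 0] = xmin + cand[:, 0] * (xmax - xmin)
            cand[:, 1] = ymin + cand[:, 1] * (ymax - ymin)
            ok = shapely.contains_xy(self.geometry, cand[:, 0], cand[:, 1])
            take = cand[ok][: n - filled]
            out[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
        return out


@dataclass
class Dataset:
    """Analysis-ready bundle: traps + captures + state space + survey window."""

    traps: TrapArray
    captures: CaptureData
    state_space: StateSpace
    survey_window: tuple[date, date] | None = None

    def __post_init__(self) -> None:
        if self.captures.y_id.shape[1] != self.traps.n_traps:
            raise ValueError("captures and traps disagree on J")
        if self.captures.n_noid.shape[1] != self.traps.n_occasions:
            raise ValueError("captures and traps disagree on K")
        inside = self.state_space.contains(self.traps.xy[:, 0], self.traps.xy[:, 1])
        if not inside.all():
            raise ValueError("every trap must lie inside the state space")
        self.captures.validate_against(self.traps)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _parse_date(v) -> date:
    if isinstance(v, date) and not isinstance(v, datetime):
        return v
    if isinstance(v, datetime):
        return v.date()
    return pd.Timestamp(v).date()


def read_traps(
    path: str | Path,
    survey_window: tuple | None = None,
    occasion_length: int = 1,
) -> TrapArray:
    """Read a trap deployment CSV into a :class:`TrapArray`.

    The CSV needs ``station,x,y`` plus either ``setup_date,retrieval_date``
    columns or per-day activity columns named ``d1..dK`` / ``occ_*``. Occasions
    are consecutive bins of ``occasion_length`` days over the survey window
    (inferred from deployment dates when not given). Deployment intervals
    falling outside the window are clipped with a warning.
    """
    df = pd.read_csv(path)
    required = {"station", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"traps CSV needs columns {sorted(required)}")
    if df["station"].duplicated().any():
        dups = df.loc[df["station"].duplicated(), "station"].tolist()
        raise ValueError(f"duplicate station ids: {dups}")
    if df[["x", "y"]].isna().any().any():
        raise ValueError("missing trap coordinates")

    day_cols = [c for c in df.columns if c.startswith(("d", "occ_")) and c not in ("station",)]
    day_cols = [c for c in day_cols if df[c].dropna().isin((0, 1)).all() and c not in ("x", "y")]

    if {"setup_date", "retrieval_date"}.issubset(df.columns):
        setup = df["setup_date"].map(_parse_date)
        retrieval = df["retrieval_date"].map(_parse_date)
        if survey_window is None:
            survey_window = (setup.min(), retrieval.max())
        w0, w1 = _parse_date(survey_window[0]), _parse_date(survey_window[1])
        n_days = (w1 - w0).days + 1
        K = int(np.ceil(n_days / occasion_length))
        operation = np.zeros((len(df), K), dtype=np.int8)
        for j, (s, r) in enumerate(zip(setup, retrieval)):
            if s < w0 or r > w1:
                warnings.warn(
                    f"station {df['station'].iloc[j]}: operation dates outside "
                    "survey window; clipping",
                    stacklevel=2,
                )
            s_c, r_c = max(s, w0), min(r, w1)
            if r_c < s_c:
                warnings.warn(
                    f"station {df['station'].iloc[j]} never active in window",
                    stacklevel=2,
                )
                continue
            d0 = (s_c - w0).days // occasion_length
            d1 = (r_c - w0).days // occasion_length
            operation[j, d0 : d1 + 1] = 1
    elif day_cols:
        operation = df[day_cols].fillna(0).to_numpy(dtype=np.int8)
    else:
        raise ValueError(
            "traps CSV needs setup_date/retrieval_date or per-day activity columns"
        )

    return TrapArray(
        station_id=df["station"].astype(str).to_numpy(dtype=object),
        xy=df[["x", "y"]].to_numpy(dtype=float),
        operation=operation,
    )


def read_records(path: str | Path) -> list[DetectionRecord]:
    """Read a detection-records CSV (``station,datetime,individual``).

    Empty / ``NA`` individual fields mean the detection could not be
    identified to individual.
    """
    df = pd.read_csv(path)
    required = {"station", "datetime"}
    if not required.issubset(df.columns):
        raise ValueError("records CSV needs columns station,datetime[,individual]")
    records = []
    for i, row in df.iterrows():
        ind = row.get("individual")
        if pd.isna(ind) or str(ind).strip() in ("", "NA", UNIDENTIFIED):
            ind = UNIDENTIFIED
        try:
            ts = pd.Timestamp(row["datetime"]).to_pydatetime()
        except (ValueError, TypeError) as exc:
            raise ValueError(f"records CSV row {i}: bad datetime {row['datetime']!r}") from exc
        records.append(DetectionRecord(str(row["station"]), ts, str(ind)))
    return records


def build_capture_data(
    records: Iterable[DetectionRecord],
    traps: TrapArray,
    dedup_window: float = 30.0,
    survey_window: tuple | None = None,
    occasion_length: int = 1,
    on_inactive: str = "drop",
) -> CaptureData:
    """Deduplicate detection records and bin them into count matrices.

    Records of the same individual (or consecutive unidentified records) at
    the same station within ``dedup_window`` minutes of the previous retained
    record collapse to a single detection event. Events are binned into
    occasions of ``occasion_length`` days; identified events increment
    ``y_id``, unidentified events increment ``n_noid``.

    Parameters
    ----------
    on_inactive
        Event at a station-occasion with operation = 0: ``"drop"`` (default,
        with warning), ``"activate"`` (flip the operation cell to 1), or
        ``"error"``.
    """
    records = sorted(records, key=lambda r: (r.station_id, r.individual_id, r.timestamp))
    sidx = traps.station_index()
    for r in records:
        if r.station_id not in sidx:
            raise ValueError(f"record references unknown station {r.station_id!r}")

    if survey_window is None:
        ts = [r.timestamp for r in records]
        survey_window = (min(ts).date(), max(ts).date())
    w0 = _parse_date(survey_window[0])
    w1 = _parse_date(survey_window[1])
    K = traps.n_occasions

    # deduplicate per (station, individual) stream, gap measured to the last
    # retained record (camtrapR-style independence)
    events: list[tuple[str, int, int]] = []  # (individual, trap j, occasion k)
    window = timedelta(minutes=dedup_window)
    last_kept: datetime | None = None
    last_key = None
    for r in records:
        key = (r.station_id, r.individual_id)
        if r.timestamp.date() < w0 or r.timestamp.date() > w1:
            warnings.warn(f"record at {r.timestamp} outside survey window; dropped",
                          stacklevel=2)
            continue
        if key == last_key and last_kept is not None and r.timestamp - last_kept <= window:
            last_kept = r.timestamp
            continue
        last_key, last_kept = key, r.timestamp
        k = (r.timestamp.date() - w0).days // occasion_length
        if k >= K:
            k = K - 1
        events.append((r.individual_id, sidx[r.station_id], k))

    ind_ids = sorted({e[0] for e in events if e[0] != UNIDENTIFIED})
    iidx = {ind: i for i, ind in enumerate(ind_ids)}
    y_id = np.zeros((len(ind_ids), traps.n_traps, K), dtype=np.int64)
    n_noid = np.zeros((traps.n_traps, K), dtype=np.int64)
    operation = traps.operation
    for ind, j, k in events:
        if operation[j, k] == 0:
            if on_inactive == "error":
                raise ValueError(
                    f"detection at inactive station-occasion ({traps.station_id[j]}, {k})"
                )
            if on_inactive == "activate":
                operation[j, k] = 1
            else:
                warnings.warn(
                    f"detection at inactive station-occasion "
                    f"({traps.station_id[j]}, occasion {k}); dropped",
                    stacklevel=2,
                )
                continue
        if ind == UNIDENTIFIED:
            n_noid[j, k] += 1
        else:
            y_id[iidx[ind], j, k] += 1

    keep = y_id.sum(axis=(1, 2)) > 0
    return CaptureData(
        y_id=y_id[keep],
        n_noid=n_noid,
        individual_ids=[ind for ind, k in zip(ind_ids, keep) if k],
    )


def build_state_space(
    traps: TrapArray,
    buffer_width: float,
    mask: Polygon | None = None,
) -> StateSpace:
    """Build the state space: buffered trap bounding box, or an explicit mask.

    The default follows the 3σ-buffer convention: expand the trap bounding
    box by ``buffer_width`` on every side, so individuals beyond the buffer
    have negligible detection probability and are excluded from inference.
    """
    if buffer_width < 0:
        raise ValueError("buffer_width must be >= 0")
    if mask is not None:
        inside = shapely.contains_xy(
            mask, traps.xy[:, 0], traps.xy[:, 1]
        ) | shapely.intersects_xy(mask.boundary, traps.xy[:, 0], traps.xy[:, 1])
        if not inside.all():
            bad = traps.station_id[~inside].tolist()
            raise ValueError(f"mask excludes traps: {bad}")
        return StateSpace(geometry=mask, buffer_width=buffer_width)
    xmin, ymin = traps.xy.min(axis=0)
    xmax, ymax = traps.xy.max(axis=0)
    geom = box(xmin - buffer_width, ymin - buffer_width,
               xmax + buffer_width, ymax + buffer_width)
    return StateSpace(geometry=geom, buffer_width=buffer_width)


def three_sigma_buffer(sigma: float) -> float:
    """The conventional state-space buffer width: three times σ (meters)."""
    return 3.0 * float(sigma)


# ---------------------------------------------------------------------------
# persistence (wide CSV; round-trip exact)
# ---------------------------------------------------------------------------


def write_traps(traps: TrapArray, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"station": traps.station_id, "x": traps.xy[:, 0], "y": traps.xy[:, 1]}
    ).to_csv(d / "traps.csv", index=False)
    op = pd.DataFrame(
        traps.operation, columns=[f"occ_{k}" for k in range(traps.n_occasions)]
    )
    op.insert(0, "station", traps.station_id)
    op.to_csv(d / "operation.csv", index=False)


def read_traps_dir(directory: str | Path) -> TrapArray:
    d = Path(directory)
    tr = pd.read_csv(d / "traps.csv")
    op = pd.read_csv(d / "operation.csv")
    occ_cols = [c for c in op.columns if c.startswith("occ_")]
    return TrapArray(
        station_id=tr["station"].astype(str).to_numpy(dtype=object),
        xy=tr[["x", "y"]].to_numpy(dtype=float),
        operation=op[occ_cols].to_numpy(dtype=np.int8),
    )


def write_captures(cap: CaptureData, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    i, j, k = np.nonzero(cap.y_id)
    pd.DataFrame(
        {
            "individual": [cap.individual_ids[a] for a in i],
            "trap": j,
            "occasion": k,
            "count": cap.y_id[i, j, k],
        }
    ).to_csv(d / "y_id.csv", index=False)
    pd.DataFrame(
        cap.n_noid, columns=[f"occ_{k}" for k in range(cap.n_noid.shape[1])]
    ).to_csv(d / "n_noid.csv", index=False)


def read_captures(directory: str | Path, n_traps: int, n_occasions: int) -> CaptureData:
    d = Path(directory)
    long = pd.read_csv(d / "y_id.csv")
    noid = pd.read_csv(d / "n_noid.csv")
    occ_cols = [c for c in noid.columns if c.startswith("occ_")]
    n_noid = noid[occ_cols].to_numpy(dtype=np.int64)
    if n_noid.shape != (n_traps, n_occasions):
        raise ValueError("n_noid.csv shape does not match trap array")
    ids = sorted(long["individual"].astype(str).unique()) if len(long) else []
    iidx = {v: a for a, v in enumerate(ids)}
    y_id = np.zeros((len(ids), n_traps, n_occasions), dtype=np.int64)
    for _, row in long.iterrows():
        y_id[iidx[str(row["individual"])], int(row["trap"]), int(row["occasion"])] += int(
            row["count"]
        )
    return CaptureData(y_id=y_id, n_noid=n_noid, individual_ids=ids)
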