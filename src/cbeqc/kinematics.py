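"""Joint-angle kinematics from 2D pose landmarks.

Landmark streams follow the MediaPipe convention: normalized image
coordinates with the origin at the top-left corner and y increasing
downward.  The eight landmarks used for lower-limb kinematics are the
shoulders (IDs 11, 12), hips (23, 24), knees (25, 26) and ankles (27, 28).

Two angle kinds are supported:

* ``vertex`` — the angle at the middle point of a three-point chain
  (e.g. hip–knee–ankle gives the knee angle), always in [0, 180] degrees.
* ``inclination`` — the unsigned angle between a directed two-point body
  segment and the downward image vertical, in [0, 180] degrees; swapping
  the endpoints maps the angle to its 180° complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

REQUIRED_LANDMARKS: tuple[int, ...] = (11, 12, 23, 24, 25, 26, 27, 28)

#: Human-readable names of the required keypoints, for error messages.
LANDMARK_NAMES = {
    11: "left_shoulder",
    12: "right_shoulder",
    23: "left_hip",
    24: "right_hip",
    25: "left_knee",
    26: "right_knee",
    27: "left_ankle",
    28: "right_ankle",
}

# Landmark coordinates are allowed slightly outside the unit square because
# pose estimators emit off-screen estimates.
COORD_BOUNDS = (-0.5, 1.5)


class LandmarkError(ValueError):
    """Raised for malformed or incomplete landmark streams."""


@dataclass(frozen=True)
class LandmarkSeries:
    """Per-frame 2D coordinates of pose keypoints at a fixed frame rate.

    Parameters
    ----------
    fps:
        Frame rate in Hz.
    landmark_ids:
        Ordered landmark identifiers; must include the eight required IDs.
    coords:
        Array of shape ``(n_frames, n_landmarks, 2)`` with (x, y) pairs in
        normalized image coordinates.
    """

    fps: float
    landmark_ids: tuple[int, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise LandmarkError(f"fps must be positive, got {self.fps}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(self.landmark_ids) or coords.shape[2] != 2:
            raise LandmarkError(
                f"coords must have shape (n_frames, {len(self.landmark_ids)}, 2), got {coords.shape}"
            )
        missing = set(REQUIRED_LANDMARKS) - set(self.landmark_ids)
        if missing:
            raise LandmarkError(f"missing required landmark IDs: {sorted(missing)}")
        if not np.all(np.isfinite(coords)):
            raise LandmarkError("landmark coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def xy(self, landmark_id: int) -> np.ndarray:
        """(n_frames, 2) trajectory of one landmark."""
        try:
            idx = self.landmark_ids.index(landmark_id)
        except ValueError:
            raise LandmarkError(f"landmark ID {landmark_id} not in series") from None
        return self.coords[:, idx, :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns frame, landmark_id, x, y."""
        n, k = self.coords.shape[:2]
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n), k),
                "landmark_id": np.tile(np.asarray(self.landmark_ids), n),
                "x": self.coords[:, :, 0].ravel(),
                "y": self.coords[:, :, 1].ravel(),
            }
        )


@dataclass(frozen=True)
class AngleSpec:
    """Definition of one named joint angle.

    ``points`` holds three landmark IDs for a vertex angle (the middle one is
    the vertex) or two IDs for a segment inclination.
    """

    name: str
    kind: str  # "vertex" | "inclination"
    points: tuple[int, ...]
    side: str = "left"

    def __post_init__(self) -> None:
        if self.kind not in ("vertex", "inclination"):
            raise ValueError(f"unknown angle kind {self.kind!r}")
        expected = 3 if self.kind == "vertex" else 2
        if len(self.points) != expected:
            raise ValueError(f"{self.kind} angle needs {expected} points, got {len(self.points)}")
        if len(set(self.points)) != len(self.points):
            raise ValueError("angle points must be distinct")
        unknown = set(self.points) - set(REQUIRED_LANDMARKS)
        if unknown:
            raise ValueError(f"unsupported landmark IDs {sorted(unknown)}")


@dataclass(frozen=True)
class AngleSeries:
    """One named joint-angle signal in degrees, frame-aligned to its source."""

    name: str
    fps: float
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("angle values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


#: Default six-angle registry: hip angles (shoulder–hip–knee), knee angles
#: (hip–knee–ankle) and lower-leg inclinations (knee–ankle), left and right.
DEFAULT_REGISTRY: tuple[AngleSpec, ...] = (
    AngleSpec("left_hip", "vertex", (11, 23, 25), "left"),
    AngleSpec("right_hip", "vertex", (12, 24, 26), "right"),
    AngleSpec("left_knee", "vertex", (23, 25, 27), "left"),
    AngleSpec("right_knee", "vertex", (24, 26, 28), "right"),
    AngleSpec("left_knee_ankle", "inclination", (25, 27), "left"),
    AngleSpec("right_knee_ankle", "inclination", (26, 28), "right"),
)


def registry_by_name(registry: Sequence[AngleSpec] = DEFAULT_REGISTRY) -> dict[str, AngleSpec]:
    return {spec.name: spec for spec in registry}


def load_registry(path: str | Path) -> tuple[AngleSpec, ...]:
    """Load an angle registry from YAML (list of name/kind/points/side maps)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return tuple(
        AngleSpec(
            name=item["name"],
            kind=item["kind"],
            points=tuple(int(p) for p in item["points"]),
            side=item.get("side", "left"),
        )
        for item in raw
    )


# ---------------------------------------------------------------------------
# Angle geometry


def vertex_angle(a, b, c) -> float:
    """Angle at vertex ``b`` between rays b→a and b→c, in degrees [0, 180].

    Symmetric in ``a`` and ``c``; invariant to translation, rotation and
    uniform scaling of the point triple.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("vertex angle undefined: zero-length ray")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def segment_inclination(p, q) -> float:
    """Unsigned angle between segment p→q and the downward image vertical.

    With y increasing downward, a segment pointing straight down has
    inclination 0° and one pointing straight up has 180°; swapping ``p`` and
    ``q`` yields the 180° complement.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    u = q - p
    n = np.linalg.norm(u)
    if n == 0.0:
        raise ValueError("segment inclination undefined: coincident points")
    cosang = np.clip(u[1] / n, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compute_angle_series(series: LandmarkSeries, spec: AngleSpec) -> AngleSeries:
    """Evaluate one angle definition on every frame of a landmark series."""
    pts = [series.xy(pid) for pid in spec.points]
    if spec.kind == "vertex":
        a, b, c = pts
        u = a - b
        v = c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        bad = np.flatnonzero((nu == 0) | (nv == 0))
        if bad.size:
            raise LandmarkError(f"zero-length ray for angle {spec.name!r} at frame {bad[0]}")
        cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        values = np.degrees(np.arccos(cosang))
    else:
        p, q = pts
        u = q - p
        n = np.linalg.norm(u, axis=1)
        bad = np.flatnonzero(n == 0)
        if bad.size:
            raise LandmarkError(f"coincident points for angle {spec.name!r} at frame {bad[0]}")
        values = np.degrees(np.arccos(np.clip(u[:, 1] / n, -1.0, 1.0)))
    return AngleSeries(name=spec.name, fps=series.fps, values=values)


def mean_angle(series: AngleSeries) -> float:
    """Arithmetic mean of the angle values across all frames."""
    if series.n_frames == 0:
        raise ValueError("cannot average an empty angle series")
    return float(np.mean(series.values))


# ---------------------------------------------------------------------------
# Landmark CSV I/O (dialect: header ``frame,landmark_id,x,y``, one row per
# landmark per frame, 0-based contiguous frames)


def write_landmarks(series: LandmarkSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_landmarks(source: str | Path, fps: float = 30.0) -> LandmarkSeries:
    """Read a landmark CSV and validate the stream.

    Raises :class:`LandmarkError` on malformed rows, non-contiguous frames,
    missing required IDs (naming the frame) or out-of-range coordinates.
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # malformed file
        raise LandmarkError(f"cannot parse landmark CSV {source}: {exc}") from exc
    required_cols = {"frame", "landmark_id", "x", "y"}
    if not required_cols.issubset(df.columns):
        raise LandmarkError(
            f"landmark CSV {source} must have columns {sorted(required_cols)}, got {list(df.columns)}"
        )
    if df[["x", "y"]].isna().any().any() or df[["frame", "landmark_id"]].isna().any().any():
        raise LandmarkError(f"landmark CSV {source} contains missing values")
    lo, hi = COORD_BOUNDS
    out = df[(df.x < lo) | (df.x > hi) | (df.y < lo) | (df.y > hi)]
    if len(out):
        row = out.iloc[0]
        raise LandmarkError(
            f"coordinate outside [{lo}, {hi}] at frame {int(row.frame)}, "
            f"landmark {int(row.landmark_id)}: ({row.x}, {row.y})"
        )
    frames = np.sort(df["frame"].unique())
    n = len(frames)
    if not np.array_equal(frames, np.arange(n)):
        raise LandmarkError(f"frames must be contiguous 0-based integers, got {frames[:10]}...")
    ids = tuple(sorted(df["landmark_id"].unique().astype(int)))
    # every frame must contain every ID exactly once
    counts = df.groupby(["frame", "landmark_id"]).size()
    if (counts != 1).any():
        frame, lid = counts[counts != 1].index[0]
        raise LandmarkError(f"duplicate entry for landmark {lid} at frame {frame}")
    per_frame = df.groupby("frame")["landmark_id"].apply(set)
    full = set(ids)
    for frame, present in per_frame.items():
        missing = set(REQUIRED_LANDMARKS) - present
        if missing:
            raise LandmarkError(f"frame {frame} is missing required landmark IDs {sorted(missing)}")
        if present != full:
            raise LandmarkError(f"frame {frame} is missing landmark IDs {sorted(full - present)}")
    wide = df.set_index(["frame", "landmark_id"]).sort_index()
    coords = np.empty((n, len(ids), 2), dtype=float)
    for j, lid in enumerate(ids):
        sub = wide.xs(lid, level="landmark_id")
        coords[:, j, 0] = sub["x"].to_numpy()
        coords[:, j, 1] = sub["y"].to_numpy()
    return LandmarkSeries(fps=fps, landmark_ids=ids, coords=coords)
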