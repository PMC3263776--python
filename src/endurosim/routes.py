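"""Road profiles: containers, file I/O and deterministic route fixtures.

A route is parametrized by distance along the road (m) against altitude
(m above sea level), with piecewise-constant gradients between breakpoints.
The gradient convention is S = vertical distance / horizontal distance,
so for a segment of road length L climbing v metres,
S = v / sqrt(L**2 - v**2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RouteProfile",
    "RouteError",
    "SyntheticRouteSpec",
    "make_alpe_dhuez_route",
    "generate_route",
    "read_route",
    "write_route",
]

_EARTH_RADIUS_M = 6_371_000.0


class RouteError(ValueError):
    """Raised for malformed route inputs (with file/line context when known)."""


@dataclass(frozen=True)
class RouteProfile:
    """Ordered breakpoints of (distance along road, altitude).

    Gradients are derived per interval and held piecewise constant, which is
    what produces the characteristic transient power spikes when a simulated
    rider crosses into a steeper section at speed.
    """

    distance_m: np.ndarray
    altitude_m: np.ndarray
    name: str = "route"

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_m, dtype=float)
        a = np.asarray(self.altitude_m, dtype=float)
        if d.ndim != 1 or d.shape != a.shape or d.size < 2:
            raise RouteError("route needs >= 2 matching (distance, altitude) breakpoints")
        if not np.all(np.diff(d) > 0):
            raise RouteError("route distances must be strictly increasing")
        climb = np.abs(np.diff(a))
        if np.any(climb >= np.diff(d)):
            raise RouteError("altitude change exceeds road length in a segment (gradient not finite)")
        object.__setattr__(self, "distance_m", d)
        object.__setattr__(self, "altitude_m", a)

    @property
    def length_m(self) -> float:
        return float(self.distance_m[-1] - self.distance_m[0])

    @property
    def net_climb_m(self) -> float:
        return float(self.altitude_m[-1] - self.altitude_m[0])

    @property
    def gradients(self) -> np.ndarray:
        """Per-interval gradient S = vertical / horizontal (dimensionless)."""
        dd = np.diff(self.distance_m)
        da = np.diff(self.altitude_m)
        horiz = np.sqrt(dd**2 - da**2)
        return da / horiz

    def segment_index(self, d: float) -> int:
        i = int(np.searchsorted(self.distance_m, d, side="right") - 1)
        return min(max(i, 0), len(self.distance_m) - 2)

    def gradient_at(self, d: float) -> float:
        return float(self.gradients[self.segment_index(d)])

    def altitude_at(self, d: float) -> float:
        """Altitude linearly interpolated in road distance."""
        return float(np.interp(d, self.distance_m, self.altitude_m))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_m": self.distance_m, "altitude_m": self.altitude_m})

    def resample(self, step_m: float) -> "RouteProfile":
        """Return the profile re-sampled on a uniform distance grid."""
        d = np.arange(self.distance_m[0], self.distance_m[-1] + 0.5 * step_m, step_m)
        d[-1] = self.distance_m[-1]
        return RouteProfile(d, np.interp(d, self.distance_m, self.altitude_m), name=self.name)


@dataclass(frozen=True)
class SyntheticRouteSpec:
    """Specification for a deterministic synthetic climb.

    The generated profile has a flat prefix followed by piecewise-constant
    1 km-style grade segments drawn (reproducibly, from ``seed``) inside
    ``grade_range`` and then rescaled so the net climb is met exactly.
    """

    length_m: float = 15_500.0
    start_altitude_m: float = 720.0
    end_altitude_m: float = 1850.0
    flat_prefix_m: float = 1500.0
    grade_range: tuple[float, float] = (0.08, 0.11)
    segment_m: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_m <= self.flat_prefix_m:
            raise RouteError("route length must exceed the flat prefix")
        climb_len = self.length_m - self.flat_prefix_m
        climb = self.end_altitude_m - self.start_altitude_m
        lo, hi = self.grade_range
        if abs(climb) >= climb_len:
            raise RouteError("requested climb exceeds the climbing road length")
        # achievability: mean grade of the climbing part within a slack band
        mean_s = climb / math.sqrt(climb_len**2 - climb**2)
        if not (0.5 * lo <= mean_s <= 1.2 * hi):
            raise RouteError("requested climb not achievable within the grade range")


def generate_route(spec: SyntheticRouteSpec) -> RouteProfile:
    """Build a synthetic climb profile; byte-identical for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    climb_len = spec.length_m - spec.flat_prefix_m
    n_seg = max(1, int(round(climb_len / spec.segment_m)))
    edges = np.linspace(spec.flat_prefix_m, spec.length_m, n_seg + 1)
    seg_len = np.diff(edges)
    lo, hi = spec.grade_range
    grades = rng.uniform(lo, hi, size=n_seg)
    vert = grades / np.sqrt(1.0 + grades**2) * seg_len
    target = spec.end_altitude_m - spec.start_altitude_m
    vert *= target / vert.sum()
    d = np.concatenate([[0.0], edges]) if spec.flat_prefix_m > 0 else edges
    alt = np.concatenate(
        [[spec.start_altitude_m], [spec.start_altitude_m], spec.start_altitude_m + np.cumsum(vert)]
    ) if spec.flat_prefix_m > 0 else np.concatenate(
        [[spec.start_altitude_m], spec.start_altitude_m + np.cumsum(vert)]
    )
    alt[-1] = spec.end_altitude_m
    return RouteProfile(d, alt, name=f"synthetic-{spec.seed}")


# Vertical gain (m) of each 1 km climbing segment of the reconstructed
# Bourg d'Oisans -> Alpe d'Huez profile.  The published constraints pin the
# endpoints (720 m and 1850 m over 15.5 km), a 1.5 km flat run-in, 1 km grade
# resolution, and 8-11 % grades over at least three quarters of the distance;
# within those constraints the shape ramps in gently, is steepest just after
# the climb starts and eases through the final village kilometre.
_ALPE_DHUEZ_VERTICALS = (55.0, 92.0, 90.0, 89.0, 88.0, 87.0, 86.0,
                         85.0, 84.0, 84.0, 83.0, 82.0, 80.0, 45.0)


def make_alpe_dhuez_route() -> RouteProfile:
    """Deterministic 15.5 km Alpe d'Huez time-trial profile (720 m -> 1850 m).

    The first 1.5 km is flat; the remaining fourteen 1 km segments climb a
    total of exactly 1130 m, twelve of them at grades between 8 and 11 %.
    """
    d = np.concatenate([[0.0, 1500.0], 1500.0 + 1000.0 * np.arange(1, 15)])
    alt = np.concatenate([[720.0, 720.0], 720.0 + np.cumsum(_ALPE_DHUEZ_VERTICALS)])
    return RouteProfile(d, alt, name="alpe_dhuez")


# ---------------------------------------------------------------------------
# File I/O: CSV (distance_m, altitude_m) and GPX track points
# ---------------------------------------------------------------------------

def _haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2.0 * _EARTH_RADIUS_M * math.asin(math.sqrt(a))


def _read_gpx(path: Path) -> RouteProfile:
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # pragma: no cover - message path
        raise RouteError(f"{path}: not valid GPX XML ({exc})") from exc
    root = tree.getroot()
    ns = {"g": root.nsmap.get(None, "http://www.topografix.com/GPX/1/1")}
    pts = root.findall(".//g:trkpt", ns) or root.findall(".//trkpt")
    if len(pts) < 2:
        raise RouteError(f"{path}: GPX track has fewer than 2 points")
    lats, lons, eles = [], [], []
    for i, pt in enumerate(pts):
        ele = pt.find("g:ele", ns)
        if ele is None:
            ele = pt.find("ele")
        if ele is None or ele.text is None:
            raise RouteError(f"{path}: track point {i + 1} lacks an <ele> elevation")
        lats.append(float(pt.get("lat")))
        lons.append(float(pt.get("lon")))
        eles.append(float(ele.text))
    horiz = np.array(
        [0.0] + [_haversine_m(lats[i - 1], lons[i - 1], lats[i], lons[i]) for i in range(1, len(pts))]
    )
    dz = np.diff(np.asarray(eles), prepend=eles[0])
    dist = np.cumsum(np.sqrt(horiz**2 + dz**2))
    keep = np.concatenate([[True], np.diff(dist) > 0])
    return RouteProfile(dist[keep], np.asarray(eles)[keep], name=path.stem)


def _read_csv(path: Path) -> RouteProfile:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise RouteError(f"{path}: cannot parse as CSV ({exc})") from exc
    for col in ("distance_m", "altitude_m"):
        if col not in df.columns:
            raise RouteError(f"{path}: line 1: missing required column '{col}'")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df[["distance_m", "altitude_m"]].isna().any(axis=1)]
    if len(bad):
        raise RouteError(f"{path}: line {int(bad[0]) + 2}: non-numeric or missing value")
    return RouteProfile(df["distance_m"].to_numpy(float), df["altitude_m"].to_numpy(float), name=path.stem)


def read_route(path: str | Path) -> RouteProfile:
    """Read a route from CSV (distance_m, altitude_m columns) or GPX."""
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        return _read_gpx(path)
    return _read_csv(path)


def write_route(route: RouteProfile, path: str | Path) -> None:
    route.to_frame().to_csv(path, index=False)
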