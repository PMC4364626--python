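"""Binary range maps, area-change decomposition, and centroid shifts.

Area change between a current and a future binary range is decomposed
relative to the current area: new habitat (gained cells), habitat lost
(vanished cells), and total change (net), all in percent of the current
area, so that total = new - lost holds identically. Range displacement is
tracked through the probability-weighted geographic centre (mean centre) of
each map; distances use the local equirectangular approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .consensus import ConsensusMap
from .evaluation import PRESENCE_THRESHOLD
from .grids import KM_PER_DEG_LAT, EnvGrid


@dataclass
class ShiftResult:
    shift_km: float
    northward_km: float
    eastward_km: float
    bearing_deg: float
    degenerate: bool = False  # identical centroids: bearing undefined, 0


@dataclass
class RangeChangeSummary:
    current_area_cells: int
    future_area_cells: int
    total_change_pct: float
    new_habitat_pct: float
    habitat_lost_pct: float
    centroid_current: tuple[float, float] | None = None
    centroid_future: tuple[float, float] | None = None
    shift: ShiftResult | None = None


def binarize(cmap: ConsensusMap | np.ndarray,
             threshold: float = PRESENCE_THRESHOLD) -> np.ndarray:
    """Presence iff probability strictly above threshold; NaN (off-mask)
    cells are absent."""
    probs = cmap.probs if isinstance(cmap, ConsensusMap) else np.asarray(cmap)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(probs), probs > threshold, False).astype(bool)


def range_change(current: np.ndarray, future: np.ndarray) -> RangeChangeSummary:
    """Area-change decomposition of two aligned binary grids, percent of the
    current area."""
    current = np.asarray(current, dtype=bool)
    future = np.asarray(future, dtype=bool)
    if current.shape != future.shape:
        raise ValueError("binary grids are not aligned")
    n_cur = int(current.sum())
    n_fut = int(future.sum())
    if n_cur == 0:
        raise ValueError("empty current range: change percentages undefined")
    new = int((future & ~current).sum())
    lost = int((current & ~future).sum())
    return RangeChangeSummary(
        current_area_cells=n_cur,
        future_area_cells=n_fut,
        total_change_pct=100.0 * (n_fut - n_cur) / n_cur,
        new_habitat_pct=100.0 * new / n_cur,
        habitat_lost_pct=100.0 * lost / n_cur,
    )


def centroid(cmap: ConsensusMap | np.ndarray, env: EnvGrid) -> tuple[float, float]:
    """Probability-weighted mean centre (lat, lon) of a map on *env*'s
    geometry. Binary maps give the unweighted centre of the range."""
    probs = cmap.probs if isinstance(cmap, ConsensusMap) else np.asarray(cmap, dtype=float)
    w = np.where(env.mask & np.isfinite(probs), probs, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero probability mass: centroid undefined")
    lat, lon = env.cell_latlon()
    return float((w * lat).sum() / total), float((w * lon).sum() / total)


def shift(c1: tuple[float, float], c2: tuple[float, float]) -> ShiftResult:
    """Displacement from centroid c1 to c2 (each (lat, lon) degrees).

    northward = dlat * 111.32 km; eastward = dlon * 111.32 * cos(mean lat);
    bearing measured from north, clockwise, in [0, 360).
    """
    (lat1, lon1), (lat2, lon2) = c1, c2
    if not all(map(math.isfinite, (lat1, lon1, lat2, lon2))):
        raise ValueError("non-finite centroid coordinates")
    north = (lat2 - lat1) * KM_PER_DEG_LAT
    east = (lon2 - lon1) * KM_PER_DEG_LAT * math.cos(math.radians(0.5 * (lat1 + lat2)))
    dist = math.hypot(north, east)
    if dist == 0.0:
        return ShiftResult(0.0, 0.0, 0.0, 0.0, degenerate=True)
    bearing = math.degrees(math.atan2(east, north)) % 360.0
    return ShiftResult(dist, north, east, bearing)


def summarize_range_change(current_map: ConsensusMap, future_map: ConsensusMap,
                           env: EnvGrid,
                           threshold: float = PRESENCE_THRESHOLD,
                           ) -> RangeChangeSummary:
    """Full per-(species, period, method) summary: area decomposition of the
    binarized maps plus the probability-weighted centroid shift."""
    summary = range_change(binarize(current_map, threshold),
                           binarize(future_map, threshold))
    summary.centroid_current = centroid(current_map, env)
    summary.centroid_future = centroid(future_map, env)
    summary.shift = shift(summary.centroid_current, summary.centroid_future)
    return summary
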