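"""Selection of representative simulation runs.

Replicate end-year maps of the land-use simulation are summarized by two
indices — Pielou evenness of class area shares and total intensively used
area — and the runs closest to the centroid and the four corners of the
axis-aligned minimum bounding rectangle of the index cloud are retained, so
that five maps span the breadth of simulated land-use change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import landuse as lu

ROLES = ("centroid", "corner_low_low", "corner_high_low", "corner_low_high", "corner_high_high")


@dataclass(frozen=True)
class RunIndexPair:
    replicate: int
    evenness: float
    intensive_area: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.evenness <= 1.0):
            raise ValueError("evenness must lie in [0, 1]")
        if self.intensive_area < 0:
            raise ValueError("intensive area must be non-negative")


def landuse_evenness(landuse_map: np.ndarray) -> float:
    """Pielou evenness J = -sum p ln p / ln K over classes present.

    A single-class map is defined as maximally even (J = 1), guarding the
    ln(1) = 0 denominator.
    """
    arr = np.asarray(landuse_map)
    if arr.size == 0:
        raise ValueError("empty land-use map")
    _, counts = np.unique(arr, return_counts=True)
    if len(counts) == 1:
        return 1.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(len(p)))


def intensive_area(landuse_map: np.ndarray, farms: Optional[dict] = None) -> int:
    """Count of 25 m cells under intensive use.

    Intensive use means non-low-input cropland, meadows mown at least three
    times a year or pastures stocked above 1.5 livestock units/ha — all of
    which are encoded directly in the class codes, so the optional farm
    registry is not needed for the decision.
    """
    return int(np.isin(np.asarray(landuse_map), lu.INTENSIVE_CLASSES).sum())


def select_representative_runs(pairs: Sequence[RunIndexPair]) -> Dict[str, int]:
    """Pick the runs nearest the centroid and the four bounding-box corners.

    Both axes are min-max normalized before Euclidean distances are taken
    (the indices have incommensurate units). Ties break to the lower
    replicate id; a run already selected for an earlier role is replaced by
    the next-nearest unused run.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 runs to select from")
    ev = np.array([p.evenness for p in pairs], float)
    ia = np.array([p.intensive_area for p in pairs], float)
    ids = np.array([p.replicate for p in pairs])

    def norm(x: np.ndarray) -> np.ndarray:
        span = x.max() - x.min()
        return (x - x.min()) / span if span > 0 else np.zeros_like(x)

    x, y = norm(ev), norm(ia)
    lo_x, hi_x = (0.0, 1.0) if ev.max() > ev.min() else (0.0, 0.0)
    lo_y, hi_y = (0.0, 1.0) if ia.max() > ia.min() else (0.0, 0.0)
    targets = {
        "centroid": (x.mean(), y.mean()),
        "corner_low_low": (lo_x, lo_y),
        "corner_high_low": (hi_x, lo_y),
        "corner_low_high": (lo_x, hi_y),
        "corner_high_high": (hi_x, hi_y),
    }
    chosen: Dict[str, int] = {}
    used: set = set()
    for role in ROLES:
        tx, ty = targets[role]
        d = np.hypot(x - tx, y - ty)
        order = np.lexsort((ids, d))  # distance first, replicate id as tie-break
        for i in order:
            if int(ids[i]) not in used:
                chosen[role] = int(ids[i])
                used.add(int(ids[i]))
                break
    return chosen
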