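"""Range-dynamics metrics from binary suitability maps.

Per species and scenario combination, three cell counts summarize range
change: C (currently suitable cells), F (future suitable cells) and O
(their overlap). From these derive the range-size ratio F/C, the exposure
(C - O)/C — the displaced fraction of the current range — and the log
response ratio ln(F/C). Species-level records are aggregated over the five
representative simulation runs and over habitat-specialist groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import landuse as lu

logger = logging.getLogger(__name__)

#: floor (in cells) applied to an empty future range before taking logs
LOG_RATIO_FLOOR = 0.5


@dataclass(frozen=True)
class RangeChangeRecord:
    species_id: str
    climate_scenario: str
    landuse_scenario: str
    run: int
    C: int
    F: int
    O: int
    ratio: float
    exposure: float
    log_ratio: float
    f_floored: bool = False

    def __post_init__(self) -> None:
        if self.O > min(self.C, self.F):
            raise ValueError("overlap exceeds one of the range sizes")
        if self.C > 0 and not (0.0 <= self.exposure <= 1.0):
            raise ValueError("exposure outside [0, 1]")


def range_change(
    current: np.ndarray,
    future: np.ndarray,
    species_id: str = "",
    climate_scenario: str = "",
    landuse_scenario: str = "",
    run: int = 0,
) -> RangeChangeRecord:
    """Count C/F/O and derive ratio, exposure and log response ratio.

    ``current``/``future`` are binary rasters of identical geometry. A
    species with C = 0 cannot be normalized and must be excluded upstream;
    an empty future range is floored at half a cell for the log ratio only
    (flag recorded).
    """
    cur = np.asarray(current).astype(bool)
    fut = np.asarray(future).astype(bool)
    if cur.shape != fut.shape:
        raise ValueError("geometry mismatch between current and future maps")
    C = int(cur.sum())
    if C == 0:
        raise ValueError("species has no currently suitable cell (C = 0)")
    F = int(fut.sum())
    O = int((cur & fut).sum())
    ratio = F / C
    exposure = (C - O) / C
    floored = F == 0
    log_ratio = float(np.log(max(F, LOG_RATIO_FLOOR) / C))
    return RangeChangeRecord(
        species_id=species_id,
        climate_scenario=climate_scenario,
        landuse_scenario=landuse_scenario,
        run=run,
        C=C,
        F=F,
        O=O,
        ratio=ratio,
        exposure=exposure,
        log_ratio=log_ratio,
        f_floored=floored,
    )


def records_to_frame(records: Iterable[RangeChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species_id,
                "climate": r.climate_scenario,
                "landuse": r.landuse_scenario,
                "run": r.run,
                "C": r.C,
                "F": r.F,
                "O": r.O,
                "ratio": r.ratio,
                "exposure": r.exposure,
                "log_ratio": r.log_ratio,
                "f_floored": r.f_floored,
            }
            for r in records
        ]
    )


def classify_specialists(
    plots,
    lookup: Optional[Mapping[int, str]] = None,
    threshold: float = 0.75,
) -> Dict[str, str]:
    """Classify species as habitat specialists or generalists.

    A species is a specialist of a habitat group when at least ``threshold``
    of its plot occurrences fall in land-use classes of that group
    (supported thresholds include the 0.5 and 0.9 sensitivity settings).
    Species with zero occurrences are left unclassified.
    """
    lookup = dict(lookup or lu.HABITAT_GROUP_LOOKUP)
    df = plots.data if hasattr(plots, "data") else plots
    species = plots.species_ids if hasattr(plots, "species_ids") else [
        c for c in df.columns if c.startswith("sp")
    ]
    groups = df["landuse"].map(lookup)
    out: Dict[str, str] = {}
    for sp in species:
        pres = df[sp].to_numpy().astype(bool)
        total = pres.sum()
        if total == 0:
            continue
        counts = groups[pres].value_counts()
        if counts.iloc[0] / total >= threshold:
            out[sp] = counts.index[0]
        else:
            out[sp] = "generalist"
    return out


def group_response(
    records: pd.DataFrame, specialists: Mapping[str, str], group: str
) -> pd.DataFrame:
    """Mean log response ratio of one specialist group per scenario pair.

    Per (climate, land-use) combination: species' run-mean log ratios are
    averaged across the group's species.
    """
    members = [s for s, g in specialists.items() if g == group]
    if not members:
        raise ValueError(f"no specialist of group {group!r}")
    sub = records[records["species"].isin(members)]
    per_species = (
        sub.groupby(["climate", "landuse", "species"])["log_ratio"].mean().reset_index()
    )
    out = (
        per_species.groupby(["climate", "landuse"])["log_ratio"]
        .mean()
        .reset_index()
        .rename(columns={"log_ratio": "mean_log_ratio"})
    )
    out["group"] = group
    return out


def richness_change(
    current_stack: Mapping[str, np.ndarray], future_stack: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Per-cell change in projected species number (future minus current)."""
    if set(current_stack) != set(future_stack):
        raise ValueError("species sets of the two stacks differ")
    if not current_stack:
        raise ValueError("empty stacks")
    first = next(iter(current_stack.values()))
    delta = np.zeros(first.shape, dtype=np.int32)
    for sp, cur in current_stack.items():
        fut = future_stack[sp]
        if fut.shape != cur.shape:
            raise ValueError("geometry mismatch in stacks")
        delta += fut.astype(np.int32) - cur.astype(np.int32)
    return delta


def aggregate_runs(values: Sequence[float]) -> Tuple[float, float, float]:
    """(mean, min, max) across the selected simulation runs."""
    if len(values) == 0:
        raise ValueError("no run values to aggregate")
    arr = np.asarray(values, float)
    return float(arr.mean()), float(arr.min()), float(arr.max())
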