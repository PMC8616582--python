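"""Rachis-versus-edge intensity ratio from germline ROI measurements.

In the C. elegans gonad, germ-cell nuclei line the tube surface (the
"edge") around a shared cytoplasmic core (the rachis).  P granules sit at
the nuclear periphery in the wild type; mutants that detach them shift
fluorescent granule signal into the rachis.  The dispersal readout is the
background-corrected ratio of the rachis ROI mean intensity to the average
of two edge ROI mean intensities:

    ratio = 2 * (rachis - background) / (edge1 + edge2 - 2 * background)

All inputs are ROI mean gray values as produced by any image tool's
measure function; no pixel-level processing happens here.  The default
("symmetric") mode above subtracts background from the numerator and the
denominator alike, which makes the ratio invariant under affine detector
changes (gain and offset); a "literal" mode subtracting background only once in the
numerator, (2*rachis - background) / (edge1 + edge2 - 2*background), is
kept for comparison with legacy spreadsheets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .enrichment import one_tailed_t

__all__ = [
    "ROIMeasurement",
    "rachis_edge_ratio",
    "ratio_table",
    "ratio_summary",
    "load_roi_measurements",
]

logger = logging.getLogger(__name__)

MODES = ("symmetric", "literal")


@dataclass(frozen=True)
class ROIMeasurement:
    """Mean gray values of the rachis, two edge, and background ROIs."""

    animal_id: str
    rachis: float
    edge1: float
    edge2: float
    background: float

    def __post_init__(self) -> None:
        for name in ("rachis", "edge1", "edge2", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} intensity must be nonnegative")


def rachis_edge_ratio(m: ROIMeasurement, mode: str = "symmetric") -> float:
    """Background-corrected rachis/edge intensity ratio for one animal.

    Returns NaN when the corrected edge denominator is not positive
    (callers exclude such records from aggregates).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    denom = m.edge1 + m.edge2 - 2.0 * m.background
    if denom <= 0:
        logger.warning(
            "animal %s: corrected edge intensity %.4g is not positive; ratio undefined",
            m.animal_id,
            denom,
        )
        return math.nan
    if mode == "symmetric":
        num = 2.0 * (m.rachis - m.background)
    else:
        num = 2.0 * m.rachis - m.background
    return num / denom


def ratio_table(
    records: Iterable[ROIMeasurement],
    group_of: Mapping[str, str] | None = None,
    mode: str = "symmetric",
) -> pd.DataFrame:
    """Per-animal ratio frame with a ``defined`` flag for valid denominators."""
    rows = []
    for m in records:
        r = rachis_edge_ratio(m, mode=mode)
        rows.append(
            {
                "animal_id": m.animal_id,
                "genotype": (group_of or {}).get(m.animal_id, ""),
                "ratio": r,
                "defined": not math.isnan(r),
            }
        )
    return pd.DataFrame(rows)


def ratio_summary(
    records: Iterable[ROIMeasurement],
    group_of: Mapping[str, str],
    mode: str = "symmetric",
) -> dict:
    """Group the per-animal ratios by genotype and t-test every pair.

    Undefined ratios (flagged records) are excluded.  Pairs are compared
    with a two-tailed pooled-variance Student's t-test; a pair with fewer
    than 2 defined ratios on either side is skipped with a warning.  Two
    groups with identical constant values give p = 1 (degenerate rule).
    """
    table = ratio_table(records, group_of=group_of, mode=mode)
    table = table[table["defined"]]
    groups: dict[str, list[float]] = {
        g: sorted(sub["ratio"].tolist()) for g, sub in table.groupby("genotype")
    }
    summary = {
        "mode": mode,
        "groups": {
            g: {"n": len(v), "ratios": v, "mean": sum(v) / len(v) if v else math.nan}
            for g, v in sorted(groups.items())
        },
        "pairwise_p": {},
    }
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                logger.warning("skipping pair (%s, %s): fewer than 2 defined ratios", a, b)
                continue
            p = one_tailed_t(groups[a], groups[b], tail="two-sided")
            summary["pairwise_p"][f"{a} vs {b}"] = p
    return summary


def load_roi_measurements(
    path: str | Path,
) -> tuple[list[ROIMeasurement], dict[str, str]]:
    """Read a measurement CSV (animal_id, genotype, rachis, edge1, edge2,
    background); returns the records and the animal -> genotype map."""
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    required = {"animal_id", "genotype", "rachis", "edge1", "edge2", "background"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table must have columns {sorted(required)}")
    records = [
        ROIMeasurement(
            animal_id=str(r.animal_id),
            rachis=float(r.rachis),
            edge1=float(r.edge1),
            edge2=float(r.edge2),
            background=float(r.background),
        )
        for r in df.itertuples()
    ]
    group_of = {str(r.animal_id): str(r.genotype) for r in df.itertuples()}
    return records, group_of
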