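"""Spectral-count enrichment calling for proximity-labeling proteomics.

Proteins biotinylated by a TurboID bait fusion are affinity-purified and
identified by mass spectrometry; the evidence per protein is a spectral
count in each replicate.  A protein is called *enriched* when its mean
count in the bait strain exceeds the untagged-control mean by at least a
fold-change threshold (computed with a pseudo-count so that zero control
means stay finite) and a one-tailed two-sample t-test rejects at level
``alpha``.  Candidate lists from two baits are intersected to define the
shared neighborhood (Venn counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "EnrichmentConfig",
    "VennCounts",
    "group_means",
    "fold_change",
    "one_tailed_t",
    "call_enrichment",
    "intersect_enrichment",
    "load_count_matrix",
    "write_enrichment_table",
]

#: p-value reported for a zero-pooled-variance comparison whose mean
#: difference points in the tested direction (the t statistic diverges).
P_DEGENERATE_EXTREME = 1e-300

GROUPS = ("bait", "control")
TAILS = ("greater", "less", "two-sided")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Replicate spectral counts (proteins x samples) with group labels.

    Parameters
    ----------
    counts
        Nonnegative matrix, rows indexed by protein id, columns by sample id.
    group_of
        Maps every sample id to ``"bait"`` or ``"control"``.
    replicate_of
        Maps every sample id to a positive replicate number.
    """

    counts: pd.DataFrame
    group_of: Mapping[str, str]
    replicate_of: Mapping[str, int]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("protein ids must be unique")
        if c.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        if (c.to_numpy() < 0).any():
            raise ValueError("spectral counts must be nonnegative")
        missing = [s for s in c.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for g in GROUPS:
            if len(self.samples(g)) < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")
        for s, r in self.replicate_of.items():
            if int(r) < 1:
                raise ValueError(f"replicate number for {s!r} must be >= 1")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of.get(s) == group]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds and statistical options for enrichment calling.

    Defaults reproduce the published procedure: pseudo-count 0.01 applied to
    the group means in the fold-change ratio, one-tailed pooled-variance
    Student's t-test on the raw replicate counts, and the call
    ``log2fc >= 3`` (fold change >= 8) with ``p < 0.05``.
    """

    pseudo_count: float = 0.01
    min_log2fc: float = 3.0
    alpha: float = 0.05
    tail: str = "greater"
    variance_model: str = "pooled"
    p_adjust: str = "none"
    pseudo_count_scope: str = "fold-change-only"
    normalize_totals: bool = False

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be > 0")
        if self.min_log2fc < 0:
            raise ValueError("min_log2fc must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        if self.variance_model not in ("pooled", "welch"):
            raise ValueError("variance_model must be 'pooled' or 'welch'")
        if self.p_adjust not in ("none", "benjamini-hochberg"):
            raise ValueError("p_adjust must be 'none' or 'benjamini-hochberg'")
        if self.pseudo_count_scope not in ("fold-change-only", "fold-change-and-test"):
            raise ValueError(
                "pseudo_count_scope must be 'fold-change-only' or 'fold-change-and-test'"
            )


@dataclass(frozen=True)
class VennCounts:
    """Two-set intersection summary; ``union = only_a + only_b + both``."""

    only_a: int
    only_b: int
    both: int

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.both

    def to_dict(self) -> dict[str, int]:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "both": self.both,
            "union": self.union,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def group_means(matrix: CountMatrix) -> pd.DataFrame:
    """Per-protein arithmetic mean count in the bait and control groups.

    Returns a frame indexed by protein id with columns ``mean_bait`` and
    ``mean_control``.
    """
    out = pd.DataFrame(
        {
            "mean_bait": matrix.counts[matrix.samples("bait")].mean(axis=1),
            "mean_control": matrix.counts[matrix.samples("control")].mean(axis=1),
        }
    )
    out.index.name = "protein_id"
    return out


def fold_change(
    mean_bait: float, mean_control: float, pseudo_count: float = 0.01
) -> tuple[float, float]:
    """Pseudo-counted fold change and its log2.

    ``fc = (mean_bait + c) / (mean_control + c)``; the pseudo-count ``c``
    keeps the ratio finite when the control mean is zero.
    """
    if mean_bait < 0 or mean_control < 0:
        raise ValueError("group means must be nonnegative")
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be > 0")
    fc = (mean_bait + pseudo_count) / (mean_control + pseudo_count)
    return fc, math.log2(fc)


def _t_pvalues(
    bait: np.ndarray,
    control: np.ndarray,
    tail: str = "greater",
    variance_model: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test p-values for row-paired matrices.

    Rows of ``bait`` (P x n1) are tested against rows of ``control``
    (P x n2).  Computed from the closed-form t statistic; degenerate rows
    (zero pooled variance) follow the limit of the statistic: p = 1 when the
    difference is zero or opposes the tested tail, and an extreme p
    (:data:`P_DEGENERATE_EXTREME`) when it points into the tail.

    Returns ``(p_values, degenerate_mask)``.
    """
    bait = np.atleast_2d(np.asarray(bait, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = bait.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 replicates")

    m1, m2 = bait.mean(axis=1), control.mean(axis=1)
    v1, v2 = bait.var(axis=1, ddof=1), control.var(axis=1, ddof=1)
    diff = m1 - m2

    if variance_model == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(diff, float(n1 + n2 - 2))
    else:  # welch
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )

    degenerate = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)

    if tail == "greater":
        p = stats.t.sf(t, df)
        p_deg = np.where(diff > 0, P_DEGENERATE_EXTREME, 1.0)
    elif tail == "less":
        p = stats.t.cdf(t, df)
        p_deg = np.where(diff < 0, P_DEGENERATE_EXTREME, 1.0)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p_deg = np.where(diff != 0, P_DEGENERATE_EXTREME, 1.0)

    p = np.where(degenerate, p_deg, p)
    return np.clip(p, 0.0, 1.0), degenerate


def one_tailed_t(
    bait_reps: Iterable[float],
    control_reps: Iterable[float],
    tail: str = "greater",
    variance_model: str = "pooled",
) -> float:
    """Two-sample t-test p-value for one protein's replicate counts.

    ``tail="greater"`` tests bait > control (P(T >= t) under H0) on the
    pooled-variance Student statistic with df = n1 + n2 - 2.  Zero-variance
    inputs follow the degenerate rules described in :func:`_t_pvalues`.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    b = np.asarray(list(bait_reps), dtype=float)
    c = np.asarray(list(control_reps), dtype=float)
    if b.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    p, _ = _t_pvalues(b[None, :], c[None, :], tail=tail, variance_model=variance_model)
    return float(p[0])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def call_enrichment(matrix: CountMatrix, config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Score every protein and flag the significantly enriched set.

    Returns the enrichment table, sorted by protein id, with columns
    ``mean_bait, mean_control, fold_change, log2fc, p_value, neg_log10_p,
    p_adjusted, degenerate, enriched``.  ``enriched`` is True when
    ``log2fc >= min_log2fc`` (inclusive) and ``p_value < alpha`` (strict).
    ``neg_log10_p`` and ``log2fc`` are the volcano-plot coordinates.
    """
    config = config or EnrichmentConfig()
    counts = matrix.counts
    if config.normalize_totals:
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("total-count scaling requires positive sample totals")
        counts = counts * (totals.mean() / totals)

    bait = counts[matrix.samples("bait")].to_numpy(dtype=float)
    control = counts[matrix.samples("control")].to_numpy(dtype=float)

    mean_bait = bait.mean(axis=1)
    mean_control = control.mean(axis=1)
    c = config.pseudo_count
    fc = (mean_bait + c) / (mean_control + c)
    log2fc = np.log2(fc)

    if config.pseudo_count_scope == "fold-change-and-test":
        bait_t, control_t = bait + c, control + c
    else:
        bait_t, control_t = bait, control
    p, degenerate = _t_pvalues(
        bait_t, control_t, tail=config.tail, variance_model=config.variance_model
    )
    p_adj = _bh_adjust(p) if config.p_adjust == "benjamini-hochberg" else np.full_like(p, np.nan)

    table = pd.DataFrame(
        {
            "mean_bait": mean_bait,
            "mean_control": mean_control,
            "fold_change": fc,
            "log2fc": log2fc,
            "p_value": p,
            "neg_log10_p": -np.log10(np.maximum(p, P_DEGENERATE_EXTREME)),
            "p_adjusted": p_adj,
            "degenerate": degenerate,
            "enriched": (log2fc >= config.min_log2fc) & (p < config.alpha),
        },
        index=counts.index,
    )
    table.index.name = "protein_id"
    return table.sort_index(kind="mergesort")


def enriched_ids(table: pd.DataFrame) -> set[str]:
    """Protein ids flagged enriched in an enrichment table."""
    return set(table.index[table["enriched"]])


def intersect_enrichment(enriched_a: Iterable[str], enriched_b: Iterable[str]) -> VennCounts:
    """Exact two-set Venn counts of the candidate lists of two baits."""
    a, b = set(enriched_a), set(enriched_b)
    both = a & b
    return VennCounts(only_a=len(a - b), only_b=len(b - a), both=len(both))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a counts table (first column protein_id) and its sample sheet.

    The sample sheet is TSV with columns ``sample_id, group, replicate``;
    ``group`` is ``bait`` or ``control``.  Separators are sniffed from the
    file extension (``.csv`` -> comma, otherwise tab).
    """
    counts = pd.read_csv(counts_path, sep=_sep(counts_path), index_col=0)
    counts.index = counts.index.astype(str)
    sheet = pd.read_csv(samples_path, sep=_sep(samples_path), dtype={"sample_id": str})
    required = {"sample_id", "group", "replicate"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    sheet = sheet.set_index("sample_id")
    counts = counts[[s for s in counts.columns if s in sheet.index]]
    return CountMatrix(
        counts=counts,
        group_of=sheet["group"].to_dict(),
        replicate_of=sheet["replicate"].astype(int).to_dict(),
    )


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.10g")


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"
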