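"""Intrinsic-disorder summaries and the target-vs-random-control comparison.

Membraneless condensates are rich in intrinsically disordered regions, so a
candidate granule proteome is expected to be more disordered than the
proteome at large.  Per-residue disorder scores in [0, 1] (e.g., IUPred
output, consumed here as input, one value per residue) are collapsed to a
per-protein mean — total score divided by protein length, computed on the
longest isoform per gene — and the candidate set's mean-disorder values are
compared to a size-matched random draw from the remaining proteome with a
Wilcoxon rank-sum test.

The rank-sum test is implemented here with an exact small-sample path
(enumeration of the null rank-sum distribution by subset-sum counting) and
a tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DisorderSummary",
    "WilcoxonResult",
    "DisorderComparison",
    "longest_isoform_filter",
    "mean_disorder",
    "summarize_residue_scores",
    "wilcoxon_rank_sum",
    "compare_to_random",
    "load_residue_scores",
    "load_summary_table",
]

logger = logging.getLogger(__name__)

#: largest min-group size for which the exact rank-sum null is enumerated
EXACT_THRESHOLD = 8


@dataclass(frozen=True)
class DisorderSummary:
    """Per-protein disorder summary: length L, total score, mean = total/L."""

    protein_id: str
    length: int
    total: float
    mean: float


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank-sum W of the first sample
    p_value: float
    method: str  # "exact" | "normal" | "degenerate"
    degenerate: bool = False


@dataclass(frozen=True)
class DisorderComparison:
    """Result of comparing a target set to seeded random controls."""

    target_n: int
    control_n: int
    statistic: float
    p_value: float
    median_target: float
    median_control: float
    seed: int
    alternative: str
    n_draws: int
    draws: tuple[dict, ...]

    def to_dict(self) -> dict:
        return {
            "target_n": self.target_n,
            "control_n": self.control_n,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "median_target": self.median_target,
            "median_control": self.median_control,
            "seed": self.seed,
            "alternative": self.alternative,
            "n_draws": self.n_draws,
            "draws": list(self.draws),
        }


# ---------------------------------------------------------------------------
# isoform selection and per-protein summaries
# ---------------------------------------------------------------------------

def longest_isoform_filter(records, gene_of: Mapping[str, str] | Callable[[object], str]):
    """Keep one record per gene: the longest isoform, ties by smallest id.

    ``records`` is an iterable of Bio.SeqRecord objects; ``gene_of`` maps a
    record id (or, if callable, the record itself) to its gene.  Records
    with empty sequences are skipped with a warning.  Returns records
    ordered by gene name.
    """
    best: dict[str, object] = {}
    for rec in records:
        if len(rec.seq) == 0:
            logger.warning("skipping %s: empty sequence", rec.id)
            continue
        gene = gene_of(rec) if callable(gene_of) else gene_of[rec.id]
        cur = best.get(gene)
        # longer wins; at equal length the lexicographically smaller id wins
        if (
            cur is None
            or len(rec.seq) > len(cur.seq)
            or (len(rec.seq) == len(cur.seq) and rec.id < cur.id)
        ):
            best[gene] = rec
    return [best[g] for g in sorted(best)]


def mean_disorder(protein_id: str, scores: Sequence[float]) -> DisorderSummary:
    """Summarize one protein's per-residue scores to total and mean."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError(f"{protein_id}: empty score vector")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"{protein_id}: disorder scores must lie in [0, 1]")
    total = float(arr.sum())
    return DisorderSummary(
        protein_id=protein_id, length=int(arr.size), total=total, mean=total / arr.size
    )


def summarize_residue_scores(scores: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-protein summary frame (length, total, mean) indexed by protein id."""
    rows = [mean_disorder(pid, s) for pid, s in scores.items()]
    df = pd.DataFrame(
        {
            "length": [r.length for r in rows],
            "total": [r.total for r in rows],
            "mean": [r.mean for r in rows],
        },
        index=pd.Index([r.protein_id for r in rows], name="protein_id"),
    )
    return df.sort_index(kind="mergesort")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_ranksum_cdf(n: int, total: int, w: int) -> float:
    """P(W <= w) for the sum W of a uniform n-subset of ranks {1..total}.

    Counts subsets by dynamic programming over (subset size, rank sum).
    """
    max_sum = sum(range(total - n + 1, total + 1))
    # ways[k, s] = number of k-subsets of the ranks seen so far with sum s
    ways = np.zeros((n + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for j in range(1, total + 1):
        for k in range(min(n, j), 0, -1):
            ways[k, j:] += ways[k - 1, : max_sum + 1 - j]
    dist = ways[n]
    return float(dist[: min(w, max_sum) + 1].sum() / dist.sum())


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_threshold: int = EXACT_THRESHOLD,
) -> WilcoxonResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two samples.

    The statistic is the rank sum W of ``x`` with midranks for ties.  When
    ``min(len(x), len(y)) <= exact_threshold`` and there are no ties the
    p-value is exact (full enumeration of the null rank-sum distribution);
    otherwise a normal approximation with tie correction and continuity
    correction is used.  Two identical samples (no separation possible)
    return p = 1 with a degenerate flag.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")

    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())

    if np.unique(pooled).size == 1:
        return WilcoxonResult(statistic=w, p_value=1.0, method="degenerate", degenerate=True)

    has_ties = np.unique(pooled).size < pooled.size
    total = n + m

    if min(n, m) <= exact_threshold and not has_ties:
        wi = int(round(w))
        lo = _exact_ranksum_cdf(n, total, wi)  # P(W <= w)
        hi = 1.0 - _exact_ranksum_cdf(n, total, wi - 1)  # P(W >= w)
        if alternative == "greater":
            p = hi
        elif alternative == "less":
            p = lo
        else:
            p = min(1.0, 2.0 * min(lo, hi))
        return WilcoxonResult(statistic=w, p_value=p, method="exact")

    mean_w = n * (total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (total * (total - 1))
    var_w = n * m / 12.0 * ((total + 1) - tie_term)
    if var_w <= 0:
        return WilcoxonResult(statistic=w, p_value=1.0, method="degenerate", degenerate=True)
    sd = math.sqrt(var_w)
    if alternative == "greater":
        p = stats.norm.sf((w - mean_w - 0.5) / sd)
    elif alternative == "less":
        p = stats.norm.cdf((w - mean_w + 0.5) / sd)
    else:
        p = 2.0 * stats.norm.sf((abs(w - mean_w) - 0.5) / sd)
    return WilcoxonResult(statistic=w, p_value=float(min(1.0, max(p, 0.0))), method="normal")


# ---------------------------------------------------------------------------
# target vs random control
# ---------------------------------------------------------------------------

def compare_to_random(
    target_ids: Iterable[str],
    summaries: pd.DataFrame,
    seed: int,
    n_draws: int = 1,
    alternative: str = "two-sided",
    exclude_targets: bool = True,
) -> DisorderComparison:
    """Compare target mean disorder to size-matched seeded random controls.

    ``summaries`` is the per-protein summary frame (index protein_id, column
    ``mean``).  Each draw samples ``len(target)`` proteins uniformly without
    replacement from the proteome — by default excluding the targets, so the
    control cannot be diluted with target proteins; ``exclude_targets=False``
    restores naive whole-proteome sampling.  With ``n_draws > 1`` the
    reported p-value is the median across draws (per-draw results are kept);
    the reported statistic and control median come from the draw whose p is
    closest to that median.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    target = sorted(set(target_ids) & set(summaries.index))
    if len(target) < 2:
        raise ValueError("need at least 2 target proteins with disorder summaries")
    pool = summaries.index.difference(target) if exclude_targets else summaries.index
    pool = np.asarray(sorted(pool))
    if pool.size < len(target):
        raise ValueError(
            f"population ({pool.size}) smaller than target set ({len(target)})"
        )

    target_vals = summaries.loc[target, "mean"].to_numpy()
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        control = rng.choice(pool, size=len(target), replace=False)
        control_vals = summaries.loc[control, "mean"].to_numpy()
        res = wilcoxon_rank_sum(target_vals, control_vals, alternative=alternative)
        draws.append(
            {
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "median_control": float(np.median(control_vals)),
            }
        )

    p_values = np.array([d["p_value"] for d in draws])
    p_med = float(np.median(p_values))
    rep = draws[int(np.argmin(np.abs(p_values - p_med)))]
    return DisorderComparison(
        target_n=len(target),
        control_n=len(target),
        statistic=rep["statistic"],
        p_value=p_med,
        median_target=float(np.median(target_vals)),
        median_control=rep["median_control"],
        seed=seed,
        alternative=alternative,
        n_draws=n_draws,
        draws=tuple(draws),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_residue_scores(path: str | Path, mode: str = "unspecified") -> dict[str, np.ndarray]:
    """Read a long-format score table (protein_id, position, score).

    Positions are 1-based and must be complete (1..L with no gaps); a file
    with missing positions is rejected rather than imputed.  ``mode``
    records which disorder predictor flavor produced the scores (metadata
    only; attached to each array via a dict attribute is not possible, so it
    is returned for bookkeeping by callers that need it).
    """
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t")
    if not {"protein_id", "position", "score"}.issubset(df.columns):
        raise ValueError("score table must have columns protein_id, position, score")
    out: dict[str, np.ndarray] = {}
    for pid, sub in df.groupby("protein_id", sort=True):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"{pid}: positions must be exactly 1..L with no gaps")
        scores = sub["score"].to_numpy(dtype=float)
        if (scores < 0).any() or (scores > 1).any():
            raise ValueError(f"{pid}: disorder scores must lie in [0, 1]")
        out[str(pid)] = scores
    return out


def load_summary_table(path: str | Path) -> pd.DataFrame:
    """Read a per-protein summary TSV (protein_id, length, total, mean)."""
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t")
    if not {"protein_id", "mean"}.issubset(df.columns):
        raise ValueError("summary table must have columns protein_id, mean")
    df = df.set_index("protein_id")
    df.index = df.index.astype(str)
    return df.sort_index(kind="mergesort")
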