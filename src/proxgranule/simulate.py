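"""Seeded synthetic data with the statistical structure the pipeline assumes.

Each generator is a pure function of a :class:`SimulationSpec` (seed
included); independent RNG sub-streams are derived from the master seed via
``numpy.random.SeedSequence`` spawn keys, so adding a generator never
perturbs another's stream.

The count model is a zero-inflated negative binomial: background
(contaminant) spectral counts have mean ``background_mean`` and variance
``m + dispersion * m**2`` (``dispersion -> 0`` recovers Poisson), and each
null/control observation independently drops to zero with probability
``detection_zero_prob`` (stochastic non-detection of low-abundance
proteins).  Planted enriched proteins draw their bait counts from the same
negative binomial at mean ``effect_fold * background_mean``, without the
detection dropout — abundant bait-proximal proteins do not vanish from the
identification list.  The model is this package's own; it is not fitted to
any real deposit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .enrichment import CountMatrix
from .imaging import ROIMeasurement
from .reference import ReferenceSets

__all__ = [
    "SimulationSpec",
    "simulate_counts",
    "simulate_bait_pair",
    "simulate_disorder",
    "simulate_reference",
    "simulate_roi",
    "write_bundle",
]

# fixed sub-stream ids; never reorder (would silently change all outputs)
_STREAMS = {
    "truth": 0,
    "counts_a": 1,
    "counts_b": 2,
    "disorder": 3,
    "reference": 4,
    "roi": 5,
}

#: default genotype -> planted rachis/edge ratio, emulating granule
#: dispersal phenotypes (wild type perinuclear, mutants dispersed)
DEFAULT_ROI_RATIOS = {
    "wild-type": 0.30,
    "eggd-1": 0.60,
    "eggd-2": 0.35,
    "eggd-1; eggd-2": 0.90,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults emulate a three-replicate TurboID bait vs untagged-control
    design: ~2,000 detected proteins, a low contaminant background of 5
    spectral counts, mild overdispersion, a 2% detection dropout, and a
    16-fold planted enrichment.  ``reference_overlap`` maps each curated
    granule set to ``(n_known, n_inside_enriched)``; the default reproduces
    the structure of a P-granule bait's recovery controls (18/20 P granule,
    2/2 Z granule, 0/11 Mutator foci).
    """

    seed: int
    n_proteins: int = 2000
    n_enriched: int = 100
    n_replicates: int = 3
    background_mean: float = 5.0
    dispersion: float = 0.1
    effect_fold: float = 16.0
    detection_zero_prob: float = 0.02
    disorder_shift: float = 0.2
    reference_overlap: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "P granule": (20, 18),
            "Z granule": (2, 2),
            "Mutator foci": (11, 0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_enriched < 0:
            raise ValueError("n_proteins >= 1 and n_enriched >= 0 required")
        if self.n_enriched > self.n_proteins:
            raise ValueError("n_enriched must not exceed n_proteins")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.background_mean <= 0 or self.dispersion <= 0:
            raise ValueError("background_mean and dispersion must be > 0")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must be > 1")
        if not 0 <= self.detection_zero_prob < 1:
            raise ValueError("detection_zero_prob must be in [0, 1)")

    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"SP{i:0{width}d}" for i in range(1, self.n_proteins + 1)]


def _rng(spec: SimulationSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAMS[stream],))
    )


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial draws parameterized by mean and overdispersion."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(float)


def _planted_ids(spec: SimulationSpec, rng: np.random.Generator, n: int) -> list[str]:
    ids = spec.protein_ids()
    chosen = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(chosen)]


def simulate_counts(
    spec: SimulationSpec, bait_name: str = "bait", stream: str = "counts_a"
) -> tuple[CountMatrix, dict[str, str]]:
    """One bait-vs-control count matrix plus per-protein truth labels.

    Returns ``(matrix, truth)`` where ``truth`` maps each protein id to
    ``"enriched"`` or ``"null"``.
    """
    enriched = set(_planted_ids(spec, _rng(spec, "truth"), spec.n_enriched))
    return _simulate_with_truth(spec, enriched, bait_name, stream)


def simulate_bait_pair(
    spec: SimulationSpec,
    n_enriched_a: int = 155,
    n_enriched_b: int = 127,
    n_shared: int = 78,
) -> tuple[CountMatrix, CountMatrix, dict[str, str], dict[str, str]]:
    """Two bait experiments with a planted overlap between enriched sets.

    Defaults plant the dual-bait structure of a P-granule labeling study:
    155 and 127 enriched proteins sharing 78.  Returns
    ``(matrix_a, matrix_b, truth_a, truth_b)``.
    """
    if n_shared > min(n_enriched_a, n_enriched_b):
        raise ValueError("n_shared cannot exceed either bait's enriched count")
    n_union = n_enriched_a + n_enriched_b - n_shared
    if n_union > spec.n_proteins:
        raise ValueError("combined enriched sets exceed n_proteins")

    rng = _rng(spec, "truth")
    union = _planted_ids(spec, rng, n_union)
    shared = list(union[:n_shared])
    only_a = union[n_shared : n_shared + (n_enriched_a - n_shared)]
    only_b = union[n_shared + (n_enriched_a - n_shared) :]
    set_a, set_b = set(shared + only_a), set(shared + only_b)

    mat_a, _ = _simulate_with_truth(spec, set_a, "glh1_turboid", "counts_a")
    mat_b, _ = _simulate_with_truth(spec, set_b, "deps1_turboid", "counts_b")
    ids = spec.protein_ids()
    truth_a = {pid: ("enriched" if pid in set_a else "null") for pid in ids}
    truth_b = {pid: ("enriched" if pid in set_b else "null") for pid in ids}
    return mat_a, mat_b, truth_a, truth_b


def _simulate_with_truth(
    spec: SimulationSpec, enriched: set[str], bait_name: str, stream: str
) -> tuple[CountMatrix, dict[str, str]]:
    """Counts for a fixed planted enriched set (shared-truth designs)."""
    ids = spec.protein_ids()
    rng = _rng(spec, stream)
    n, k = spec.n_proteins, spec.n_replicates
    control = _nb(rng, spec.background_mean, spec.dispersion, (n, k))
    bait = _nb(rng, spec.background_mean, spec.dispersion, (n, k))
    control[rng.random((n, k)) < spec.detection_zero_prob] = 0.0
    dropout_bait = rng.random((n, k)) < spec.detection_zero_prob
    enriched_mask = np.array([pid in enriched for pid in ids])
    bait[dropout_bait & ~enriched_mask[:, None]] = 0.0
    bait[enriched_mask] = _nb(
        rng,
        spec.effect_fold * spec.background_mean,
        spec.dispersion,
        (int(enriched_mask.sum()), k),
    )
    samples = [f"{bait_name}_{i}" for i in range(1, k + 1)] + [
        f"control_{i}" for i in range(1, k + 1)
    ]
    counts = pd.DataFrame(np.hstack([bait, control]), index=ids, columns=samples)
    counts.index.name = "protein_id"
    group_of = {s: ("bait" if s.startswith(bait_name) else "control") for s in samples}
    replicate_of = {s: int(s.rsplit("_", 1)[1]) for s in samples}
    matrix = CountMatrix(counts=counts, group_of=group_of, replicate_of=replicate_of)
    truth = {pid: ("enriched" if pid in enriched else "null") for pid in ids}
    return matrix, truth


def simulate_disorder(
    spec: SimulationSpec,
    target_ids: Iterable[str],
    mean_length: float = 400.0,
    length_sigma: float = 0.4,
    base_mean: float = 0.35,
    population_concentration: float = 6.0,
    residue_concentration: float = 10.0,
) -> dict[str, np.ndarray]:
    """Per-residue disorder scores for every simulated protein.

    Protein lengths are log-normal (median ``mean_length`` residues,
    log-sd ``length_sigma``, floor 30).  Each protein receives a latent mean
    disorder drawn from a Beta distribution centered at ``base_mean``
    (concentration ``population_concentration``, giving the proteome-wide
    spread of mean disorder); target proteins' latent means are shifted by
    ``spec.disorder_shift`` and clipped into (0.01, 0.99) with a warning.
    Residue scores are Beta draws around the latent mean.
    """
    targets = set(target_ids)
    ids = spec.protein_ids()
    unknown = targets - set(ids)
    if unknown:
        raise ValueError(f"target ids outside the simulated proteome: {sorted(unknown)[:5]}")

    rng = _rng(spec, "disorder")
    nu = population_concentration
    kappa = residue_concentration
    out: dict[str, np.ndarray] = {}
    clipped = 0
    lengths = np.maximum(
        30, np.round(np.exp(rng.normal(np.log(mean_length), length_sigma, len(ids))))
    ).astype(int)
    for pid, length in zip(ids, lengths):
        mu = rng.beta(base_mean * nu, (1 - base_mean) * nu)
        if pid in targets:
            shifted = mu + spec.disorder_shift
            mu = min(max(shifted, 0.01), 0.99)
            clipped += shifted != mu
        out[pid] = rng.beta(mu * kappa, (1 - mu) * kappa, size=length)
    if clipped:
        logging.getLogger(__name__).warning(
            "disorder_shift pushed %d latent means outside (0,1); clipped", clipped
        )
    return out


def simulate_reference(
    spec: SimulationSpec, truth: Mapping[str, str]
) -> ReferenceSets:
    """Curated-style reference sets with configured overlap vs the truth.

    For each granule, ``(n_known, n_in)`` members are drawn without
    replacement: ``n_in`` from the enriched truth set and the rest from the
    null proteins; sets are mutually disjoint, like real curated lists.
    """
    rng = _rng(spec, "reference")
    enriched_pool = sorted(pid for pid, lab in truth.items() if lab == "enriched")
    null_pool = sorted(pid for pid, lab in truth.items() if lab == "null")
    need_in = sum(v[1] for v in spec.reference_overlap.values())
    need_out = sum(v[0] - v[1] for v in spec.reference_overlap.values())
    if need_in > len(enriched_pool) or need_out > len(null_pool):
        raise ValueError("requested reference overlap exceeds available proteins")
    for name, (n_known, n_in) in spec.reference_overlap.items():
        if n_in > n_known:
            raise ValueError(f"{name}: overlap {n_in} exceeds set size {n_known}")

    enriched_pool = list(rng.permutation(enriched_pool))
    null_pool = list(rng.permutation(null_pool))
    sets = {}
    for name in sorted(spec.reference_overlap):
        n_known, n_in = spec.reference_overlap[name]
        members = [enriched_pool.pop() for _ in range(n_in)]
        members += [null_pool.pop() for _ in range(n_known - n_in)]
        sets[name] = frozenset(members)
    return ReferenceSets(sets=sets, provenance="synthetic")


def simulate_roi(
    spec: SimulationSpec,
    group_ratios: Mapping[str, float] | None = None,
    n_animals: int = 4,
    edge_signal: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
) -> tuple[list[ROIMeasurement], dict[str, str]]:
    """ROI mean-intensity records as planted signal + background + noise.

    Each animal's true edge signal is ``edge_signal`` above background and
    its rachis signal is ``ratio * edge_signal`` above background, so with
    ``noise_sd = 0`` the symmetric-mode ratio recovers the planted value
    exactly.  Returns the records and the animal -> genotype map.
    """
    ratios = dict(group_ratios or DEFAULT_ROI_RATIOS)
    rng = _rng(spec, "roi")
    records, group_of = [], {}
    for genotype in sorted(ratios):
        ratio = ratios[genotype]
        for i in range(1, n_animals + 1):
            animal = f"{genotype.replace(' ', '')}_{i}"
            noise = rng.normal(0.0, noise_sd, size=4) if noise_sd > 0 else np.zeros(4)
            records.append(
                ROIMeasurement(
                    animal_id=animal,
                    rachis=max(0.0, ratio * edge_signal + background + noise[0]),
                    edge1=max(0.0, edge_signal + background + noise[1]),
                    edge2=max(0.0, edge_signal + background + noise[2]),
                    background=max(0.0, background + noise[3]),
                )
            )
            group_of[animal] = genotype
    return records, group_of


def write_bundle(spec: SimulationSpec, outdir: str | Path, write_residue_scores: bool = False) -> dict[str, Path]:
    """Write a complete synthetic input bundle for the pipeline.

    Emits counts + sample sheets for two baits, truth labels, a per-protein
    disorder summary (optionally the long per-residue score table),
    reference lists, and ROI measurements.  Returns the path of each file.
    """
    from .disorder import summarize_residue_scores

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mat_a, mat_b, truth_a, truth_b = simulate_bait_pair(spec)
    for tag, mat in (("a", mat_a), ("b", mat_b)):
        p = out / f"counts_{tag}.tsv"
        mat.counts.to_csv(p, sep="\t", float_format="%.10g")
        paths[f"counts_{tag}"] = p
        sheet = pd.DataFrame(
            {
                "sample_id": list(mat.counts.columns),
                "group": [mat.group_of[s] for s in mat.counts.columns],
                "replicate": [mat.replicate_of[s] for s in mat.counts.columns],
            }
        )
        ps = out / f"samples_{tag}.tsv"
        sheet.to_csv(ps, sep="\t", index=False)
        paths[f"samples_{tag}"] = ps

    truth = pd.DataFrame(
        {
            "protein_id": spec.protein_ids(),
            "truth_a": [truth_a[p] for p in spec.protein_ids()],
            "truth_b": [truth_b[p] for p in spec.protein_ids()],
        }
    )
    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    shared = {p for p in spec.protein_ids() if truth_a[p] == truth_b[p] == "enriched"}
    scores = simulate_disorder(spec, shared)
    summary = summarize_residue_scores(scores)
    paths["disorder_summary"] = out / "disorder_summary.tsv"
    summary.to_csv(paths["disorder_summary"], sep="\t", float_format="%.10g")
    if write_residue_scores:
        long = pd.concat(
            [
                pd.DataFrame(
                    {"protein_id": pid, "position": np.arange(1, len(s) + 1), "score": s}
                )
                for pid, s in scores.items()
            ]
        )
        paths["residue_scores"] = out / "residue_scores.tsv"
        long.to_csv(paths["residue_scores"], sep="\t", index=False, float_format="%.6g")

    # recovery is scored against the union candidate list, so the planted
    # overlap is configured against the union truth: members counted as
    # "inside" come from either bait's enriched set, the rest from proteins
    # enriched in neither
    union_truth = {
        p: ("enriched" if "enriched" in (truth_a[p], truth_b[p]) else "null")
        for p in spec.protein_ids()
    }
    refs = simulate_reference(spec, union_truth)
    ref_rows = [
        {"protein_id": pid, "granule": name}
        for name in sorted(refs.sets)
        for pid in sorted(refs.sets[name])
    ]
    paths["reference"] = out / "reference.tsv"
    pd.DataFrame(ref_rows).to_csv(paths["reference"], sep="\t", index=False)

    records, group_of = simulate_roi(spec)
    roi = pd.DataFrame(
        [
            {
                "animal_id": m.animal_id,
                "genotype": group_of[m.animal_id],
                "rachis": m.rachis,
                "edge1": m.edge1,
                "edge2": m.edge2,
                "background": m.background,
            }
            for m in records
        ]
    )
    paths["roi"] = out / "roi.csv"
    roi.to_csv(paths["roi"], index=False, float_format="%.10g")
    return paths
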