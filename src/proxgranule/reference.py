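"""Recovery of curated germ-granule protein sets by candidate lists.

The C. elegans germ line hosts three adjacent perinuclear condensates —
P granules, Z granules, and Mutator foci — each with a short curated list
of known residents.  Scoring what fraction of each list the
proximity-labeling candidates recover is the positive/negative control for
the bait's labeling neighborhood: a P-granule bait should recover most
P-granule and Z-granule proteins (the two compartments touch) and no
Mutator-foci proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ReferenceSets",
    "GranuleRecovery",
    "RecoveryReport",
    "recovery",
    "harmonize_ids",
    "load_reference_sets",
    "load_alias_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceSets:
    """Named granule -> set of member protein ids, plus a provenance label."""

    sets: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, ids in self.sets.items():
            if any(not str(i) for i in ids):
                raise ValueError(f"empty protein id in reference set {name!r}")


@dataclass(frozen=True)
class GranuleRecovery:
    granule: str
    n_known: int
    n_recovered: int
    fraction: float
    recovered_ids: tuple[str, ...]
    missed_ids: tuple[str, ...]
    empty_reference: bool = False


@dataclass(frozen=True)
class RecoveryReport:
    """Per-granule recovery, sorted by granule name."""

    entries: tuple[GranuleRecovery, ...]

    def __getitem__(self, granule: str) -> GranuleRecovery:
        for e in self.entries:
            if e.granule == granule:
                return e
        raise KeyError(granule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "granule": e.granule,
                    "n_known": e.n_known,
                    "n_recovered": e.n_recovered,
                    "fraction": e.fraction,
                    "recovered_ids": ",".join(e.recovered_ids),
                    "missed_ids": ",".join(e.missed_ids),
                }
                for e in self.entries
            ]
        )

    def to_dict(self) -> dict:
        return {
            e.granule: {
                "n_known": e.n_known,
                "n_recovered": e.n_recovered,
                "fraction": e.fraction,
                "recovered_ids": list(e.recovered_ids),
                "missed_ids": list(e.missed_ids),
            }
            for e in self.entries
        }


def recovery(candidates: Iterable[str], references: ReferenceSets) -> RecoveryReport:
    """Fraction of each curated granule set present among the candidates.

    An empty reference set is reported with ``fraction = 0`` and an
    ``empty_reference`` warning flag rather than raising.
    """
    cand = set(candidates)
    entries = []
    for granule in sorted(references.sets):
        known = set(references.sets[granule])
        if not known:
            logger.warning("reference set %r is empty; fraction undefined, set to 0", granule)
            entries.append(
                GranuleRecovery(granule, 0, 0, 0.0, (), (), empty_reference=True)
            )
            continue
        hit = known & cand
        entries.append(
            GranuleRecovery(
                granule=granule,
                n_known=len(known),
                n_recovered=len(hit),
                fraction=len(hit) / len(known),
                recovered_ids=tuple(sorted(hit)),
                missed_ids=tuple(sorted(known - hit)),
            )
        )
    return RecoveryReport(entries=tuple(entries))


def _resolve(alias_map: Mapping[str, str], name: str) -> str:
    """Follow an alias chain to its canonical id, rejecting cycles."""
    seen = [name]
    while name in alias_map:
        name = alias_map[name]
        if name in seen:
            raise ValueError(f"alias cycle detected: {' -> '.join(seen + [name])}")
        seen.append(name)
    return name


def harmonize_ids(
    candidates: Iterable[str],
    references: ReferenceSets,
    alias_map: Mapping[str, str] | None = None,
    uppercase: bool = True,
) -> tuple[set[str], ReferenceSets]:
    """Map candidate and reference ids into one canonical namespace.

    Aliases are resolved transitively (a cycle is an error); ids without an
    alias pass through unchanged.  With ``uppercase`` (the default) ids are
    case-folded to upper case after aliasing, since C. elegans gene and
    protein symbols differ only in case (pgl-1 vs PGL-1).
    """
    alias_map = dict(alias_map or {})

    def canon(i: str) -> str:
        out = _resolve(alias_map, str(i))
        return out.upper() if uppercase else out

    mapped_candidates = {canon(i) for i in candidates}
    mapped_sets = {
        name: frozenset(canon(i) for i in ids) for name, ids in references.sets.items()
    }
    return mapped_candidates, ReferenceSets(sets=mapped_sets, provenance=references.provenance)


def load_reference_sets(path: str | Path, provenance: str = "") -> ReferenceSets:
    """Read a reference TSV with columns ``protein_id, granule``."""
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t", dtype=str)
    if not {"protein_id", "granule"}.issubset(df.columns):
        raise ValueError("reference table must have columns protein_id, granule")
    sets = {
        granule: frozenset(sub["protein_id"])
        for granule, sub in df.groupby("granule")
    }
    return ReferenceSets(sets=sets, provenance=provenance or str(path))


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read an alias TSV with columns ``alias, canonical``.

    The same alias mapping to two different canonical ids is an error.
    """
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t", dtype=str)
    if not {"alias", "canonical"}.issubset(df.columns):
        raise ValueError("alias table must have columns alias, canonical")
    conflicts = df.groupby("alias")["canonical"].nunique()
    bad = list(conflicts[conflicts > 1].index)
    if bad:
        raise ValueError(f"conflicting aliases: {bad}")
    return dict(zip(df["alias"], df["canonical"]))
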