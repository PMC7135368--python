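"""Ensemble and chemotype-subset enrichment.

Docking against a single rigid binding-site model cannot capture induced
fit.  A cheap alternative is to screen an ensemble of models of the same
receptor and give each compound its best (lowest) docking energy across the
members, then score the merged table like a single screen.  Chemotype-subset
enrichment rescoreds a screen counting only a named subset of the ligands
(e.g. compounds similar to a template's co-crystallized ligand) against the
full decoy background, exposing template-induced chemotype bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .enrichment import (
    DEFAULT_LAMBDA,
    EnrichmentResult,
    InvalidScreenError,
    ScoreRecord,
    ScreenTable,
    alogauc,
    build_roc,
)

__all__ = [
    "EnsembleMismatchError",
    "InvalidSubsetError",
    "ChemotypeSet",
    "merge_best_score",
    "ensemble_enrichment",
    "subset_enrichment",
]


class EnsembleMismatchError(ValueError):
    """Member screens do not share one compound universe."""


class InvalidSubsetError(ValueError):
    """Chemotype subset has no usable ligands in the screen."""


@dataclass(frozen=True)
class ChemotypeSet:
    """Named subset of ligand compound ids (e.g. one chemotype)."""

    name: str
    ligand_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_ids", frozenset(self.ligand_ids))
        if not self.ligand_ids:
            raise InvalidSubsetError(f"chemotype set {self.name!r} is empty")


def merge_best_score(
    screens: list[ScreenTable], ensemble_id: str = "ensemble"
) -> ScreenTable:
    """Best-score merge of screens sharing one compound universe.

    Per compound the merged score is the minimum (most favourable energy)
    over members where the compound docked; the merged record is docked if
    it docked anywhere.  Compounds undocked in every member stay undocked.
    """
    if not screens:
        raise EnsembleMismatchError("need at least one member screen")
    universe = {r.compound_id: r.is_ligand for r in screens[0].records}
    for s in screens[1:]:
        other = {r.compound_id: r.is_ligand for r in s.records}
        if other != universe:
            mismatched = sorted(set(other.items()) ^ set(universe.items()))
            raise EnsembleMismatchError(
                f"compound universes differ between members; offending ids: "
                f"{[cid for cid, _ in mismatched][:10]}"
            )
    best: dict[str, float] = {}
    docked_any: dict[str, bool] = {cid: False for cid in universe}
    for s in screens:
        for r in s.records:
            if not r.docked:
                continue
            docked_any[r.compound_id] = True
            if r.compound_id not in best or r.score < best[r.compound_id]:
                best[r.compound_id] = r.score
    records = [
        ScoreRecord(
            compound_id=cid,
            is_ligand=is_lig,
            score=best.get(cid, math.nan),
            docked=docked_any[cid],
            model_id=ensemble_id,
        )
        for cid, is_lig in universe.items()
    ]
    return ScreenTable(records=records, model_id=ensemble_id)


def ensemble_enrichment(
    screens: list[ScreenTable],
    lam: float = DEFAULT_LAMBDA,
    ensemble_id: str = "ensemble",
) -> EnrichmentResult:
    """aLogAUC of the best-score merged ensemble table."""
    merged = merge_best_score(screens, ensemble_id=ensemble_id)
    return alogauc(build_roc(merged), lam, model_id=ensemble_id)


def subset_enrichment(
    screen: ScreenTable, subset: ChemotypeSet, lam: float = DEFAULT_LAMBDA
) -> EnrichmentResult:
    """aLogAUC counting only subset members as ligands.

    All decoys are retained; ligands outside the subset are removed from
    both numerator and denominator (they are known actives, so recasting
    them as decoys would contaminate the negative set).
    """
    ligand_ids = {r.compound_id for r in screen.records if r.is_ligand}
    usable = subset.ligand_ids & ligand_ids
    if not usable:
        raise InvalidSubsetError(
            f"chemotype set {subset.name!r} shares no ligand with screen "
            f"{screen.model_id!r}"
        )
    records = [
        r
        for r in screen.records
        if (not r.is_ligand) or (r.compound_id in usable)
    ]
    filtered = ScreenTable(records=records, model_id=screen.model_id)
    result = alogauc(build_roc(filtered), lam, model_id=screen.model_id)
    return result
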