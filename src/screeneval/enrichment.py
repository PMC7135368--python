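"""Semi-log ROC enrichment metrics for retrospective virtual screens.

A retrospective screen docks a library of known ligands and property-matched
decoys against one binding-site model and ranks every successfully docked
compound by predicted binding energy (lower = better).  Enrichment is judged
from the receiver operating characteristic (ROC) curve — the fraction of
ligands retrieved as a function of the fraction of decoys retrieved — but
integrated on a logarithmic decoy-fraction axis so that early retrieval
dominates the score:

    logAUC = 100 * (integral_{lambda}^{1} TPR(x) dlog10 x) / log10(1/lambda)

The adjusted value subtracts the same integral of the random diagonal
TPR(x) = x, so aLogAUC = 0 means random performance and positive values
mean early enrichment.  With the conventional lower bound lambda = 0.001 the
random baseline is 100*(1-lambda)/ln(1/lambda) ~= 14.47, and a model that
retrieves twice the random ligand fraction everywhere scores aLogAUC ~= 10.

Scores are energies: *lower is better* throughout this module.  Compounds
that failed to dock anywhere are retrieved last, as a single tied block, so
docking failures of ligands are penalized rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LAMBDA",
    "DEFAULT_BAND_EDGES",
    "DEFAULT_BAND_LABELS",
    "InvalidScreenError",
    "InvalidParameterError",
    "ScoreRecord",
    "ScreenTable",
    "ROCCurve",
    "EnrichmentResult",
    "build_roc",
    "logauc",
    "random_logauc",
    "alogauc",
    "classify_enrichment",
    "read_screens",
    "write_screens",
]

#: Lower bound of the log10 decoy-fraction axis.
DEFAULT_LAMBDA = 0.001

#: Band edges for the qualitative categories; the first edge is exclusive
#: below ("< 10" is poor) and every further edge is upper-inclusive, so
#: 10 and 15 are "fair", 20 is "good" and 25 is "very good".
DEFAULT_BAND_EDGES = (10.0, 15.0, 20.0, 25.0)
DEFAULT_BAND_LABELS = ("poor", "fair", "good", "very good", "excellent")


class InvalidScreenError(ValueError):
    """The screen table violates its invariants."""


class InvalidParameterError(ValueError):
    """A metric parameter (e.g. lambda) is out of its domain."""


@dataclass(frozen=True)
class ScoreRecord:
    """One compound's docking outcome against one binding-site model."""

    compound_id: str
    is_ligand: bool
    score: float
    docked: bool = True
    model_id: str = ""


@dataclass
class ScreenTable:
    """Ligand/decoy score table for a single binding-site model.

    Invariants (checked by :meth:`validate`): at least one ligand and one
    decoy, unique compound ids, and finite scores for docked records.
    """

    records: list[ScoreRecord]
    model_id: str = ""

    def __post_init__(self) -> None:
        if not self.model_id and self.records:
            self.model_id = self.records[0].model_id
        self.validate()

    @property
    def n_ligands(self) -> int:
        return sum(1 for r in self.records if r.is_ligand)

    @property
    def n_decoys(self) -> int:
        return sum(1 for r in self.records if not r.is_ligand)

    def validate(self) -> None:
        if self.n_ligands < 1 or self.n_decoys < 1:
            raise InvalidScreenError(
                f"screen {self.model_id!r} needs >=1 ligand and >=1 decoy "
                f"(got {self.n_ligands} ligands, {self.n_decoys} decoys)"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.compound_id in seen:
                raise InvalidScreenError(
                    f"duplicate compound_id {r.compound_id!r} in screen {self.model_id!r}"
                )
            seen.add(r.compound_id)
            if r.docked and not math.isfinite(r.score):
                raise InvalidScreenError(
                    f"non-finite score for docked compound {r.compound_id!r}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "is_ligand": [r.is_ligand for r in self.records],
                "model_id": [r.model_id or self.model_id for r in self.records],
                "score": [r.score for r in self.records],
                "docked": [r.docked for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, model_id: str = "") -> "ScreenTable":
        records = [
            ScoreRecord(
                compound_id=str(row.compound_id),
                is_ligand=bool(row.is_ligand),
                score=float(row.score) if pd.notna(row.score) else math.nan,
                docked=bool(row.docked) if "docked" in frame.columns else True,
                model_id=str(row.model_id) if "model_id" in frame.columns else model_id,
            )
            for row in frame.itertuples()
        ]
        return cls(records=records, model_id=model_id)


@dataclass(frozen=True)
class ROCCurve:
    """Piecewise-linear ROC: ordered (decoy fraction, ligand fraction) points.

    Both coordinates are non-decreasing, starting at (0, 0) and ending at
    (1, 1).  Tied score blocks appear as single diagonal jumps.
    """

    points: np.ndarray  # shape (k, 2): columns fpr, tpr

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise InvalidScreenError("ROC curve needs >=2 (fpr, tpr) points")
        if not (np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)):
            raise InvalidScreenError("ROC coordinates must be non-decreasing")
        if not (np.allclose(pts[0], (0.0, 0.0)) and np.allclose(pts[-1], (1.0, 1.0))):
            raise InvalidScreenError("ROC curve must run from (0,0) to (1,1)")

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


@dataclass(frozen=True)
class EnrichmentResult:
    """logAUC/aLogAUC (percent scale) plus the qualitative band."""

    logauc: float
    alogauc: float
    category: str
    lam: float
    model_id: str = ""


def build_roc(table: ScreenTable) -> ROCCurve:
    """ROC curve of a screen, ranking docked compounds by ascending score.

    Compounds sharing an identical score form one tied block that advances
    the decoy and ligand fractions simultaneously; undocked compounds form a
    single final tied block.
    """
    table.validate()
    n_lig, n_dec = table.n_ligands, table.n_decoys
    docked = [r for r in table.records if r.docked]
    undocked = [r for r in table.records if not r.docked]

    points = [(0.0, 0.0)]
    cum_lig = cum_dec = 0
    docked.sort(key=lambda r: r.score)
    i = 0
    while i < len(docked):
        j = i
        while j < len(docked) and docked[j].score == docked[i].score:
            j += 1
        block = docked[i:j]
        cum_lig += sum(1 for r in block if r.is_ligand)
        cum_dec += sum(1 for r in block if not r.is_ligand)
        points.append((cum_dec / n_dec, cum_lig / n_lig))
        i = j
    if undocked:
        points.append((1.0, 1.0))
    return ROCCurve(points=np.array(points, dtype=float))


def random_logauc(lam: float = DEFAULT_LAMBDA) -> float:
    """logAUC of the random diagonal TPR(x) = x: 100*(1-lam)/ln(1/lam)."""
    _check_lambda(lam)
    return 100.0 * (1.0 - lam) / math.log(1.0 / lam)


def logauc(curve: ROCCurve, lam: float = DEFAULT_LAMBDA) -> float:
    """Semi-log AUC (percent) of a piecewise-linear ROC curve.

    The ROC is linearly interpolated between its points on the linear fpr
    axis, clamped at fpr = lam on the left, and integrated exactly against
    log10(fpr) segment by segment:

        integral (a + b*x) dln x = a*ln(x2/x1) + b*(x2 - x1)
    """
    _check_lambda(lam)
    pts = curve.points
    total = 0.0
    for k in range(len(pts) - 1):
        x1, y1 = pts[k]
        x2, y2 = pts[k + 1]
        if x2 <= lam or x2 == x1:
            continue  # left of the window, or a vertical jump (zero width)
        lo = max(x1, lam)
        b = (y2 - y1) / (x2 - x1)
        a = y1 - b * x1
        total += a * math.log(x2 / lo) + b * (x2 - lo)
    return 100.0 * total / math.log(1.0 / lam)


def classify_enrichment(
    value: float,
    edges: Sequence[float] = DEFAULT_BAND_EDGES,
    labels: Sequence[str] = DEFAULT_BAND_LABELS,
) -> str:
    """Qualitative enrichment band for an aLogAUC value.

    The lowest band is everything strictly below the first edge; every other
    edge is upper-inclusive, so with the default bands 10 -> fair, 15 ->
    fair, 20 -> good, 25 -> very good and anything above 25 -> excellent.
    """
    if len(labels) != len(edges) + 1:
        raise InvalidParameterError("need exactly one more label than edges")
    if not math.isfinite(value):
        raise InvalidParameterError("aLogAUC must be finite")
    for i, edge in enumerate(edges):
        if (value < edge) if i == 0 else (value <= edge):
            return labels[i]
    return labels[-1]


def alogauc(
    curve: ROCCurve,
    lam: float = DEFAULT_LAMBDA,
    model_id: str = "",
    edges: Sequence[float] = DEFAULT_BAND_EDGES,
    labels: Sequence[str] = DEFAULT_BAND_LABELS,
) -> EnrichmentResult:
    """Adjusted logAUC: logAUC minus the random-selection baseline."""
    la = logauc(curve, lam)
    adj = la - random_logauc(lam)
    return EnrichmentResult(
        logauc=la,
        alogauc=adj,
        category=classify_enrichment(adj, edges, labels),
        lam=lam,
        model_id=model_id,
    )


def screen_alogauc(table: ScreenTable, lam: float = DEFAULT_LAMBDA) -> EnrichmentResult:
    """Convenience: ROC construction + adjusted logAUC for one screen."""
    return alogauc(build_roc(table), lam, model_id=table.model_id)


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_screens(path_or_buf, sep: str = ",") -> dict[str, ScreenTable]:
    """Read score tables (one or several models) from delimited text.

    Expected header: compound_id, is_ligand, model_id, score, docked.
    Returns a mapping from model_id to its ScreenTable.
    """
    frame = pd.read_csv(path_or_buf, sep=sep)
    required = {"compound_id", "is_ligand", "model_id", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidScreenError(f"missing columns: {sorted(missing)}")
    if "docked" not in frame.columns:
        frame["docked"] = True
    out: dict[str, ScreenTable] = {}
    for model_id, grp in frame.groupby("model_id", sort=True):
        out[str(model_id)] = ScreenTable.from_frame(grp, model_id=str(model_id))
    return out


def write_screens(tables: Iterable[ScreenTable], path_or_buf, sep: str = ",") -> None:
    frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frame.to_csv(path_or_buf, sep=sep, index=False)


def _check_lambda(lam: float) -> None:
    if not (0.0 < lam < 1.0):
        raise InvalidParameterError(f"lambda must lie in (0, 1), got {lam}")
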