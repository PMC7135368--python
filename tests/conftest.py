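"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately use different code paths from the library: a
threshold-sweep ROC construction and a dense-grid midpoint quadrature on
the log axis, against which the exact per-segment integration is checked.
"""

from __future__ import annotations

import numpy as np
import pytest

from screeneval.enrichment import ROCCurve, ScoreRecord, ScreenTable


def logauc_quadrature(curve: ROCCurve, lam: float, n: int = 200001) -> float:
    """Fine-grid numeric quadrature of the interpolated ROC on the log axis.

    Midpoint rule on a uniform log10 grid augmented with the curve's
    breakpoints, so each interval lies inside one linear segment.
    """
    pts = curve.points
    u = np.linspace(np.log10(lam), 0.0, n)
    x = np.union1d(np.power(10.0, u), np.clip(pts[:, 0], lam, 1.0))
    x = x[(x >= lam * (1 - 1e-12)) & (x <= 1.0)]
    xm = np.sqrt(x[:-1] * x[1:])  # geometric midpoint = midpoint in log space
    y = np.interp(xm, pts[:, 0], pts[:, 1])
    du = np.diff(np.log10(x))
    return float(100.0 * np.sum(y * du) / (0.0 - np.log10(lam)))


def roc_threshold_sweep(table: ScreenTable) -> list[tuple[float, float]]:
    """Brute-force ROC by evaluating retrieval fractions at every threshold."""
    docked = [(r.score, r.is_ligand) for r in table.records if r.docked]
    n_l, n_d = table.n_ligands, table.n_decoys
    pts = [(0.0, 0.0)]
    for t in sorted({s for s, _ in docked}):
        fpr = sum(1 for s, lig in docked if s <= t and not lig) / n_d
        tpr = sum(1 for s, lig in docked if s <= t and lig) / n_l
        pts.append((fpr, tpr))
    if any(not r.docked for r in table.records):
        pts.append((1.0, 1.0))
    return pts


def random_small_table(rng: np.random.Generator, max_compounds: int = 50) -> ScreenTable:
    """Random screen with ties and occasional docking failures."""
    n_lig = int(rng.integers(1, max(2, max_compounds // 3)))
    n_dec = int(rng.integers(1, max_compounds - n_lig + 1))
    records = []
    for i in range(n_lig + n_dec):
        is_lig = i < n_lig
        docked = rng.random() > 0.1
        # coarse integer scores provoke tied blocks
        score = float(rng.integers(-15, 0)) if docked else float("nan")
        records.append(
            ScoreRecord(f"c{i:03d}", is_lig, score, docked, "rand")
        )
    return ScreenTable(records=records, model_id="rand")


@pytest.fixture(scope="session")
def toy_structure():
    from screeneval.synthetic import gen_toy_structure

    return gen_toy_structure(30)


@pytest.fixture(scope="session")
def toy_region_pair():
    from screeneval.synthetic import toy_regions

    return toy_regions(30)
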