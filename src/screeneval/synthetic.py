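"""Synthetic inputs with analytically known properties.

Every stage of the evaluation pipeline can be exercised without any
external data: score tables drawn from a two-Gaussian (binormal) model with
a closed-form ROC, correlated multi-model score ensembles, perturbed and
symmetry-relabelled structures, toy receptor-ligand complexes with exact
interaction geometry, and toy alignments with exact region identity.

The binormal score model: docked energies of ligands and decoys are
Normal(mu_ligand, sigma) and Normal(mu_decoy, sigma) respectively (lower =
better), so the population ROC is

    TPR(x) = Phi(Phi^{-1}(x) + (mu_decoy - mu_ligand)/sigma)

which an independent quadrature (``binormal_logauc_oracle``) integrates on
the log axis.  Default sizes mirror a large retrospective screen of a
biogenic-amine receptor: 822 ligands against 55,146 property-matched
decoys, with a one-sigma ligand/decoy separation that lands in the "good"
enrichment band.  Docking failures are off by default (the clean
statistical model); a nonzero ``dock_failure_rate`` marks compounds
undocked independently of their score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .enrichment import DEFAULT_LAMBDA, ScoreRecord, ScreenTable, random_logauc
from .poses import LigandPose, PoseAtom, SiteAnchors
from .sequences import PairwiseAlignment
from .structure import (
    AtomRecord,
    StructureModel,
    SYMMETRIC_ATOM_PAIRS,
)

__all__ = [
    "ScoreSimConfig",
    "EnsembleSimConfig",
    "gen_screen",
    "gen_ensemble",
    "binormal_logauc_oracle",
    "binormal_alogauc_oracle",
    "gen_toy_structure",
    "toy_regions",
    "gen_perturbed_structure",
    "gen_toy_complex",
    "toy_site_anchors",
    "gen_toy_alignment",
]


class SimParameterError(ValueError):
    """A simulation configuration value is out of its domain."""


@dataclass(frozen=True)
class ScoreSimConfig:
    """Binormal ligand/decoy score model for one screen."""

    n_ligands: int = 822
    n_decoys: int = 55146
    mu_ligand: float = -12.0  # kcal/mol-like docking energy
    mu_decoy: float = -10.0
    sigma: float = 2.0
    dock_failure_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise SimParameterError("sigma must be positive")
        if self.n_ligands < 1 or self.n_decoys < 1:
            raise SimParameterError("need >=1 ligand and >=1 decoy")
        if not 0.0 <= self.dock_failure_rate < 1.0:
            raise SimParameterError("dock_failure_rate must lie in [0, 1)")

    @property
    def separation(self) -> float:
        """Ligand/decoy mean separation in sigma units (positive = enriching)."""
        return (self.mu_decoy - self.mu_ligand) / self.sigma


@dataclass(frozen=True)
class EnsembleSimConfig:
    """Correlated multi-model score ensemble.

    Each compound has a latent score from the base binormal model; model m
    adds a scalar bias ~ N(0, model_bias_sd) and per-compound noise
    ~ N(0, within_model_noise_sd), giving an inter-model score correlation
    of latent_var / (latent_var + noise_var).
    """

    n_models: int = 50
    base: ScoreSimConfig = field(default_factory=ScoreSimConfig)
    model_bias_sd: float = 0.5
    within_model_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise SimParameterError("need >=1 model")
        if self.model_bias_sd < 0 or self.within_model_noise_sd < 0:
            raise SimParameterError("noise standard deviations must be >= 0")


def gen_screen(
    config: ScoreSimConfig,
    model_id: str = "m00",
    ligand_shifts: np.ndarray | None = None,
) -> ScreenTable:
    """One reproducible screen from the binormal score model.

    ``ligand_shifts`` (optional, length n_ligands) adds per-ligand mean
    offsets, e.g. to emulate chemotype-specific affinity for a template.
    """
    rng = np.random.default_rng(config.seed)
    lig_mu = np.full(config.n_ligands, config.mu_ligand)
    if ligand_shifts is not None:
        shifts = np.asarray(ligand_shifts, dtype=float)
        if shifts.shape != (config.n_ligands,):
            raise SimParameterError("ligand_shifts must have length n_ligands")
        lig_mu = lig_mu + shifts
    lig_scores = rng.normal(lig_mu, config.sigma)
    dec_scores = rng.normal(config.mu_decoy, config.sigma, config.n_decoys)
    n_total = config.n_ligands + config.n_decoys
    docked = rng.random(n_total) >= config.dock_failure_rate
    records = []
    for i, s in enumerate(lig_scores):
        d = bool(docked[i])
        records.append(
            ScoreRecord(f"lig{i:05d}", True, float(s) if d else math.nan, d, model_id)
        )
    for i, s in enumerate(dec_scores):
        d = bool(docked[config.n_ligands + i])
        records.append(
            ScoreRecord(f"dec{i:05d}", False, float(s) if d else math.nan, d, model_id)
        )
    return ScreenTable(records=records, model_id=model_id)


def gen_ensemble(config: EnsembleSimConfig) -> list[ScreenTable]:
    """Correlated screens of one compound universe against several models."""
    rng = np.random.default_rng(config.seed)
    base = config.base
    n_lig, n_dec = base.n_ligands, base.n_decoys
    n_total = n_lig + n_dec
    latent = np.concatenate(
        [
            rng.normal(base.mu_ligand, base.sigma, n_lig),
            rng.normal(base.mu_decoy, base.sigma, n_dec),
        ]
    )
    ids = [f"lig{i:05d}" for i in range(n_lig)] + [f"dec{i:05d}" for i in range(n_dec)]
    is_lig = [True] * n_lig + [False] * n_dec
    screens = []
    for m in range(config.n_models):
        model_id = f"m{m:02d}"
        bias = rng.normal(0.0, config.model_bias_sd) if config.model_bias_sd else 0.0
        noise = (
            rng.normal(0.0, config.within_model_noise_sd, n_total)
            if config.within_model_noise_sd
            else np.zeros(n_total)
        )
        scores = latent + bias + noise
        docked = rng.random(n_total) >= base.dock_failure_rate
        records = [
            ScoreRecord(
                ids[i],
                is_lig[i],
                float(scores[i]) if docked[i] else math.nan,
                bool(docked[i]),
                model_id,
            )
            for i in range(n_total)
        ]
        screens.append(ScreenTable(records=records, model_id=model_id))
    return screens


def binormal_logauc_oracle(
    mu_ligand: float,
    mu_decoy: float,
    sigma: float,
    lam: float = DEFAULT_LAMBDA,
    n_grid: int = 20001,
) -> float:
    """Population logAUC (percent) of the binormal model by quadrature.

    Integrates the analytic TPR(x) = Phi(Phi^{-1}(x) + d) on a uniform
    log10(x) grid over [lam, 1] with the trapezoidal rule — a code path
    independent of the empirical ROC machinery.
    """
    if sigma <= 0:
        raise SimParameterError("sigma must be positive")
    if not 0.0 < lam < 1.0:
        raise SimParameterError("lambda must lie in (0, 1)")
    d = (mu_decoy - mu_ligand) / sigma
    u = np.linspace(math.log10(lam), 0.0, n_grid)
    x = np.power(10.0, u)
    with np.errstate(divide="ignore"):
        tpr = norm.cdf(norm.ppf(x) + d)
    tpr[-1] = 1.0  # Phi(inf + d)
    return float(100.0 * np.trapezoid(tpr, u) / (0.0 - math.log10(lam)))


def binormal_alogauc_oracle(
    mu_ligand: float,
    mu_decoy: float,
    sigma: float,
    lam: float = DEFAULT_LAMBDA,
    n_grid: int = 20001,
) -> float:
    return binormal_logauc_oracle(mu_ligand, mu_decoy, sigma, lam, n_grid) - random_logauc(lam)


# ---------------------------------------------------------------------------
# structures

# Idealized-ish local atom offsets (Angstrom) relative to each residue's CA.
_BACKBONE_OFFSETS = {
    "N": (-1.20, 0.60, 0.00),
    "CA": (0.00, 0.00, 0.00),
    "C": (1.10, 0.80, 0.30),
    "O": (1.30, 1.95, 0.45),
}
_SIDECHAIN_OFFSETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "GLY": {},
    "ALA": {"CB": (0.20, -1.45, 0.45)},
    "SER": {"CB": (0.20, -1.45, 0.45), "OG": (0.10, -2.55, -0.35)},
    "VAL": {
        "CB": (0.20, -1.45, 0.45),
        "CG1": (-0.90, -2.35, 0.10),
        "CG2": (1.40, -2.20, 0.20),
    },
    "LEU": {
        "CB": (0.20, -1.45, 0.45),
        "CG": (0.25, -2.90, 0.30),
        "CD1": (-0.95, -3.65, 0.75),
        "CD2": (1.45, -3.55, -0.15),
    },
    "ASP": {
        "CB": (0.20, -1.45, 0.45),
        "CG": (0.20, -2.90, 0.20),
        "OD1": (-0.85, -3.60, 0.45),
        "OD2": (1.25, -3.45, -0.25),
    },
    "GLU": {
        "CB": (0.20, -1.45, 0.45),
        "CG": (0.25, -2.90, 0.30),
        "CD": (0.20, -4.30, 0.10),
        "OE1": (-0.90, -4.95, 0.35),
        "OE2": (1.25, -4.85, -0.30),
    },
    "ARG": {
        "CB": (0.20, -1.45, 0.45),
        "CG": (0.25, -2.90, 0.30),
        "CD": (0.20, -4.30, 0.10),
        "NE": (0.25, -5.55, 0.45),
        "CZ": (0.20, -6.80, 0.10),
        "NH1": (-0.90, -7.45, 0.40),
        "NH2": (1.30, -7.35, -0.30),
    },
    "PHE": {
        "CB": (0.20, -1.45, 0.45),
        "CG": (0.20, -2.90, 0.20),
        "CD1": (-1.00, -3.60, 0.30),
        "CD2": (1.40, -3.55, 0.05),
        "CE1": (-1.00, -5.00, 0.25),
        "CE2": (1.40, -4.95, 0.00),
        "CZ": (0.20, -5.65, 0.10),
    },
    "TYR": {
        "CB": (0.20, -1.45, 0.45),
        "CG": (0.20, -2.90, 0.20),
        "CD1": (-1.00, -3.60, 0.30),
        "CD2": (1.40, -3.55, 0.05),
        "CE1": (-1.00, -5.00, 0.25),
        "CE2": (1.40, -4.95, 0.00),
        "CZ": (0.20, -5.65, 0.10),
        "OH": (0.20, -7.00, 0.00),
    },
}
_TOY_SEQUENCE_CYCLE = (
    "ALA", "ASP", "PHE", "LEU", "VAL", "ARG", "GLU", "TYR", "SER", "GLY",
)


def gen_toy_structure(
    n_residues: int = 30, chain: str = "A", model_id: str = "toy"
) -> StructureModel:
    """Deterministic toy protein chain rich in symmetric side chains.

    Residues cycle through ten amino-acid types (including every residue
    with chemically equivalent atom pairs) along a gently curved backbone,
    3.8 A CA spacing.  Geometry is schematic, not stereochemically exact —
    sufficient for superposition, RMSD and relabelling tests.
    """
    if n_residues < 1:
        raise SimParameterError("need >=1 residue")
    atoms: list[AtomRecord] = []
    for i in range(n_residues):
        resname = _TOY_SEQUENCE_CYCLE[i % len(_TOY_SEQUENCE_CYCLE)]
        ca = np.array([3.8 * i, 1.5 * math.sin(0.6 * i), 1.5 * math.cos(0.6 * i)])
        offsets = dict(_BACKBONE_OFFSETS)
        offsets.update(_SIDECHAIN_OFFSETS[resname])
        for name, off in offsets.items():
            atoms.append(
                AtomRecord(chain, i + 1, resname, name, ca + np.asarray(off))
            )
    return StructureModel(atoms, model_id=model_id)


def toy_regions(
    n_residues: int = 30, chain: str = "A"
) -> tuple["RegionDefinition", "RegionDefinition"]:
    """(TM, BS) region pair for a toy chain: all residues / a central third."""
    from .structure import RegionDefinition

    tm = RegionDefinition("TM", frozenset((chain, i + 1) for i in range(n_residues)))
    lo, hi = n_residues // 3, max(n_residues // 3 * 2, n_residues // 3 + 1)
    bs = RegionDefinition("BS", frozenset((chain, i + 1) for i in range(lo, hi)))
    return tm, bs.restricted_to(tm)


def gen_perturbed_structure(
    base: StructureModel,
    sigma: float,
    relabel_symmetric: bool = False,
    seed: int = 0,
    relabel_probability: float = 0.5,
    model_id: str | None = None,
) -> StructureModel:
    """IID Gaussian displacement per heavy atom, optional symmetry relabel.

    With ``relabel_symmetric``, residues carrying chemically equivalent
    atom pairs are chosen at random (per-residue Bernoulli) and their
    symmetric labels swapped jointly *without moving coordinates* — a pure
    nomenclature flip that only symmetry-aware RMSD forgives.
    """
    if sigma < 0:
        raise SimParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    coords = base.coords()
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma, coords.shape)
    model = base.with_coords(coords, model_id=model_id or f"{base.model_id}_pert")
    if not relabel_symmetric:
        return model
    swap_by_residue: dict[tuple[str, int], dict[str, str]] = {}
    for key in model.residue_keys:
        res = model.residue(*key)
        pairs = SYMMETRIC_ATOM_PAIRS.get(res["resname"])
        if pairs and rng.random() < relabel_probability:
            swap: dict[str, str] = {}
            for a, b in pairs:
                swap[a], swap[b] = b, a
            swap_by_residue[key] = swap
    atoms = [
        AtomRecord(
            a.chain,
            a.residue_number,
            a.residue_name,
            swap_by_residue.get((a.chain, a.residue_number), {}).get(
                a.atom_name, a.atom_name
            ),
            a.position,
        )
        for a in model.atoms
    ]
    return StructureModel(atoms, model_id=model.model_id)


# ---------------------------------------------------------------------------
# toy complexes

_ASP_ANCHOR = ("A", 100)
_TM56_ANCHOR = ("A", 200)


def gen_toy_complex(
    salt_bridge_distance: float = 3.0,
    centroid_distance: float = 5.0,
    pose_id: str = "pose",
) -> tuple[StructureModel, LigandPose]:
    """Receptor fragment + ligand pose with exact interaction distances.

    The receptor carries an anchor Asp (chain A, residue 100) whose OD1
    sits at the origin, and a TM5/6 anchor residue (Phe, A/200) whose CZ is
    the nearest anchor atom to the ligand ring.  The pose's cation nitrogen
    lies exactly ``salt_bridge_distance`` from OD1 and its six-membered
    ring centroid exactly ``centroid_distance`` from CZ; all other anchor
    atoms are strictly farther, so the minima equal the requested values.
    """
    if salt_bridge_distance < 0 or centroid_distance < 0:
        raise SimParameterError("requested distances must be >= 0")
    asp_atoms = {
        "CB": (0.55, -2.50, 0.10),
        "CG": (0.70, -1.10, 0.05),
        "OD1": (0.00, 0.00, 0.00),
        "OD2": (1.90, -0.70, 0.00),
    }
    cz = np.array([0.0, 8.0, 0.0])
    phe_atoms = {
        "CB": (0.20, 11.20, 0.30),
        "CG": (0.20, 10.40, 0.15),
        "CD1": (-1.00, 9.80, 0.20),
        "CD2": (1.40, 9.75, 0.05),
        "CE1": (-1.00, 8.70, 0.15),
        "CE2": (1.40, 8.65, 0.00),
        "CZ": tuple(cz),
    }
    atoms = [
        AtomRecord(_ASP_ANCHOR[0], _ASP_ANCHOR[1], "ASP", n, np.array(p))
        for n, p in asp_atoms.items()
    ] + [
        AtomRecord(_TM56_ANCHOR[0], _TM56_ANCHOR[1], "PHE", n, np.array(p))
        for n, p in phe_atoms.items()
    ]
    receptor = StructureModel(atoms, model_id="toy_receptor")

    cation = np.array([-salt_bridge_distance, 0.0, 0.0])
    centroid = cz + np.array([0.0, -centroid_distance, 0.0])
    ring = [
        centroid + 1.39 * np.array([math.cos(a), 0.0, math.sin(a)])
        for a in np.linspace(0.0, 2.0 * math.pi, 6, endpoint=False)
    ]
    pose_atoms = [PoseAtom("N1", "N", cation)] + [
        PoseAtom(f"C{i+1}", "C", p) for i, p in enumerate(ring)
    ]
    pose = LigandPose(
        pose_id=pose_id,
        atoms=pose_atoms,
        cation_atoms=["N1"],
        aromatic_rings=[[1, 2, 3, 4, 5, 6]],
    )
    return receptor, pose


def toy_site_anchors(receptor: StructureModel) -> SiteAnchors:
    """Anchors for structures built by :func:`gen_toy_complex`."""
    return SiteAnchors.from_structure(receptor, _ASP_ANCHOR, [_TM56_ANCHOR])


# ---------------------------------------------------------------------------
# alignments

_AA = "ACDEFGHIKLMNPQRSTVWY"
# deterministic "different residue" substitution
_SUBSTITUTE = {a: _AA[(i + 7) % len(_AA)] for i, a in enumerate(_AA)}


def gen_toy_alignment(
    region_size: int,
    n_matches: int,
    n_gap_columns: int = 0,
    seed: int = 0,
    flank: int = 3,
) -> tuple[PairwiseAlignment, dict[str, set[int]]]:
    """Alignment whose region identity is exactly 100*n_matches/region_size.

    The target has ``flank`` matching residues on each side of a contiguous
    region; within the region, ``n_matches`` columns are identical,
    ``n_gap_columns`` place a template gap (counted as mismatch) and the
    rest substitute a different residue.  Returns the alignment and a
    region map {"TM": positions}.
    """
    if not 0 <= n_matches <= region_size:
        raise SimParameterError("need 0 <= n_matches <= region_size")
    if n_gap_columns < 0 or n_matches + n_gap_columns > region_size:
        raise SimParameterError("gaps + matches must fit inside the region")
    rng = np.random.default_rng(seed)
    length = region_size + 2 * flank
    target = "".join(rng.choice(list(_AA), size=length))
    roles = (
        ["match"] * n_matches
        + ["gap"] * n_gap_columns
        + ["mismatch"] * (region_size - n_matches - n_gap_columns)
    )
    rng.shuffle(roles)
    template_chars = []
    for i, t in enumerate(target):
        if i < flank or i >= flank + region_size:
            template_chars.append(t)
            continue
        role = roles[i - flank]
        if role == "match":
            template_chars.append(t)
        elif role == "gap":
            template_chars.append("-")
        else:
            template_chars.append(_SUBSTITUTE[t])
    aln = PairwiseAlignment(
        target_name="target",
        template_name="template",
        target_row=target,
        template_row="".join(template_chars),
    )
    region = {"TM": set(range(flank + 1, flank + region_size + 1))}
    return aln, region
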