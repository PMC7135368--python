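"""Structural accuracy and diversity metrics for receptor models.

Receptor models are compared to a reference (e.g. a crystal structure) by a
single least-squares (Kabsch) superposition on the transmembrane backbone
(N, CA, C, O), after which region-restricted RMSDs are computed without
refitting: TM backbone (RMSD_TMBB), binding-site backbone (RMSD_BSBB) and
binding-site side-chain heavy atoms (RMSD_BSSC).  Side-chain RMSDs account
for chemical symmetry: residues with chemically equivalent atom pairs
(Asp OD1/OD2, Glu OE1/OE2, Phe/Tyr ring CD/CE pairs, Arg NH1/NH2,
Leu CD1/CD2, Val CG1/CG2) take the labelling that minimizes that residue's
squared deviation, independently per residue, so a 180-degree ring flip
costs nothing.

Atom pairing is strict: (chain, residue number, atom name).  Residues or
atoms missing on either side are skipped symmetrically.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = [
    "StructureParseError",
    "InsufficientOverlapError",
    "EmptyRegionError",
    "AtomRecord",
    "StructureModel",
    "RegionDefinition",
    "RmsdReport",
    "Transform",
    "read_structure",
    "write_structure",
    "superpose",
    "region_rmsd",
    "rmsd_report",
    "pairwise_diversity",
    "improvement_fraction",
    "BACKBONE_ATOMS",
    "SYMMETRIC_ATOM_PAIRS",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
_NON_SIDECHAIN = frozenset({"N", "CA", "C", "O", "OXT"})
_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Chemically equivalent heavy-atom pairs, swapped jointly per residue.
SYMMETRIC_ATOM_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "ASP": (("OD1", "OD2"),),
    "GLU": (("OE1", "OE2"),),
    "PHE": (("CD1", "CD2"), ("CE1", "CE2")),
    "TYR": (("CD1", "CD2"), ("CE1", "CE2")),
    "ARG": (("NH1", "NH2"),),
    "LEU": (("CD1", "CD2"),),
    "VAL": (("CG1", "CG2"),),
}


class StructureParseError(ValueError):
    """PDB text could not be parsed into atoms."""


class InsufficientOverlapError(ValueError):
    """Fewer than three paired fit atoms between two structures."""


class EmptyRegionError(ValueError):
    """No paired atoms of the requested class inside the region."""


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # (3,) in Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureParseError(
                f"bad position for atom {self.atom_name} "
                f"{self.chain}/{self.residue_number}"
            )


class StructureModel:
    """Flat list of heavy atoms with residue indexing."""

    def __init__(self, atoms: Sequence[AtomRecord], model_id: str = "model"):
        self.atoms = list(atoms)
        self.model_id = model_id
        self._residues: dict[tuple[str, int], dict] = {}
        for idx, a in enumerate(self.atoms):
            res = self._residues.setdefault(
                (a.chain, a.residue_number),
                {"resname": a.residue_name, "atoms": {}},
            )
            if a.atom_name in res["atoms"]:
                raise StructureParseError(
                    f"duplicate atom {a.atom_name} in residue "
                    f"{a.chain}/{a.residue_number}"
                )
            res["atoms"][a.atom_name] = idx

    def residue(self, chain: str, number: int) -> dict | None:
        return self._residues.get((chain, number))

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return list(self._residues)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_id: str | None = None) -> "StructureModel":
        atoms = [
            AtomRecord(a.chain, a.residue_number, a.residue_name, a.atom_name, c)
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, model_id=model_id or self.model_id)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class RegionDefinition:
    """Named set of (chain, residue_number) selectors.

    Regions may be given directly, or derived from generic helix.position
    (Ballesteros–Weinstein) labels through a numbering map so binding-site
    definitions transfer between receptors.
    """

    name: str
    residues: frozenset[tuple[str, int]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "residues",
            frozenset((str(c), int(n)) for c, n in self.residues),
        )
        if not self.residues:
            raise EmptyRegionError(f"region {self.name!r} is empty")

    @classmethod
    def from_bw(
        cls,
        name: str,
        bw_positions: Iterable[str],
        numbering_map: dict[str, tuple[str, int]],
    ) -> "RegionDefinition":
        missing = [p for p in bw_positions if p not in numbering_map]
        if missing:
            raise KeyError(f"BW positions absent from numbering map: {missing}")
        return cls(name, frozenset(tuple(numbering_map[p]) for p in bw_positions))

    def restricted_to(self, other: "RegionDefinition") -> "RegionDefinition":
        """Intersection, e.g. a binding site restricted to the TM region."""
        return RegionDefinition(self.name, self.residues & other.residues)


@dataclass(frozen=True)
class Transform:
    """Rigid transform y = x @ rotation + translation (row vectors)."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation + self.translation

    def apply_to(self, model: StructureModel) -> StructureModel:
        return model.with_coords(self.apply(model.coords()))


@dataclass(frozen=True)
class RmsdReport:
    rmsd_tmbb: float
    rmsd_bsbb: float
    rmsd_bssc: float
    n_tmbb: int
    n_bsbb: int
    n_bssc: int
    symmetry_corrected: bool
    model_id: str = ""


# ---------------------------------------------------------------------------
# PDB I/O

def read_structure(
    pdb_text: str,
    model_id: str = "model",
    keep_waters: bool = False,
) -> StructureModel:
    """Parse PDB coordinate text into a StructureModel.

    Alternate locations resolve to the highest-occupancy conformer (ties
    fall to the first encountered, normally altloc 'A'); waters and
    hydrogens are excluded.  Only the first MODEL of multi-model files is
    read.
    """
    parser = PDBParser(QUIET=False, PERMISSIVE=True)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PDBConstructionWarning)
        try:
            structure = parser.get_structure(model_id, io.StringIO(pdb_text))
        except Exception as exc:
            raise StructureParseError(f"PDB parse failed: {exc}") from exc
    for w in caught:
        msg = str(w.message)
        # benign bookkeeping records are tolerated; bad numbers are not
        if "coordinate" in msg.lower() or "exceptionally" in msg.lower():
            raise StructureParseError(f"PDB parse failed: {msg}")
    atoms: list[AtomRecord] = []
    for model in structure:
        for chain in model:
            for res in chain:
                resname = res.get_resname().strip()
                if not keep_waters and (res.id[0] == "W" or resname in _WATER_NAMES):
                    continue
                for atom in res:
                    if (atom.element or "").strip().upper() in {"H", "D"}:
                        continue
                    atoms.append(
                        AtomRecord(
                            chain=chain.id.strip() or "A",
                            residue_number=res.id[1],
                            residue_name=resname,
                            atom_name=atom.get_name().strip(),
                            position=np.asarray(atom.coord, dtype=float),
                        )
                    )
        break
    if not atoms:
        raise StructureParseError("no ATOM/HETATM records found")
    return StructureModel(atoms, model_id=model_id)


def write_structure(model: StructureModel) -> str:
    """Serialize to PDB coordinate text (ATOM records, single chain set)."""
    lines = []
    for serial, a in enumerate(model.atoms, start=1):
        element = _element_of(a.atom_name)
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {a.residue_name:<3s} "
            f"{a.chain:1s}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# superposition and RMSD

def _paired_region_coords(
    mobile: StructureModel,
    reference: StructureModel,
    region: RegionDefinition,
    atom_names: frozenset[str] | None,
    atom_class: Literal["backbone", "sidechain_heavy"] | None = None,
):
    """Per-residue paired coordinates for atoms present in both structures.

    Yields (resname, names, mobile_xyz, reference_xyz, mobile_res) per
    region residue with at least one paired atom.
    """
    for key in sorted(region.residues):
        mres = mobile.residue(*key)
        rres = reference.residue(*key)
        if mres is None or rres is None:
            continue
        names = sorted(set(mres["atoms"]) & set(rres["atoms"]))
        if atom_names is not None:
            names = [n for n in names if n in atom_names]
        elif atom_class == "sidechain_heavy":
            names = [n for n in names if n not in _NON_SIDECHAIN]
        if not names:
            continue
        mob = np.array([mobile.atoms[mres["atoms"][n]].position for n in names])
        ref = np.array([reference.atoms[rres["atoms"][n]].position for n in names])
        yield rres["resname"], names, mob, ref, mres


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    fit_region: RegionDefinition,
) -> Transform:
    """Least-squares rigid fit of mobile onto reference.

    Fits on the paired backbone atoms (N, CA, C, O) of the fit region;
    missing atoms are skipped symmetrically.  Raises if fewer than three
    pairs remain.
    """
    mob_list, ref_list = [], []
    for _, _, mob, ref, _ in _paired_region_coords(
        mobile, reference, fit_region, BACKBONE_ATOMS
    ):
        mob_list.append(mob)
        ref_list.append(ref)
    if not mob_list or sum(len(m) for m in mob_list) < 3:
        raise InsufficientOverlapError(
            f"fewer than 3 paired backbone atoms in region {fit_region.name!r}"
        )
    mob = np.vstack(mob_list)
    ref = np.vstack(ref_list)
    sup = SVDSuperimposer()
    sup.set(ref, mob)
    sup.run()
    rot, tran = sup.get_rotran()
    return Transform(
        rotation=rot, translation=tran, fit_rmsd=float(sup.get_rms()), n_atoms=len(mob)
    )


def region_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    region: RegionDefinition,
    atom_class: Literal["backbone", "sidechain_heavy"] = "backbone",
    symmetry: bool = False,
) -> tuple[float, int]:
    """RMSD over paired region atoms of one class; no refit inside.

    With ``symmetry``, each residue with chemically equivalent atom pairs
    independently takes the relabelling (all pairs swapped jointly, e.g. a
    ring flip) that minimizes its squared deviation.  Returns (rmsd,
    n_atoms).
    """
    atom_names = BACKBONE_ATOMS if atom_class == "backbone" else None
    total = 0.0
    count = 0
    for resname, names, mob, ref, mres in _paired_region_coords(
        mobile, reference, region, atom_names, atom_class
    ):
        ssd = float(np.sum((mob - ref) ** 2))
        if symmetry and resname in SYMMETRIC_ATOM_PAIRS:
            swap: dict[str, str] = {}
            for a, b in SYMMETRIC_ATOM_PAIRS[resname]:
                swap[a], swap[b] = b, a
            if any(n in swap for n in names):
                alt = _swapped_ssd(names, ref, mres, mobile, swap)
                if alt is not None:
                    ssd = min(ssd, alt)
        total += ssd
        count += len(names)
    if count == 0:
        raise EmptyRegionError(
            f"no paired {atom_class} atoms in region {region.name!r}"
        )
    return math.sqrt(total / count), count


def _swapped_ssd(names, ref, mres, mobile, swap) -> float | None:
    """Squared deviation with the mobile residue's symmetric labels swapped."""
    coords = []
    for n in names:
        partner = swap.get(n, n)
        idx = mres["atoms"].get(partner)
        if idx is None:
            return None  # partner atom missing: identity labelling only
        coords.append(mobile.atoms[idx].position)
    return float(np.sum((np.array(coords) - ref) ** 2))


def rmsd_report(
    mobile: StructureModel,
    reference: StructureModel,
    tm_region: RegionDefinition,
    bs_region: RegionDefinition,
    symmetry: bool = True,
) -> RmsdReport:
    """TM-backbone fit, then TM/BS backbone and BS side-chain RMSDs."""
    transform = superpose(mobile, reference, tm_region)
    fitted = transform.apply_to(mobile)
    tmbb, n_tm = region_rmsd(fitted, reference, tm_region, "backbone")
    bsbb, n_bsbb = region_rmsd(fitted, reference, bs_region, "backbone")
    bssc, n_bssc = region_rmsd(
        fitted, reference, bs_region, "sidechain_heavy", symmetry=symmetry
    )
    return RmsdReport(
        rmsd_tmbb=tmbb,
        rmsd_bsbb=bsbb,
        rmsd_bssc=bssc,
        n_tmbb=n_tm,
        n_bsbb=n_bsbb,
        n_bssc=n_bssc,
        symmetry_corrected=symmetry,
        model_id=mobile.model_id,
    )


def pairwise_diversity(
    models: Sequence[StructureModel],
    region: RegionDefinition,
    atom_class: Literal["backbone", "sidechain_heavy"] = "sidechain_heavy",
    fit_region: RegionDefinition | None = None,
    symmetry: bool = True,
) -> tuple[np.ndarray, float]:
    """Symmetric pairwise RMSD matrix and its off-diagonal mean.

    Each pair is superposed on the fit region's backbone (default: the
    scored region itself) before the region RMSD is taken.
    """
    if len(models) < 2:
        raise InvalidStructureSetError("need >=2 models for pairwise diversity")
    fit = fit_region or region
    n = len(models)
    matrix = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            transform = superpose(models[i], models[j], fit)
            fitted = transform.apply_to(models[i])
            value, _ = region_rmsd(fitted, models[j], region, atom_class, symmetry)
            matrix[i, j] = matrix[j, i] = value
    mean = float(matrix[np.triu_indices(n, k=1)].mean())
    return matrix, mean


class InvalidStructureSetError(ValueError):
    """A structure-set operation got too few models."""


def improvement_fraction(
    candidates: Sequence[StructureModel],
    reference: StructureModel,
    baseline: StructureModel,
    region: RegionDefinition,
    atom_class: Literal["backbone", "sidechain_heavy"] = "backbone",
    fit_region: RegionDefinition | None = None,
    symmetry: bool = True,
) -> float:
    """Fraction of candidates strictly closer to the reference than baseline.

    Mirrors how refined snapshots are judged against the starting model:
    every structure is fitted to the reference on the fit region (default:
    the scored region) and the region RMSD is compared to the baseline's.
    """
    if not candidates:
        raise InvalidStructureSetError("need >=1 candidate model")
    fit = fit_region or region

    def rmsd_to_ref(model: StructureModel) -> float:
        fitted = superpose(model, reference, fit).apply_to(model)
        value, _ = region_rmsd(fitted, reference, region, atom_class, symmetry)
        return value

    base = rmsd_to_ref(baseline)
    improved = sum(1 for c in candidates if rmsd_to_ref(c) < base)
    return improved / len(candidates)
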