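"""Geometric classification of docked ligand binding modes.

Aminergic receptor ligands share two hallmark interactions in every
experimentally determined complex: a charge-charge contact between a
protonated amine and the conserved anchor aspartate (generic position
3.32), and an aromatic moiety extending toward the TM5/TM6 face of the
pocket.  A docked pose is classified "Good" when both geometric criteria
hold and "Bad" otherwise:

* salt bridge: minimum distance from any declared cation atom to the
  anchor carboxylate oxygens (OD1/OD2) at or below a cutoff (default 4 A);
* aromatic engagement: minimum distance from any aromatic ring centroid to
  any TM5/6 anchor heavy atom at or below a cutoff (default 6 A).

Cation atoms and aromatic rings are declared metadata (side-car
annotations); no chemical perception is attempted.  TM5/6 anchor residues
are configuration, typically chosen through the generic numbering map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import StructureModel, Transform, read_structure

__all__ = [
    "CriterionInapplicableError",
    "PoseAnnotationError",
    "PoseAtom",
    "LigandPose",
    "SiteAnchors",
    "PoseVerdict",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
    "DEFAULT_AROMATIC_CUTOFF",
    "detect_salt_bridge",
    "detect_aromatic_engagement",
    "classify_pose",
    "classify_poses",
    "pose_from_pdb",
    "pose_from_mol2",
]

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # Angstrom, N+ to carboxylate O
DEFAULT_AROMATIC_CUTOFF = 6.0  # Angstrom, ring centroid to anchor heavy atom


class CriterionInapplicableError(ValueError):
    """Pose lacks the metadata a criterion needs (not a silent 'Bad')."""


class PoseAnnotationError(ValueError):
    """Cation/ring annotations reference atoms that do not exist."""


@dataclass(frozen=True)
class PoseAtom:
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))


@dataclass
class LigandPose:
    """Ligand atoms plus declared cation atoms and aromatic-ring index sets."""

    pose_id: str
    atoms: list[PoseAtom]
    cation_atoms: list[str]
    aromatic_rings: list[list[int]]

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        for cname in self.cation_atoms:
            if cname not in names:
                raise PoseAnnotationError(
                    f"cation atom {cname!r} not in pose {self.pose_id!r}"
                )
        for ring in self.aromatic_rings:
            if len(ring) < 5:
                raise PoseAnnotationError("aromatic rings need >=5 atoms")
            for idx in ring:
                if not 0 <= idx < len(self.atoms):
                    raise PoseAnnotationError(
                        f"ring atom index {idx} out of range in pose {self.pose_id!r}"
                    )

    def cation_coords(self) -> np.ndarray:
        byname = {a.name: a.position for a in self.atoms}
        return np.array([byname[n] for n in self.cation_atoms])

    def ring_centroids(self) -> np.ndarray:
        return np.array(
            [
                np.mean([self.atoms[i].position for i in ring], axis=0)
                for ring in self.aromatic_rings
            ]
        )

    def transformed(self, transform: Transform) -> "LigandPose":
        atoms = [
            PoseAtom(a.name, a.element, transform.apply(a.position[None, :])[0])
            for a in self.atoms
        ]
        return LigandPose(self.pose_id, atoms, list(self.cation_atoms),
                          [list(r) for r in self.aromatic_rings])


@dataclass(frozen=True)
class SiteAnchors:
    """Receptor-side interaction anchors.

    ``carboxylate`` holds the anchor aspartate's OD1/OD2 coordinates;
    ``tm56_atoms`` the heavy-atom coordinates of the configured TM5/TM6
    face residues.
    """

    carboxylate: np.ndarray  # (2, 3)
    tm56_atoms: np.ndarray  # (m, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "carboxylate", np.asarray(self.carboxylate, float))
        object.__setattr__(self, "tm56_atoms", np.asarray(self.tm56_atoms, float))
        if self.carboxylate.shape != (2, 3):
            raise PoseAnnotationError("anchor carboxylate needs OD1 and OD2")
        if self.tm56_atoms.ndim != 2 or len(self.tm56_atoms) == 0:
            raise PoseAnnotationError("TM5/6 anchor atom set is empty")

    @classmethod
    def from_structure(
        cls,
        receptor: StructureModel,
        asp_anchor: tuple[str, int],
        tm56_residues: Sequence[tuple[str, int]],
    ) -> "SiteAnchors":
        res = receptor.residue(*asp_anchor)
        if res is None or res["resname"] != "ASP":
            raise PoseAnnotationError(
                f"anchor residue {asp_anchor} is not an Asp in the receptor"
            )
        try:
            carbox = np.array(
                [
                    receptor.atoms[res["atoms"]["OD1"]].position,
                    receptor.atoms[res["atoms"]["OD2"]].position,
                ]
            )
        except KeyError as exc:
            raise PoseAnnotationError("anchor Asp lacks OD1/OD2") from exc
        tm56 = []
        for key in tm56_residues:
            r = receptor.residue(*tuple(key))
            if r is None:
                raise PoseAnnotationError(f"TM5/6 anchor residue {key} missing")
            tm56.extend(receptor.atoms[i].position for i in r["atoms"].values())
        return cls(carboxylate=carbox, tm56_atoms=np.array(tm56))

    def transformed(self, transform: Transform) -> "SiteAnchors":
        return SiteAnchors(
            carboxylate=transform.apply(self.carboxylate),
            tm56_atoms=transform.apply(self.tm56_atoms),
        )


@dataclass(frozen=True)
class PoseVerdict:
    pose_id: str
    salt_bridge: bool
    salt_bridge_distance: float
    aromatic_engaged: bool
    aromatic_distance: float

    @property
    def verdict(self) -> str:
        return "Good" if (self.salt_bridge and self.aromatic_engaged) else "Bad"


def detect_salt_bridge(
    pose: LigandPose,
    anchors: SiteAnchors,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> tuple[bool, float]:
    """Min cation-to-carboxylate-oxygen distance vs the cutoff."""
    if not pose.cation_atoms:
        raise CriterionInapplicableError(
            f"pose {pose.pose_id!r} declares no cation atoms"
        )
    d = np.linalg.norm(
        pose.cation_coords()[:, None, :] - anchors.carboxylate[None, :, :], axis=-1
    )
    dmin = float(d.min())
    return dmin <= cutoff, dmin


def detect_aromatic_engagement(
    pose: LigandPose,
    anchors: SiteAnchors,
    cutoff: float = DEFAULT_AROMATIC_CUTOFF,
) -> tuple[bool, float]:
    """Min ring-centroid-to-anchor-atom distance vs the cutoff."""
    if not pose.aromatic_rings:
        raise CriterionInapplicableError(
            f"pose {pose.pose_id!r} declares no aromatic rings"
        )
    d = np.linalg.norm(
        pose.ring_centroids()[:, None, :] - anchors.tm56_atoms[None, :, :], axis=-1
    )
    dmin = float(d.min())
    return dmin <= cutoff, dmin


def classify_pose(
    pose: LigandPose,
    anchors: SiteAnchors,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    aromatic_cutoff: float = DEFAULT_AROMATIC_CUTOFF,
) -> PoseVerdict:
    """Good iff both the salt bridge and the aromatic engagement hold."""
    sb, sb_dist = detect_salt_bridge(pose, anchors, salt_bridge_cutoff)
    ar, ar_dist = detect_aromatic_engagement(pose, anchors, aromatic_cutoff)
    return PoseVerdict(
        pose_id=pose.pose_id,
        salt_bridge=sb,
        salt_bridge_distance=sb_dist,
        aromatic_engaged=ar,
        aromatic_distance=ar_dist,
    )


def classify_poses(
    poses: Sequence[LigandPose],
    anchors: SiteAnchors,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    aromatic_cutoff: float = DEFAULT_AROMATIC_CUTOFF,
) -> list[PoseVerdict]:
    return [
        classify_pose(p, anchors, salt_bridge_cutoff, aromatic_cutoff)
        for p in poses
    ]


# ---------------------------------------------------------------------------
# pose input

def _resolve_rings(
    rings: Sequence[Sequence[object]], names: list[str], pose_id: str
) -> list[list[int]]:
    resolved = []
    for ring in rings:
        idxs = []
        for member in ring:
            if isinstance(member, int):
                idxs.append(member)
            else:
                try:
                    idxs.append(names.index(str(member)))
                except ValueError as exc:
                    raise PoseAnnotationError(
                        f"ring atom {member!r} not in pose {pose_id!r}"
                    ) from exc
        resolved.append(idxs)
    return resolved


def pose_from_pdb(pdb_text: str, annotations: dict, pose_id: str = "pose") -> LigandPose:
    """Build a pose from PDB coordinate text plus a side-car annotation dict.

    ``annotations`` needs ``cation_atoms`` (atom names) and
    ``aromatic_rings`` (lists of atom names or indices).
    """
    model = read_structure(pdb_text, model_id=pose_id)
    atoms = [
        PoseAtom(a.atom_name, _first_alpha(a.atom_name), a.position)
        for a in model.atoms
    ]
    names = [a.name for a in atoms]
    return LigandPose(
        pose_id=pose_id,
        atoms=atoms,
        cation_atoms=[str(n) for n in annotations.get("cation_atoms", [])],
        aromatic_rings=_resolve_rings(
            annotations.get("aromatic_rings", []), names, pose_id
        ),
    )


def pose_from_mol2(mol2_text: str, annotations: dict, pose_id: str = "pose") -> LigandPose:
    """Build a pose from the @<TRIPOS>ATOM section of a Mol2 file.

    Reads atom name, coordinates and the element prefix of the SYBYL atom
    type; bonds and charges are ignored (interaction metadata comes from
    the side-car annotations).
    """
    atoms: list[PoseAtom] = []
    in_atoms = False
    for line in mol2_text.splitlines():
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            in_atoms = stripped == "@<TRIPOS>ATOM"
            continue
        if not in_atoms or not stripped:
            continue
        fields = stripped.split()
        if len(fields) < 6:
            raise PoseAnnotationError(f"malformed Mol2 atom line: {line!r}")
        name = fields[1]
        x, y, z = (float(v) for v in fields[2:5])
        element = fields[5].split(".")[0].upper()
        if element in {"H", "D"}:
            continue
        atoms.append(PoseAtom(name, element, np.array([x, y, z])))
    if not atoms:
        raise PoseAnnotationError("no @<TRIPOS>ATOM records found")
    names = [a.name for a in atoms]
    return LigandPose(
        pose_id=pose_id,
        atoms=atoms,
        cation_atoms=[str(n) for n in annotations.get("cation_atoms", [])],
        aromatic_rings=_resolve_rings(
            annotations.get("aromatic_rings", []), names, pose_id
        ),
    )


def _first_alpha(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"
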