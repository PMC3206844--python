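"""Coordinate model for scattering calculations.

A :class:`Structure` is an ordered set of point scattering centres (atoms or
beads) carrying excess scattering weights, grouped into named components
(PDB chains).  Rigid-body work is done on a :class:`RigidBodyAssembly`,
which pairs each component with a :class:`RigidTransform` (proper rotation
about the component's own centroid, followed by a translation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ScatteringCentre",
    "Structure",
    "RigidTransform",
    "RigidBodyAssembly",
    "StructureError",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "apply_assembly",
    "radius_of_gyration",
    "min_intercomponent_distance",
    "is_clashing",
    "assembly_rmsd",
    "DEFAULT_CLASH_THRESHOLD",
]

#: Default heavy-atom/bead clash threshold in Angstrom.  A centre-centre
#: distance below any bonded or van der Waals contact distance; a pair is a
#: clash iff its distance is strictly below this value.
DEFAULT_CLASH_THRESHOLD = 2.5

#: Mean solvent electron density, e/A^3 (water at 20 C).
SOLVENT_DENSITY = 0.334

# Average displaced-solvent volumes per atom, A^3 (Fraser, MacRae & Suzuki,
# J. Appl. Cryst. 11 (1978) 693).  Elements absent from the table displace
# no solvent in this model (weight = electron count), which overweights
# exotic elements slightly but never produces negative weights.
ATOMIC_VOLUMES = {
    "H": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
    "FE": 7.99,
}


class StructureError(ValueError):
    """Invalid structure content (empty, mismatched topology, bad weights)."""


class StructureFormatError(StructureError):
    """Unparseable or unwritable PDB content."""


@dataclass(frozen=True)
class ScatteringCentre:
    """One point scatterer.

    Parameters
    ----------
    label : str
        Free-text identifier (atom name for atomic models, bead index for
        bead models).
    component_id : str
        Rigid component the centre belongs to; the PDB chain identifier.
    position : (3,) array
        Cartesian coordinates in Angstrom.
    weight : float
        Excess scattering length in effective electrons; must be >= 0.
    element : str
        Element symbol, kept for PDB round-trips.  Beads default to "C".
    """

    label: str
    component_id: str
    position: np.ndarray
    weight: float = 1.0
    element: str = "C"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"position must be a finite 3-vector, got {self.position!r}")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise StructureError(f"weight must be finite and >= 0, got {self.weight!r}")
        object.__setattr__(self, "position", pos)


class Structure:
    """Ordered collection of scattering centres.

    Coordinates and weights are also exposed as dense arrays
    (:attr:`coords`, :attr:`weights`) for vectorised work.
    """

    def __init__(self, centres, name: str = "") -> None:
        centres = list(centres)
        if not centres:
            raise StructureError("a Structure must contain at least one centre")
        self.centres: list[ScatteringCentre] = centres
        self.name = name
        self.coords = np.array([c.position for c in centres], dtype=float)
        self.weights = np.array([c.weight for c in centres], dtype=float)

    def __len__(self) -> int:
        return len(self.centres)

    def __repr__(self) -> str:
        return (
            f"<Structure {self.name!r}: {len(self)} centres, "
            f"{len(self.component_ids)} component(s)>"
        )

    @property
    def component_ids(self) -> list[str]:
        """Distinct component identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.centres:
            seen.setdefault(c.component_id, None)
        return list(seen)

    def component(self, component_id: str) -> "Structure":
        """Sub-structure holding only the centres of one component."""
        sub = [c for c in self.centres if c.component_id == component_id]
        if not sub:
            raise StructureError(f"no component {component_id!r} in structure")
        return Structure(sub, name=f"{self.name}:{component_id}")

    def split_components(self) -> dict[str, "Structure"]:
        return {cid: self.component(cid) for cid in self.component_ids}

    def centroid(self) -> np.ndarray:
        """Unweighted centroid of the centres (rotation pivot convention)."""
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise StructureError("coordinate array shape mismatch")
        centres = [
            dataclasses.replace(c, position=coords[i]) for i, c in enumerate(self.centres)
        ]
        return Structure(centres, name=self.name)

    @classmethod
    def from_arrays(cls, coords, weights=None, component_id="A", name="", labels=None):
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        if weights is None:
            weights = np.ones(n)
        if labels is None:
            labels = [f"X{i + 1}" for i in range(n)]
        centres = [
            ScatteringCentre(labels[i], component_id, coords[i], float(weights[i]))
            for i in range(n)
        ]
        return cls(centres, name=name)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: rotation matrix plus translation vector (A)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3):
            raise StructureError("rotation must be a 3x3 matrix")
        if tr.shape != (3,):
            raise StructureError("translation must be a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise StructureError("rotation matrix is not orthonormal (R^T R != I)")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
            raise StructureError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def compose_about(self, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        """Follow this transform by a further centroid-pivoted move.

        Because both transforms pivot about the component's (moving)
        centroid, the composition is simply (R_new @ R_old, t_old + t_new).
        """
        return RigidTransform(np.asarray(rotation) @ self.rotation,
                              self.translation + np.asarray(translation))


class RigidBodyAssembly:
    """Named rigid components plus one transform per component."""

    def __init__(self, components: Mapping[str, Structure],
                 transforms: Mapping[str, RigidTransform] | None = None) -> None:
        self.components = dict(components)
        if not self.components:
            raise StructureError("assembly needs at least one component")
        if transforms is None:
            transforms = {cid: RigidTransform.identity() for cid in self.components}
        self.transforms = dict(transforms)
        if set(self.components) != set(self.transforms):
            raise StructureError(
                "component and transform key sets differ: "
                f"{sorted(self.components)} vs {sorted(self.transforms)}"
            )

    def __repr__(self) -> str:
        return f"<RigidBodyAssembly: components {sorted(self.components)}>"

    @property
    def component_ids(self) -> list[str]:
        return list(self.components)

    def replace_transform(self, component_id: str, transform: RigidTransform) -> "RigidBodyAssembly":
        new = dict(self.transforms)
        new[component_id] = transform
        return RigidBodyAssembly(self.components, new)

    def transformed_coords(self, component_id: str) -> np.ndarray:
        """Coordinates of one component after its transform."""
        comp = self.components[component_id]
        t = self.transforms[component_id]
        if np.array_equal(t.rotation, np.eye(3)) and not t.translation.any():
            return comp.coords.copy()
        pivot = comp.centroid()
        return (comp.coords - pivot) @ t.rotation.T + pivot + t.translation

    @classmethod
    def from_structure(cls, structure: Structure) -> "RigidBodyAssembly":
        """Split a multi-chain structure into an identity-transform assembly."""
        return cls(structure.split_components())


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_structure(path, bead_mode: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Every ATOM/HETATM record becomes one centre; hydrogens are skipped.
    The chain identifier becomes the component id.  In ``bead_mode`` each
    centre has unit weight; otherwise the weight is the element's electron
    count minus the displaced-solvent term ``rho_s * V`` (rho_s = 0.334
    e/A^3, Fraser-MacRae-Suzuki volumes).  No hydration shell is added.
    """
    import gemmi

    # gemmi tolerates malformed records; validate coordinate fields first so
    # format errors carry the offending line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise StructureFormatError(
                        f"{path}:{lineno}: unparseable coordinates in "
                        f"{line.rstrip()!r}"
                    ) from None
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        # gemmi reports the offending line in its message
        raise StructureFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    centres: list[ScatteringCentre] = []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    elem = atom.element.name.upper()
                    if elem in ("H", "D"):
                        continue
                    if bead_mode:
                        w = 1.0
                    else:
                        z = atom.element.atomic_number
                        vol = ATOMIC_VOLUMES.get(elem, 0.0)
                        w = float(z) - SOLVENT_DENSITY * vol
                    centres.append(
                        ScatteringCentre(
                            label=atom.name,
                            component_id=chain.name,
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            weight=max(w, 0.0),
                            element=elem if elem else "C",
                        )
                    )
        break  # first model only
    if not centres:
        raise StructureError(f"no (non-hydrogen) atoms found in {path}")
    return Structure(centres, name=str(path))


def write_structure(s: Structure, path) -> None:
    """Write a :class:`Structure` as PDB text, one chain per component.

    PDB coordinate columns are fixed width (%8.3f), so any coordinate with
    magnitude >= 10000 A raises before anything is written.
    """
    import gemmi

    if np.any(np.abs(s.coords) > 9999.999):
        raise StructureFormatError(
            "coordinate magnitude exceeds the 9999.999 A PDB column limit"
        )
    st = gemmi.Structure()
    st.name = s.name or "saxskit"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = {}
    for c in s.centres:
        if c.component_id not in chains:
            chains[c.component_id] = gemmi.Chain(c.component_id)
            serial[c.component_id] = 0
        serial[c.component_id] += 1
        res = gemmi.Residue()
        res.name = "DUM"
        res.seqid = gemmi.SeqId(serial[c.component_id], " ")
        atom = gemmi.Atom()
        atom.name = (c.label or "X")[:4]
        atom.element = gemmi.Element(c.element)
        atom.pos = gemmi.Position(*c.position)
        atom.occ = 1.0
        # stash the weight in the B-factor column so bead weights round-trip
        atom.b_iso = min(float(c.weight), 999.99)
        res.add_atom(atom)
        chains[c.component_id].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise StructureFormatError(f"cannot write PDB file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def apply_assembly(a: RigidBodyAssembly) -> Structure:
    """Materialise an assembly: apply each component's transform and
    concatenate the components in order."""
    centres: list[ScatteringCentre] = []
    for cid in a.component_ids:
        comp = a.components[cid]
        coords = a.transformed_coords(cid)
        centres.extend(
            dataclasses.replace(c, position=coords[i]) for i, c in enumerate(comp.centres)
        )
    return Structure(centres, name="assembly")


def radius_of_gyration(s: Structure) -> float:
    """Weight-weighted radius of gyration in Angstrom.

    Rg = sqrt( sum_j w_j |x_j - xbar|^2 / sum_j w_j ) with xbar the
    weighted centroid.
    """
    wsum = s.weights.sum()
    if wsum <= 0:
        raise StructureError("radius of gyration undefined: all weights are zero")
    xbar = (s.weights[:, None] * s.coords).sum(axis=0) / wsum
    d2 = ((s.coords - xbar) ** 2).sum(axis=1)
    return float(np.sqrt((s.weights * d2).sum() / wsum))


def min_intercomponent_distance(a: RigidBodyAssembly) -> float:
    """Minimum centre-centre distance between different components (A)."""
    ids = a.component_ids
    if len(ids) < 2:
        raise StructureError("need at least two components for inter-component distance")
    coords = {cid: a.transformed_coords(cid) for cid in ids}
    best = np.inf
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            d = cdist(coords[ci], coords[cj]).min()
            best = min(best, float(d))
    return best


def is_clashing(a: RigidBodyAssembly, threshold: float = DEFAULT_CLASH_THRESHOLD) -> bool:
    """Strict clash predicate: clash iff min inter-component distance < threshold."""
    return min_intercomponent_distance(a) < threshold


def assembly_rmsd(a: RigidBodyAssembly, b: RigidBodyAssembly) -> float:
    """RMSD between two poses of the same assembly, without re-superposition.

    Both assemblies must hold identical component sets with matching centre
    counts; the deviation is taken over all centres after applying each
    assembly's transforms.
    """
    if set(a.component_ids) != set(b.component_ids):
        raise StructureError("assemblies have different component sets")
    sq = 0.0
    n = 0
    for cid in a.component_ids:
        xa = a.transformed_coords(cid)
        xb = b.transformed_coords(cid)
        if xa.shape != xb.shape:
            raise StructureError(f"component {cid!r} centre counts differ")
        sq += float(((xa - xb) ** 2).sum())
        n += len(xa)
    return float(np.sqrt(sq / n))
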