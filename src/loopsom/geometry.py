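"""Backbone coordinate primitives.

This module holds the geometry layer the rest of the package is built on:
torsion angles in the IUPAC sign convention, phi/psi extraction from backbone
frames, least-squares rigid superposition (Kabsch), and an idealized backbone
builder that turns (phi, psi, omega) sequences into coordinates by natural
extension.  Only the three backbone atoms N, CA and C are modelled; side
chains and hydrogens are out of scope.

Conventions
-----------
* Angles are degrees throughout, reported in the half-open interval
  ``(-180, 180]``.
* Torsion sign follows IUPAC: looking from the second atom toward the third,
  a clockwise rotation of the far bond is positive.  Worked example:
  ``torsion((1,1,0), (1,0,0), (0,0,0), (0, cos60, sin60)) == +60``.
* Residue indices are 1-based and carried through from the input.  Mapping
  between an author's residue labels (e.g. "E59") and the indices of a
  user-supplied structure is the caller's responsibility (the reference
  allergen model spans residues 38-135 of the mature-chain numbering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError

BACKBONE_ATOMS = ("N", "CA", "C")

#: Ideal backbone internal coordinates (lengths in Angstrom, angles degrees).
DEFAULT_BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
DEFAULT_BOND_ANGLES = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.7}


@dataclass(frozen=True)
class AtomRecord:
    """A single labelled backbone atom."""

    atom_name: str
    residue_index: int
    residue_name: str
    position: np.ndarray

    def __post_init__(self):
        if self.atom_name not in BACKBONE_ATOMS:
            raise ValidationError(
                f"atom_name must be one of {BACKBONE_ATOMS}, got {self.atom_name!r}"
            )
        if self.residue_index < 1:
            raise ValidationError("residue_index must be >= 1")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive 1-based residue index range with a human-readable label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"start {self.start} > end {self.end}")

    def contains(self, residue_index) -> np.ndarray | bool:
        idx = np.asarray(residue_index)
        return (idx >= self.start) & (idx <= self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


class BackboneFrame:
    """One conformer: N/CA/C coordinates for a run of residues.

    Coordinates are stored as an ``(n_residues, 3, 3)`` array indexed by
    (residue, atom, xyz) with atoms ordered N, CA, C.
    """

    def __init__(self, coords, residue_indices, residue_names=None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (3, 3):
            raise ValidationError(
                f"coords must have shape (n_residues, 3, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        residue_indices = np.asarray(residue_indices, dtype=int)
        if residue_indices.shape != (coords.shape[0],):
            raise ValidationError("residue_indices length must match coords")
        if residue_indices.size and (
            np.any(residue_indices < 1) or np.any(np.diff(residue_indices) <= 0)
        ):
            raise ValidationError("residue_indices must be >= 1 and strictly increasing")
        if residue_names is None:
            residue_names = ["ALA"] * coords.shape[0]
        if len(residue_names) != coords.shape[0]:
            raise ValidationError("residue_names length must match coords")
        self.coords = coords
        self.residue_indices = residue_indices
        self.residue_names = list(residue_names)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def atoms(self) -> Iterable[AtomRecord]:
        for i in range(self.n_residues):
            for a, name in enumerate(BACKBONE_ATOMS):
                yield AtomRecord(
                    name,
                    int(self.residue_indices[i]),
                    self.residue_names[i],
                    self.coords[i, a],
                )

    def residue_mask(self, subset: ResidueRange | None) -> np.ndarray:
        if subset is None:
            return np.ones(self.n_residues, dtype=bool)
        mask = np.asarray(subset.contains(self.residue_indices), dtype=bool)
        if not mask.any():
            raise GeometryError(
                f"residue range {subset.start}-{subset.end} selects no residues"
            )
        return mask

    def ca_coords(self, subset: ResidueRange | None = None) -> np.ndarray:
        return self.coords[self.residue_mask(subset), 1, :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneFrame":
        flat = self.coords.reshape(-1, 3)
        moved = flat @ rotation.T + translation
        return BackboneFrame(
            moved.reshape(self.coords.shape), self.residue_indices, self.residue_names
        )

    def same_topology(self, other: "BackboneFrame") -> bool:
        return self.n_residues == other.n_residues and np.array_equal(
            self.residue_indices, other.residue_indices
        )


class ConformerTrajectory:
    """Ordered conformer frames of one simulated system.

    All frames share residue identity and atom ordering; coordinates live in
    a single ``(n_frames, n_residues, 3, 3)`` array.
    """

    def __init__(self, coords, residue_indices, residue_names=None,
                 system_label: str = "system", replica_id: int = 0):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 4 or coords.shape[2:] != (3, 3) or coords.shape[0] < 1:
            raise ValidationError(
                f"coords must have shape (n_frames>=1, n_residues, 3, 3), got {coords.shape}"
            )
        # reuse BackboneFrame validation for metadata
        template = BackboneFrame(coords[0], residue_indices, residue_names)
        self.coords = coords
        self.residue_indices = template.residue_indices
        self.residue_names = template.residue_names
        self.system_label = system_label
        self.replica_id = int(replica_id)

    @classmethod
    def from_frames(cls, frames: Sequence[BackboneFrame],
                    system_label: str = "system", replica_id: int = 0):
        if not frames:
            raise ValidationError("need at least one frame")
        first = frames[0]
        for f in frames[1:]:
            if not first.same_topology(f):
                raise ValidationError("all frames must share residue ordering")
        coords = np.stack([f.coords for f in frames])
        return cls(coords, first.residue_indices, first.residue_names,
                   system_label, replica_id)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> BackboneFrame:
        return BackboneFrame(self.coords[i], self.residue_indices, self.residue_names)

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# torsions


def torsion(p1, p2, p3, p4) -> float | np.ndarray:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180].

    Accepts single 3-vectors or broadcastable ``(..., 3)`` stacks.  Raises
    :class:`GeometryError` for coincident consecutive points or collinear
    bond geometry, where the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.any(np.linalg.norm(b, axis=-1) < 1e-9):
            raise GeometryError("coincident consecutive points: torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-9
    ):
        raise GeometryError("collinear bond vectors: torsion undefined")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def wrap_angle(angles):
    """Wrap angles in degrees into (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    wrapped = ((-a + 180.0) % 360.0)
    wrapped = 180.0 - wrapped
    out = np.where(wrapped <= -180.0, wrapped + 360.0, wrapped)
    return float(out) if out.ndim == 0 else out


def phi_psi(frame: BackboneFrame, subset: ResidueRange | None = None) -> pd.DataFrame:
    """Backbone phi/psi table for ``frame``.

    phi_i is C(i-1)-N(i)-CA(i)-C(i) and psi_i is N(i)-CA(i)-C(i)-N(i+1);
    a terminal angle with no flanking residue is reported as NaN (explicitly
    undefined, never a sentinel number).  Chain continuity requires the
    neighbouring residue index to be exactly one away.
    """
    mask = frame.residue_mask(subset)
    rows = []
    idx = frame.residue_indices
    for j in np.nonzero(mask)[0]:
        has_prev = j > 0 and idx[j - 1] == idx[j] - 1
        has_next = j < frame.n_residues - 1 and idx[j + 1] == idx[j] + 1
        phi = np.nan
        psi = np.nan
        if has_prev:
            phi = torsion(
                frame.coords[j - 1, 2], frame.coords[j, 0],
                frame.coords[j, 1], frame.coords[j, 2],
            )
        if has_next:
            psi = torsion(
                frame.coords[j, 0], frame.coords[j, 1],
                frame.coords[j, 2], frame.coords[j + 1, 0],
            )
        rows.append(
            {
                "residue_index": int(idx[j]),
                "residue_name": frame.residue_names[j],
                "phi": phi,
                "psi": psi,
            }
        )
    return pd.DataFrame(rows, columns=["residue_index", "residue_name", "phi", "psi"])


# ---------------------------------------------------------------------------
# superposition


def _select_atoms(frame: BackboneFrame, subset: ResidueRange | None,
                  atoms: Sequence[str]) -> np.ndarray:
    bad = set(atoms) - set(BACKBONE_ATOMS)
    if bad:
        raise ValidationError(f"unknown atom names {sorted(bad)}")
    mask = frame.residue_mask(subset)
    cols = [BACKBONE_ATOMS.index(a) for a in atoms]
    return frame.coords[np.ix_(np.nonzero(mask)[0], cols)].reshape(-1, 3)


def kabsch_superpose(mobile: BackboneFrame, reference: BackboneFrame,
                     subset: ResidueRange | None = None,
                     atoms: Sequence[str] = BACKBONE_ATOMS,
                     ) -> tuple[BackboneFrame, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation is found on the selected subset (Kabsch via
    SVD); the returned frame carries the transform applied to *all* atoms and
    the returned RMSD is the optimum over the subset.
    """
    if not mobile.same_topology(reference):
        raise GeometryError("mobile and reference frames differ in residue topology")
    mob = _select_atoms(mobile, subset, atoms)
    ref = _select_atoms(reference, subset, atoms)
    if mob.shape[0] < 3:
        raise GeometryError("superposition subset must select at least 3 atoms")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = mob - mob_c
    b = ref - ref_c
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise GeometryError("superposition subset is collinear")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    rotated = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((rotated - b) ** 2, axis=1))))
    translation = ref_c - mob_c @ rot.T
    return mobile.transformed(rot, translation), rmsd


# ---------------------------------------------------------------------------
# backbone construction (natural extension / NeRF)


@dataclass(frozen=True)
class IdealGeometry:
    """Idealized backbone internal coordinates used by :func:`build_backbone`."""

    n_ca: float = DEFAULT_BOND_LENGTHS["N-CA"]
    ca_c: float = DEFAULT_BOND_LENGTHS["CA-C"]
    c_n: float = DEFAULT_BOND_LENGTHS["C-N"]
    angle_n_ca_c: float = DEFAULT_BOND_ANGLES["N-CA-C"]
    angle_ca_c_n: float = DEFAULT_BOND_ANGLES["CA-C-N"]
    angle_c_n_ca: float = DEFAULT_BOND_ANGLES["C-N-CA"]

    def __post_init__(self):
        for name in ("n_ca", "ca_c", "c_n"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"bond length {name} must be positive")
        for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValidationError(f"bond angle {name} must be in (0, 180)")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with given internal coordinates relative to a-b-c."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi),
         -bond * np.sin(theta) * np.sin(chi)]
    )
    basis = np.stack([bc, m, n], axis=1)
    return c + basis @ d_local


def build_backbone(phi_psi_omega: Sequence[tuple[float, float, float]],
                   geometry: IdealGeometry | None = None,
                   start_index: int = 1,
                   residue_names: Sequence[str] | None = None) -> BackboneFrame:
    """Construct an idealized backbone from per-residue (phi, psi, omega).

    The first residue's phi and the last residue's psi/omega are ignored
    (they are undefined for a chain).  Extracting dihedrals from the result
    with :func:`phi_psi` reproduces the inputs to well below 1e-3 degrees.
    """
    if len(phi_psi_omega) < 2:
        raise ValidationError("need at least 2 residues to build a backbone")
    geo = geometry or IdealGeometry()
    n_res = len(phi_psi_omega)
    coords = np.zeros((n_res, 3, 3))
    # first residue in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (geo.n_ca, 0.0, 0.0)
    th = np.radians(geo.angle_n_ca_c)
    coords[0, 2] = coords[0, 1] + geo.ca_c * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(n_res - 1):
        psi = phi_psi_omega[i][1]
        omega = phi_psi_omega[i][2]
        phi_next = phi_psi_omega[i + 1][0]
        n_i, ca_i, c_i = coords[i]
        n_next = _place_atom(n_i, ca_i, c_i, geo.c_n, geo.angle_ca_c_n, psi)
        ca_next = _place_atom(ca_i, c_i, n_next, geo.n_ca, geo.angle_c_n_ca, omega)
        c_next = _place_atom(c_i, n_next, ca_next, geo.ca_c, geo.angle_n_ca_c, phi_next)
        coords[i + 1] = np.stack([n_next, ca_next, c_next])
    indices = np.arange(start_index, start_index + n_res)
    return BackboneFrame(coords, indices, residue_names)


# ---------------------------------------------------------------------------
# I/O: multi-model PDB and coordinate CSV


def write_pdb(trajectory: ConformerTrajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_res = trajectory.n_residues
    n_atoms = n_res * 3
    template = struc.AtomArray(n_atoms)
    template.res_id = np.repeat(trajectory.residue_indices, 3)
    template.res_name = np.repeat(np.asarray(trajectory.residue_names, dtype="U5"), 3)
    template.atom_name = np.tile(np.asarray(BACKBONE_ATOMS, dtype="U4"), n_res)
    template.element = np.tile(np.asarray(["N", "C", "C"], dtype="U2"), n_res)
    template.chain_id = np.full(n_atoms, "A", dtype="U4")
    template.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.AtomArrayStack(trajectory.n_frames, n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = trajectory.coords.reshape(trajectory.n_frames, n_atoms, 3)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, system_label: str = "system", replica_id: int = 0) -> ConformerTrajectory:
    """Read a multi-model PDB, keeping only backbone N/CA/C atoms."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    keep = np.isin(stack.atom_name, BACKBONE_ATOMS)
    stack = stack[..., keep]
    res_ids = np.unique(stack.res_id)
    n_frames = stack.stack_depth()
    coords = np.empty((n_frames, len(res_ids), 3, 3))
    names = []
    for r, rid in enumerate(res_ids):
        for a, atom in enumerate(BACKBONE_ATOMS):
            sel = (stack.res_id == rid) & (stack.atom_name == atom)
            if sel.sum() != 1:
                raise GeometryError(
                    f"residue {rid}: expected exactly one {atom} atom, found {int(sel.sum())}"
                )
            coords[:, r, a, :] = stack.coord[:, sel, :][:, 0, :]
        names.append(str(stack.res_name[(stack.res_id == rid)][0]))
    return ConformerTrajectory(coords, res_ids, names, system_label, replica_id)


def write_coord_csv(trajectory: ConformerTrajectory, path) -> None:
    """Write a long-format coordinate table (frame, residue_index, atom_name, x, y, z)."""
    f, r = np.meshgrid(
        np.arange(trajectory.n_frames), trajectory.residue_indices, indexing="ij"
    )
    frames = np.repeat(f.ravel(), 3)
    residues = np.repeat(r.ravel(), 3)
    atom = np.tile(np.asarray(BACKBONE_ATOMS), trajectory.n_frames * trajectory.n_residues)
    xyz = trajectory.coords.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": frames,
            "residue_index": residues,
            "atom_name": atom,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_coord_csv(path, system_label: str = "system", replica_id: int = 0) -> ConformerTrajectory:
    df = pd.read_csv(path)
    required = {"frame", "residue_index", "atom_name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"coordinate CSV missing columns {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    res_ids = np.sort(df["residue_index"].unique())
    coords = np.empty((len(frames), len(res_ids), 3, 3))
    atom_order = {a: i for i, a in enumerate(BACKBONE_ATOMS)}
    df = df.sort_values(["frame", "residue_index"])
    for (fr, rid), grp in df.groupby(["frame", "residue_index"], sort=True):
        fi = np.searchsorted(frames, fr)
        ri = np.searchsorted(res_ids, rid)
        for _, row in grp.iterrows():
            coords[fi, ri, atom_order[row["atom_name"]]] = (row["x"], row["y"], row["z"])
    return ConformerTrajectory(coords, res_ids, None, system_label, replica_id)
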