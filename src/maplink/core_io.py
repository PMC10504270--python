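"""Shared geometric types and file IO.

This module defines the three containers everything else operates on —
:class:`AtomicModel` (atoms with Cartesian coordinates in Å),
:class:`DensityMap` (a regular voxel grid in Å), and
:class:`RigidTransform` (a proper rotation plus translation) — and the
readers/writers that move them between memory and the standard formats
(mmCIF/PDB for structures, MRC/CCP4 mode-2 for maps, JSON for transforms).

Conventions used throughout the package:

* all coordinates are in Å;
* voxel indices are 0-based and voxel ``(0, 0, 0)`` is *centered* at the
  map origin, so voxel ``(i, j, k)`` is centered at
  ``origin + voxel_size * (i, j, k)``;
* the in-memory map axis order is logical X, Y, Z (axis 0 = X); files
  with permuted MAPC/MAPR/MAPS headers are re-indexed on read so world
  coordinates are unchanged;
* residues are addressed by ``(chain_id, residue_number)`` in author
  numbering; insertion codes are rejected.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-8


class MapLinkError(Exception):
    """Base class for errors raised by this package."""


class ParseError(MapLinkError):
    """A file did not conform to its declared format."""


class ValidationError(MapLinkError):
    """An in-memory object violated one of its invariants."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion ``x -> rotation @ x + translation``.

    ``rotation`` must be a proper orthogonal 3x3 matrix (determinant +1);
    ``translation`` is in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if not np.all(np.isfinite(rot)) or not np.all(np.isfinite(tr)):
            raise ValidationError("rigid transform contains non-finite values")
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > 1e-6:
            raise ValidationError(
                f"rotation matrix is not orthogonal (max |R^T R - I| = {err:.3g})"
            )
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise ValidationError("rotation matrix determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation(cls, rotation: np.ndarray) -> "RigidTransform":
        return cls(rotation, np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    # JSON serialization: {"rotation": 9 numbers row-major, "translation": 3}
    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"], dtype=float).reshape(3, 3),
                   np.array(d["translation"], dtype=float))


def write_transforms(transforms: dict, path) -> None:
    """Write a mapping ``label -> RigidTransform`` as a JSON file."""
    with open(path, "w") as fh:
        json.dump({k: t.to_dict() for k, t in transforms.items()}, fh, indent=1)


def read_transforms(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: RigidTransform.from_dict(d) for k, d in raw.items()}


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------


@dataclass
class AtomicModel:
    """A flat atom table with per-chain subunit labels.

    Columns are parallel arrays over atoms. ``subunit_map`` assigns every
    chain id to a subunit label (e.g. two chains of the same protein copy
    may share a label, or paralog copies get ``"DRC8_copy1"``-style labels);
    it defaults to the identity mapping chain id -> chain id.
    """

    chain_ids: np.ndarray          # str array (N,)
    residue_numbers: np.ndarray    # int array (N,) author numbering
    residue_names: np.ndarray      # str array (N,) 3-letter codes
    atom_names: np.ndarray         # str array (N,)
    elements: np.ndarray           # str array (N,)
    positions: np.ndarray          # float array (N, 3) in Å
    occupancies: np.ndarray = None  # float (N,)
    b_factors: np.ndarray = None    # float (N,) Å²
    subunit_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        if self.b_factors is None:
            self.b_factors = np.zeros(n)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("atom positions must be finite")
        for chain in self.chains():
            if chain not in self.subunit_map:
                self.subunit_map[chain] = chain

    def __len__(self) -> int:
        return len(self.positions)

    def chains(self) -> list:
        """Chain ids in order of first appearance."""
        seen, out = set(), []
        for c in self.chain_ids:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def subunits(self) -> list:
        seen, out = set(), []
        for c in self.chains():
            s = self.subunit_map[c]
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def select(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            self.chain_ids[mask], self.residue_numbers[mask],
            self.residue_names[mask], self.atom_names[mask],
            self.elements[mask], self.positions[mask],
            self.occupancies[mask], self.b_factors[mask],
            dict(self.subunit_map),
        )

    def subunit(self, label: str) -> "AtomicModel":
        chains = {c for c, s in self.subunit_map.items() if s == label}
        return self.select(np.array([c in chains for c in self.chain_ids]))

    def ca_mask(self) -> np.ndarray:
        return np.array([a == "CA" for a in self.atom_names])

    def ca_coords(self) -> np.ndarray:
        return self.positions[self.ca_mask()]

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str = "CA") -> int:
        hits = np.flatnonzero(
            (self.chain_ids == chain_id)
            & (self.residue_numbers == int(residue_number))
            & (self.atom_names == atom_name)
        )
        if len(hits) == 0:
            raise KeyError(
                f"no atom {atom_name!r} in residue ({chain_id}, {residue_number})"
            )
        return int(hits[0])

    def with_positions(self, positions: np.ndarray) -> "AtomicModel":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def subunit_of_atoms(self) -> np.ndarray:
        """Subunit label per atom (object array)."""
        return np.array([self.subunit_map[c] for c in self.chain_ids], dtype=object)


def concat_models(models, labels=None) -> AtomicModel:
    """Concatenate models into one, optionally relabeling each one's chains.

    When ``labels`` is given (one per model), every chain of model *i* is
    renamed to a unique id and mapped to subunit ``labels[i]``.
    """
    chain_pool = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [
        chr(a) + chr(b)
        for a in range(ord("A"), ord("Z") + 1)
        for b in range(ord("A"), ord("Z") + 1)
    ]
    parts, submap = [], {}
    next_chain = 0
    for i, m in enumerate(models):
        rename = {}
        for c in m.chains():
            rename[c] = chain_pool[next_chain]
            next_chain += 1
            submap[rename[c]] = labels[i] if labels is not None else m.subunit_map[c]
        parts.append(
            (np.array([rename[c] for c in m.chain_ids], dtype=object), m)
        )
    return AtomicModel(
        np.concatenate([p[0] for p in parts]),
        np.concatenate([p[1].residue_numbers for p in parts]),
        np.concatenate([p[1].residue_names for p in parts]),
        np.concatenate([p[1].atom_names for p in parts]),
        np.concatenate([p[1].elements for p in parts]),
        np.concatenate([p[1].positions for p in parts]),
        np.concatenate([p[1].occupancies for p in parts]),
        np.concatenate([p[1].b_factors for p in parts]),
        submap,
    )


def apply_transform(model: AtomicModel, t: RigidTransform) -> AtomicModel:
    """Return a copy of ``model`` with every position mapped through ``t``."""
    return model.with_positions(t.apply(model.positions))


def _guess_format(path, format=None) -> str:
    if format is not None:
        f = format.lower()
        if f in ("mmcif", "cif"):
            return "mmcif"
        if f == "pdb":
            return "pdb"
        raise ValueError(f"unsupported structure format {format!r}")
    p = str(path).lower()
    if p.endswith(".cif") or p.endswith(".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path, format=None) -> AtomicModel:
    """Read an mmCIF or PDB file into an :class:`AtomicModel`.

    Author residue numbering is preserved and chains are enumerated in file
    order. Only the first model of a multi-model file is kept (a warning is
    logged); for atoms with alternate locations only the first altloc is
    kept. Residues with insertion codes are rejected.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) > 1:
        logger.warning("%s: %d models present, keeping the first", path, len(st))
    st.remove_alternative_conformations()
    cols = {k: [] for k in ("chain", "resnum", "resname", "atom", "elem")}
    xyz, occ, bf = [], [], []
    model = st[0] if len(st) else []
    for chain in model:
        for res in chain:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise ParseError(
                    f"{path}: residue {chain.name}/{res.seqid.num}{res.seqid.icode.strip()} "
                    "has an insertion code; insertion codes are not supported"
                )
            for atom in res:
                cols["chain"].append(chain.name)
                cols["resnum"].append(res.seqid.num)
                cols["resname"].append(res.name)
                cols["atom"].append(atom.name)
                cols["elem"].append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occ.append(atom.occ)
                bf.append(atom.b_iso)
    return AtomicModel(
        np.array(cols["chain"], dtype=object),
        np.array(cols["resnum"], dtype=int),
        np.array(cols["resname"], dtype=object),
        np.array(cols["atom"], dtype=object),
        np.array(cols["elem"], dtype=object),
        np.array(xyz, dtype=float).reshape(len(xyz), 3),
        np.array(occ, dtype=float),
        np.array(bf, dtype=float),
    )


def write_structure(model: AtomicModel, path, format=None) -> None:
    """Write an :class:`AtomicModel` as mmCIF or PDB (guessed from suffix)."""
    fmt = _guess_format(path, format)
    st = gemmi.Structure()
    st.name = "maplink"
    gm = gemmi.Model("1")
    for chain_id in model.chains():
        ch = gemmi.Chain(str(chain_id))
        cmask = model.chain_ids == chain_id
        idx = np.flatnonzero(cmask)
        current = None
        res = None
        for i in idx:
            key = int(model.residue_numbers[i])
            if current != key:
                if res is not None:
                    ch.add_residue(res)
                res = gemmi.Residue()
                res.name = str(model.residue_names[i])
                res.seqid = gemmi.SeqId(key, " ")
                current = key
            at = gemmi.Atom()
            at.name = str(model.atom_names[i])
            at.element = gemmi.Element(str(model.elements[i]))
            x, y, z = model.positions[i]
            at.pos = gemmi.Position(x, y, z)
            at.occ = float(model.occupancies[i])
            at.b_iso = float(model.b_factors[i])
            res.add_atom(at)
        if res is not None:
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------


@dataclass
class DensityMap:
    """A 3D density grid with isotropic voxels.

    ``values[i, j, k]`` is the density of the voxel centered at
    ``origin + voxel_size * (i, j, k)`` with logical axis order X, Y, Z.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = None
    resolution_hint: float = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("density grid must be 3D with extent >= 1 on each axis")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("density grid contains non-finite values")
        self.voxel_size = float(self.voxel_size)
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.values.shape

    def voxel_volume(self) -> float:
        return self.voxel_size ** 3

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world-coordinate points."""
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, dtype=float) * self.voxel_size + self.origin

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def interpolate(self, points: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Trilinear interpolation at world coordinates (out-of-grid -> fill)."""
        from scipy.ndimage import map_coordinates

        idx = self.world_to_index(points)
        return map_coordinates(
            self.values.astype(float), idx.T, order=1, mode="constant", cval=fill
        )


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing axis order to logical X, Y, Z.

    Files whose MAPC/MAPR/MAPS header permutes the axes are re-indexed so
    that every voxel keeps its world coordinate. The origin is taken from
    the ORIGIN header if set, otherwise from the start offsets.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot read map {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise ParseError(f"{path}: unsupported MRC mode {mode} (only real-valued modes)")
    m.setup(0.0)  # re-orders axes to X, Y, Z
    values = np.array(m.grid, copy=True)
    sx, sy, sz = m.grid.spacing
    if abs(sx - sy) > 1e-4 or abs(sx - sz) > 1e-4:
        raise ParseError(f"{path}: anisotropic voxels are not supported")
    voxel = float(sx)
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    if np.allclose(origin, 0.0):
        start = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float)
        origin = start * voxel
    return DensityMap(values, voxel, origin)


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC/CCP4 mode 2 (32-bit real), X fastest, ORIGIN set."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    n = dmap.shape
    grid.unit_cell = gemmi.UnitCell(
        n[0] * dmap.voxel_size, n[1] * dmap.voxel_size, n[2] * dmap.voxel_size,
        90.0, 90.0, 90.0,
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))
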