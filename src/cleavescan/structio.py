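"""Structure data model and PDB input/output.

The in-memory world uses nanometres throughout; PDB files (Angstrom) are
converted on the way in and out.  A :class:`Structure` is an ordered atom
table plus a bond topology; a :class:`Ensemble` is a set of coordinate
frames sharing one topology.  Multi-model PDB is the ensemble interchange
format.  Bond topology travels in a plain-text sidecar file (two integer
columns of 1-based atom serials), because PDB CONECT records do not cover
polymer topologies.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as _bst
import biotite.structure.io.pdb as _pdbio

NM_PER_ANGSTROM = 0.1

#: default nonbonded-type assignment from PDB atom names (united-atom world)
_NB_BY_NAME = {
    "N": "N",
    "H": "H",
    "CA": "CH1",
    "CB": "CH3",
    "C": "C",
    "O": "O",
    "OXT": "O",
    "CH3": "CH3",
}


class StructureError(ValueError):
    """Raised for malformed structures or files."""


@dataclasses.dataclass
class AtomRecord:
    """One atom: identity labels, position (nm), charge and nonbonded type."""

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    partial_charge: float = 0.0
    nb_type: str = ""


def default_nb_type(atom_name: str, residue_name: str = "") -> str:
    """Guess a nonbonded type from a PDB atom name.

    Glycine's CA is a CH2 bead in the united-atom picture; all other mappings
    are name-based.  Unknown names fall back to an element-like guess.
    """
    if atom_name == "CA" and residue_name == "GLY":
        return "CH2"
    if atom_name in _NB_BY_NAME:
        return _NB_BY_NAME[atom_name]
    head = atom_name.lstrip("0123456789")[:1]
    return {"C": "CH2", "N": "N", "O": "O", "H": "H", "S": "S"}.get(head, "CH2")


class Structure:
    """Ordered atom table with coordinates (nm) and bond topology.

    Atoms of one residue are contiguous; ``(chain_id, residue_index,
    atom_name)`` is unique.  Bonds are unordered pairs of 0-based atom
    indices.  Instances are cheap to copy; coordinate updates go through
    :meth:`with_coords` so cached topology (neighbour lists, nonbonded
    exclusions) is shared between frames.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        coords: np.ndarray,
        elements: Sequence[str] | None = None,
        charges: Sequence[float] | None = None,
        nb_types: Sequence[str] | None = None,
        bonds: Iterable[tuple[int, int]] = (),
        label: str = "",
        validate: bool = True,
    ):
        n = len(atom_names)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if elements is None:
            elements = [str(a).lstrip("0123456789")[:1] for a in atom_names]
        self.elements = np.asarray(elements, dtype=object)
        self.charges = (
            np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
        )
        if nb_types is None:
            nb_types = [
                default_nb_type(a, r) for a, r in zip(atom_names, residue_names)
            ]
        self.nb_types = np.asarray(nb_types, dtype=object)
        self.bonds = frozenset(
            (min(int(i), int(j)), max(int(i), int(j))) for i, j in bonds
        )
        self.label = label
        self._shared_cache: dict = {}
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        n = self.n_atoms
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.residue_indices, self.atom_names))
        if len(set(keys)) != n:
            raise StructureError("(chain, residue, atom name) not unique")
        for i, j in self.bonds:
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i},{j}) references missing atom")
        # residue contiguity
        seen: set[tuple] = set()
        prev = None
        for key in zip(self.chain_ids, self.residue_indices):
            if key != prev:
                if key in seen:
                    raise StructureError(f"residue {key} atoms not contiguous")
                seen.add(key)
                prev = key

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                self.atom_names[i],
                self.elements[i],
                int(self.residue_indices[i]),
                self.residue_names[i],
                self.chain_ids[i],
                self.coords[i].copy(),
                float(self.charges[i]),
                self.nb_types[i],
            )
            for i in range(self.n_atoms)
        ]

    def copy(self) -> "Structure":
        s = self.with_coords(self.coords.copy())
        return s

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A sibling structure with new coordinates but shared topology."""
        s = Structure.__new__(Structure)
        s.atom_names = self.atom_names
        s.residue_indices = self.residue_indices
        s.residue_names = self.residue_names
        s.chain_ids = self.chain_ids
        s.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        s.elements = self.elements
        s.charges = self.charges
        s.nb_types = self.nb_types
        s.bonds = self.bonds
        s.label = self.label
        s._shared_cache = self._shared_cache
        return s

    # -- topology queries ----------------------------------------------------

    def neighbors(self) -> list[list[int]]:
        """Adjacency list of the bond graph (cached)."""
        if "neighbors" not in self._shared_cache:
            adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
            for i, j in sorted(self.bonds):
                adj[i].append(j)
                adj[j].append(i)
            for lst in adj:
                lst.sort()
            self._shared_cache["neighbors"] = adj
        return self._shared_cache["neighbors"]

    def excluded_pairs(self, max_separation: int = 3) -> frozenset:
        """Atom pairs within ``max_separation`` bonds of each other.

        These pairs are excluded from nonbonded sums (the 1-2, 1-3 and 1-4
        neighbours for the default of 3).
        """
        key = ("excl", max_separation)
        if key not in self._shared_cache:
            adj = self.neighbors()
            pairs = set()
            for start in range(self.n_atoms):
                frontier = {start}
                visited = {start}
                for _ in range(max_separation):
                    nxt = set()
                    for a in frontier:
                        for b in adj[a]:
                            if b not in visited:
                                nxt.add(b)
                                visited.add(b)
                                pairs.add((min(start, b), max(start, b)))
                    frontier = nxt
            self._shared_cache[key] = frozenset(pairs)
        return self._shared_cache[key]

    def find_atom(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        mask = (
            (self.chain_ids == chain_id)
            & (self.residue_indices == residue_index)
            & (self.atom_names == atom_name)
        )
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise KeyError(f"no atom {chain_id}/{residue_index}/{atom_name}")
        return int(idx[0])

    def sequence(self, chain_id: str | None = None) -> list[tuple[int, str]]:
        """Ordered (residue_index, residue_name) pairs of one chain."""
        out = []
        prev = None
        for i in range(self.n_atoms):
            if chain_id is not None and self.chain_ids[i] != chain_id:
                continue
            key = (int(self.residue_indices[i]), self.residue_names[i])
            if key != prev:
                out.append(key)
                prev = key
        return out


@dataclasses.dataclass
class Ensemble:
    """Coordinate frames over one shared topology, with per-frame provenance."""

    topology: Structure
    frames: list[np.ndarray]
    provenance: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise StructureError(
                    f"frame {k} has shape {f.shape}, expected {(n, 3)}"
                )
            self.frames[k] = f
        if not self.provenance:
            self.provenance = [{} for _ in self.frames]
        if len(self.provenance) != len(self.frames):
            raise StructureError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    def structure(self, k: int) -> Structure:
        return self.topology.with_coords(self.frames[k])


# -- PDB I/O ------------------------------------------------------------------


def _to_atom_array(structure: Structure) -> _bst.AtomArray:
    n = structure.n_atoms
    arr = _bst.AtomArray(n)
    arr.coord = (structure.coords / NM_PER_ANGSTROM).astype(np.float32)
    arr.atom_name = structure.atom_names.astype("U6")
    arr.res_id = structure.residue_indices
    arr.res_name = structure.residue_names.astype("U5")
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.element = structure.elements.astype("U2")
    return arr


def write_pdb(obj: Structure | Ensemble, path, bonds_path=None) -> None:
    """Write a structure (or a multi-MODEL ensemble) as PDB.

    Coordinates are emitted in Angstrom at the format's 3-decimal precision.
    When ``bonds_path`` is given the bond topology is written as a two-column
    sidecar of 1-based atom serials.
    """
    if isinstance(obj, Ensemble):
        top = obj.topology
        for c in top.chain_ids:
            if len(str(c)) > 1:
                raise StructureError(f"chain id {c!r} exceeds the PDB 1-char field")
        arrays = []
        for f in obj.frames:
            arrays.append(_to_atom_array(top.with_coords(f)))
        stack = _bst.stack(arrays)
        pdb_file = _pdbio.PDBFile()
        _pdbio.set_structure(pdb_file, stack)
        pdb_file.write(str(path))
        bonds = top.bonds
    else:
        for c in obj.chain_ids:
            if len(str(c)) > 1:
                raise StructureError(f"chain id {c!r} exceeds the PDB 1-char field")
        pdb_file = _pdbio.PDBFile()
        _pdbio.set_structure(pdb_file, _to_atom_array(obj))
        pdb_file.write(str(path))
        bonds = obj.bonds
    if bonds_path is not None:
        write_bond_list(bonds, bonds_path)


def write_bond_list(bonds: Iterable[tuple[int, int]], path) -> None:
    with open(path, "w") as fh:
        for i, j in sorted((min(i, j), max(i, j)) for i, j in bonds):
            fh.write(f"{i + 1} {j + 1}\n")


def read_bond_list(path) -> list[tuple[int, int]]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise StructureError(f"{path}:{ln}: expected two integer columns")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise StructureError(f"{path}:{ln}: non-integer serial") from exc
        out.append((i - 1, j - 1))
    return out


def _from_atom_array(arr: _bst.AtomArray, bonds, label: str) -> Structure:
    return Structure(
        atom_names=[str(a) for a in arr.atom_name],
        residue_indices=arr.res_id.tolist(),
        residue_names=[str(r) for r in arr.res_name],
        chain_ids=[str(c) for c in arr.chain_id],
        coords=arr.coord.astype(float) * NM_PER_ANGSTROM,
        elements=[str(e) for e in arr.element],
        bonds=bonds,
        label=label,
    )


def read_pdb(path, bonds_path=None) -> Structure | Ensemble:
    """Read a PDB file; >1 MODEL block yields an :class:`Ensemble`.

    Coordinates come back in nm.  Insertion codes are rejected; an
    inconsistent atom count across models is an error.  Charges come back as
    zero and nonbonded types from the name heuristic — callers wanting
    force-field metadata apply it afterwards (see ``ffenergy.apply_charges``).
    """
    try:
        pdb_file = _pdbio.PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite message passthrough
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    try:
        model_count = pdb_file.get_model_count()
    except Exception as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    bonds = read_bond_list(bonds_path) if bonds_path is not None else ()
    label = Path(str(path)).stem
    for ln, line in enumerate(pdb_file.lines, start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) > 26 and \
                line[26] != " ":
            raise StructureError(
                f"{path}:{ln}: insertion codes are not supported"
            )

    def _one(model: int) -> _bst.AtomArray:
        try:
            return pdb_file.get_structure(model=model)
        except Exception as exc:
            raise StructureError(f"{path}: malformed model {model}: {exc}") from exc

    if model_count == 1:
        return _from_atom_array(_one(1), bonds, label)
    arrays = [_one(m) for m in range(1, model_count + 1)]
    counts = {a.array_length() for a in arrays}
    if len(counts) != 1:
        raise StructureError(
            f"{path}: inconsistent atom counts across models: {sorted(counts)}"
        )
    top = _from_atom_array(arrays[0], bonds, label)
    frames = [a.coord.astype(float) * NM_PER_ANGSTROM for a in arrays]
    prov = [{"model": m + 1} for m in range(len(arrays))]
    return Ensemble(top, frames, prov)


# -- selection ----------------------------------------------------------------

BACKBONE3 = ("N", "CA", "C")


def select(structure: Structure, query) -> np.ndarray:
    """Resolve a selection to an ordered 0-based atom-index array.

    ``query`` is either a shorthand (``"backbone3"`` — the N/CA/C backbone
    atoms; ``"fit4"`` — the four ligation fit atoms, see ``stitcher``), a
    string of ``and``-joined terms (``name N CA C``, ``resid 1-4``,
    ``chain A``), or an explicit index sequence.  The result preserves
    structure order; an empty match is an empty array, not an error.
    """
    if isinstance(query, (list, tuple, np.ndarray)):
        return np.asarray(query, dtype=int)
    if not isinstance(query, str):
        raise TypeError(f"unsupported query type {type(query)!r}")
    q = query.strip()
    if q == "backbone3":
        q = "name N CA C"
    elif q == "fit4":
        from .stitcher import fit4_indices  # local import to avoid a cycle

        return fit4_indices(structure)
    mask = np.ones(structure.n_atoms, dtype=bool)
    for term in q.split(" and "):
        parts = term.split()
        if not parts:
            continue
        kind, args = parts[0], parts[1:]
        if kind == "name":
            mask &= np.isin(structure.atom_names.astype(str), args)
        elif kind == "resid":
            sub = np.zeros(structure.n_atoms, dtype=bool)
            for a in args:
                a = a.replace(":", "-")
                if "-" in a[1:]:  # range; a leading '-' would be a sign
                    lo_s, hi_s = a[1:].split("-", 1)
                    lo, hi = int(a[0] + lo_s), int(hi_s)
                    sub |= (structure.residue_indices >= lo) & (
                        structure.residue_indices <= hi
                    )
                else:
                    sub |= structure.residue_indices == int(a)
            mask &= sub
        elif kind == "chain":
            mask &= np.isin(structure.chain_ids.astype(str), args)
        else:
            raise ValueError(f"unknown selection term {kind!r}")
    return np.nonzero(mask)[0]


def determine_flexible_span(secondary_structure: str, min_len: int = 4) -> int:
    """Length of the flexible N-terminal span from a per-residue H/E/C string.

    The span is the leading run of coil ('C') assignments, floored at
    ``min_len`` — a protease active site with nine substrate-binding subsites
    needs at least four substrate residues upstream of the fold to reach the
    scissile position, so at least four residues are treated as flexible even
    when secondary structure starts at residue 1.
    """
    ss = secondary_structure.strip().upper()
    if not ss:
        raise ValueError("empty secondary-structure string")
    if any(c not in "HEC" for c in ss):
        raise ValueError("secondary structure must use H/E/C only")
    if len(ss) < min_len:
        raise ValueError(
            f"secondary-structure string shorter than the minimum span ({min_len})"
        )
    run = 0
    for c in ss:
        if c != "C":
            break
        run += 1
    return max(run, min_len)
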