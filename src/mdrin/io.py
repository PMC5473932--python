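"""Structures, trajectories and domain partitions.

All downstream modules consume only the types defined here: a light
:class:`Topology` (residue index/name, atom name, element per atom), a
:class:`Trajectory` (frames x atoms x 3 coordinates in Angstrom) and a
:class:`DomainPartition` (residue -> domain tag).  Multi-model PDB is the
canonical on-disk format; DCD/XTC-class containers are read through
MDAnalysis when it is installed.

Residue numbering is 1-based throughout (as in PDB files); internal atom
indices are 0-based and never serialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Topology",
    "Trajectory",
    "DomainPartition",
    "read_structure_frames",
    "write_trajectory_pdb",
    "read_domain_partition",
    "write_feature_table",
    "read_feature_table",
]

DOMAIN_TAGS = ("a", "b", "b'", "a'", "L1", "x-linker", "other")


@dataclass
class Topology:
    """Ordered atom metadata for one chain.

    Residue indices must be non-decreasing along the atom list.
    """

    residue_indices: np.ndarray  # (n_atoms,) int, 1-based
    residue_names: np.ndarray  # (n_atoms,) str
    atom_names: np.ndarray  # (n_atoms,) str
    elements: np.ndarray  # (n_atoms,) str
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype="U4")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        n = len(self.residue_indices)
        for arr, what in (
            (self.residue_names, "residue_names"),
            (self.atom_names, "atom_names"),
            (self.elements, "elements"),
        ):
            if len(arr) != n:
                raise ValueError(f"{what} length {len(arr)} != {n} atoms")
        if n and np.any(np.diff(self.residue_indices) < 0):
            raise ValueError("residue indices must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_indices)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue indices in order of appearance."""
        _, first = np.unique(self.residue_indices, return_index=True)
        return self.residue_indices[np.sort(first)]

    def ca_mask(self) -> np.ndarray:
        return self.atom_names == "CA"

    def ca_index_of(self, residue: int) -> int:
        hits = np.flatnonzero((self.residue_indices == residue) & self.ca_mask())
        if len(hits) == 0:
            raise ValueError(f"residue {residue} has no CA atom")
        return int(hits[0])

    def atom_mask(self, residues=None, atom_names=None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            mask &= np.isin(self.residue_indices, np.asarray(list(residues), dtype=int))
        if atom_names is not None:
            mask &= np.isin(self.atom_names, np.asarray(list(atom_names)))
        return mask


@dataclass
class Trajectory:
    """Coordinates (frames x atoms x 3, Angstrom) over a fixed topology."""

    topology: Topology
    coordinates: np.ndarray
    frame_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates")
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels)
            if len(self.frame_labels) != self.n_frames:
                raise ValueError("frame_labels length != number of frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def ca_coordinates(self, residues=None) -> np.ndarray:
        """Ca coordinates, optionally restricted to a residue subset."""
        mask = self.topology.ca_mask()
        if residues is not None:
            mask &= self.topology.atom_mask(residues=residues)
        return self.coordinates[:, mask, :]


@dataclass
class DomainPartition:
    """Assignment of every residue to a domain tag (a, b, b', a', linkers)."""

    assignment: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, tag in self.assignment.items():
            if not isinstance(tag, str):
                raise ValueError(f"non-string tag for residue {res}")

    def tag_of(self, residue: int) -> str:
        return self.assignment.get(residue, "other")

    def residues(self, tag: str) -> list[int]:
        return sorted(r for r, t in self.assignment.items() if t == tag)

    @property
    def tags(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    @classmethod
    def from_ranges(
        cls, ranges: dict[str, list[tuple[int, int]]], topology: Topology
    ) -> "DomainPartition":
        """Build a complete partition from residue ranges per tag.

        Residues of the topology not covered by any range are tagged
        ``"other"``.  Overlapping ranges and ranges outside the topology
        are rejected.
        """
        topo_residues = set(int(r) for r in topology.residue_ids)
        assignment: dict[int, str] = {}
        for tag, tag_ranges in ranges.items():
            for lo, hi in tag_ranges:
                if lo > hi:
                    raise ValueError(f"range {lo}-{hi} for '{tag}' is inverted")
                for res in range(int(lo), int(hi) + 1):
                    if res not in topo_residues:
                        raise ValueError(
                            f"residue {res} of '{tag}' outside topology"
                        )
                    if res in assignment:
                        raise ValueError(
                            f"residue {res} assigned to both "
                            f"'{assignment[res]}' and '{tag}'"
                        )
                    assignment[res] = tag
        for res in topo_residues:
            assignment.setdefault(res, "other")
        return cls(assignment)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _scan_pdb_model_atom_counts(path: Path) -> list[int]:
    counts: list[int] = []
    in_model = False
    n = 0
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                n = 0
            elif rec.startswith("ENDMDL"):
                counts.append(n)
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                if saw_model and not in_model:
                    continue
                n += 1
    if not saw_model:
        counts = [n]
    return counts


def read_structure_frames(
    path: str | Path,
    topology_path: str | Path | None = None,
    chain: str = "A",
) -> Trajectory:
    """Read a multi-model PDB, or a DCD/XTC-class trajectory plus topology.

    One frame per MODEL record (PDB) or per stored frame (binary
    container); atom order is identical across frames.  Only the named
    chain is read (default ``A``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return _read_multimodel_pdb(path, chain)
    if suffix in (".dcd", ".xtc", ".trr"):
        if topology_path is None:
            raise ValueError(f"{suffix} trajectory requires a topology file")
        return _read_binary_trajectory(path, Path(topology_path), chain)
    raise ValueError(f"unknown trajectory format: {path.name}")


def _read_multimodel_pdb(path: Path, chain: str) -> Trajectory:
    import biotite.structure.io.pdb as pdb

    counts = _scan_pdb_model_atom_counts(path)
    if len(set(counts)) > 1:
        ref = counts[0]
        bad = next(i for i, c in enumerate(counts, start=1) if c != ref)
        raise ValueError(
            f"inconsistent atom count across models: frame {bad} has "
            f"{counts[bad - 1]} atoms, frame 1 has {ref}"
        )
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None, altloc="first")
    mask = stack.chain_id == chain
    if not mask.any():
        raise ValueError(f"chain '{chain}' not found in {path.name}")
    stack = stack[..., mask]
    topo = Topology(
        residue_indices=stack.res_id,
        residue_names=stack.res_name,
        atom_names=stack.atom_name,
        elements=stack.element,
        chain_id=chain,
    )
    return Trajectory(topology=topo, coordinates=np.asarray(stack.coord, dtype=float))


def _read_binary_trajectory(path: Path, topology_path: Path, chain: str) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading DCD/XTC trajectories requires MDAnalysis") from exc

    u = mda.Universe(str(topology_path), str(path))
    sel = u.select_atoms(f"chainID {chain}") if hasattr(u.atoms, "chainIDs") else u.atoms
    if len(sel) == 0:
        sel = u.atoms
    coords = np.stack([sel.positions.copy() for _ in u.trajectory]).astype(float)
    topo = Topology(
        residue_indices=sel.resids,
        residue_names=sel.resnames,
        atom_names=sel.names,
        elements=getattr(sel, "elements", np.array([n[0] for n in sel.names])),
        chain_id=chain,
    )
    return Trajectory(topology=topo, coordinates=coords)


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    topo = traj.topology
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.coordinates.astype(np.float32)
    stack.chain_id = np.full(traj.n_atoms, topo.chain_id, dtype="U4")
    stack.res_id = topo.residue_indices.copy()
    stack.res_name = topo.residue_names.copy()
    stack.atom_name = topo.atom_names.copy()
    stack.element = topo.elements.copy()
    stack.hetero = np.zeros(traj.n_atoms, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    path = Path(path)
    pdb_file.write(str(path))
    return path


def read_domain_partition(path: str | Path, topology: Topology) -> DomainPartition:
    """Read a YAML/JSON domain config of residue ranges per tag.

    Accepted per-tag forms: ``"5-20"``, ``[5, 20]``, or a list of either.
    An empty config tags every residue ``"other"``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("domain config must map tags to residue ranges")
    ranges: dict[str, list[tuple[int, int]]] = {}
    for tag, val in raw.items():
        ranges[str(tag)] = _parse_ranges(val, tag)
    return DomainPartition.from_ranges(ranges, topology)


def _parse_ranges(val, tag) -> list[tuple[int, int]]:
    def one(item) -> tuple[int, int]:
        if isinstance(item, str):
            lo, _, hi = item.partition("-")
            return int(lo), int(hi if hi else lo)
        if isinstance(item, (list, tuple)) and len(item) == 2:
            return int(item[0]), int(item[1])
        if isinstance(item, int):
            return item, item
        raise ValueError(f"cannot parse range {item!r} for '{tag}'")

    if isinstance(val, (str, int)):
        return [one(val)]
    if isinstance(val, (list, tuple)):
        if len(val) == 2 and all(isinstance(x, int) for x in val):
            return [one(val)]
        return [one(item) for item in val]
    raise ValueError(f"cannot parse ranges {val!r} for '{tag}'")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-frame feature table as TSV (one row per frame).

    A ``state`` column holds the labels.  Non-finite values are rejected
    with the offending row and column named.
    """
    numeric = table.select_dtypes(include=[np.number])
    bad = ~np.isfinite(numeric.to_numpy())
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value at row {numeric.index[r]}, "
            f"column '{numeric.columns[c]}'"
        )
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
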