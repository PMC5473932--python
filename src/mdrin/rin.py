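"""Per-frame typed residue interaction networks from geometry.

Each frame becomes a graph with residues as vertices and non-covalent
contacts as typed edges; five interaction types are detected — hydrogen
bond, van der Waals, salt bridge, pi-pi and cation-pi — from documented
geometric criteria (distance cutoffs plus a donor-H-acceptor angle gate
for hydrogen bonds).  A pair of residues may carry several edges of
different types in the same frame.

The criteria are literature-standard defaults, shipped as a versioned,
user-overridable config:

* hydrogen bond: donor-acceptor heavy-atom distance <= 3.5 A and, when a
  donor hydrogen is present, D-H...A angle >= 120 deg (heavy-atom-only
  fallback otherwise);
* salt bridge: charged-group centroid distance <= 4.0 A between basic
  (Arg, Lys, His) and acidic (Asp, Glu) groups;
* van der Waals: heavy-atom distance <= sum of vdW radii + 0.5 A;
* pi-pi: aromatic ring-centroid distance <= 6.5 A;
* cation-pi: cation center to ring centroid <= 6.0 A.

Residues closer than 2 in sequence are excluded (covalent neighbours are
not non-covalent contacts).  Coarse synthetic fixtures may attach labelled
pseudo-atoms (DON/HD, ACC, POSC, NEGC, RNGC) that stand directly for
donor, acceptor, charge-center and ring-centroid groups, so detection is
testable without full side-chain chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .io import Topology, Trajectory

__all__ = [
    "INTERACTION_TYPES",
    "InteractionCriteria",
    "AdjacencySeries",
    "detect_interactions",
    "build_adjacency_series",
    "write_sif",
]

INTERACTION_TYPES = ("hbond", "vdw", "salt_bridge", "pi_pi", "cation_pi")

CRITERIA_VERSION = "1.0"

# vdW radii (A) by element; atoms with other elements (pseudo-atom markers,
# hydrogens) do not take part in vdW detection
_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

_DONOR_ATOMS = {
    None: {"N"},  # backbone amide of every residue
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "CYS": {"SG"},
}
_ACCEPTOR_ATOMS = {
    None: {"O", "OXT"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}
_POSITIVE_GROUPS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_NEGATIVE_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_RING_GROUPS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# pseudo-atom markers used by coarse synthetic fixtures
_PSEUDO_DONOR, _PSEUDO_DONOR_H = "DON", "HD"
_PSEUDO_ACCEPTOR = "ACC"
_PSEUDO_POSITIVE, _PSEUDO_NEGATIVE = "POSC", "NEGC"
_PSEUDO_RING = "RNGC"


@dataclass
class InteractionCriteria:
    """Geometric cutoffs for the five interaction types (all overridable)."""

    hbond_distance: float = 3.5  # A, donor-acceptor heavy atoms
    hbond_angle: float = 120.0  # deg, D-H...A gate when H is present
    salt_bridge_distance: float = 4.0  # A, charged-group centroids
    vdw_slack: float = 0.5  # A added to the radii sum
    pi_pi_distance: float = 6.5  # A, ring centroids
    cation_pi_distance: float = 6.0  # A, cation center to ring centroid
    min_sequence_separation: int = 2  # exclude i, i+-1
    version: str = CRITERIA_VERSION

    def validate(self) -> None:
        for name in (
            "hbond_distance",
            "salt_bridge_distance",
            "vdw_slack",
            "pi_pi_distance",
            "cation_pi_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InteractionCriteria":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class AdjacencySeries:
    """Binary interaction time series A_ij(t) for one pair and one type."""

    kind: str
    pair: tuple[int, int]  # residue indices, i < j
    values: np.ndarray  # (n_frames,) uint8 in {0, 1}

    def __post_init__(self) -> None:
        if self.kind not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type '{self.kind}'")
        i, j = self.pair
        if i >= j:
            raise ValueError("pair must be ordered (i < j), no self pairs")
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency values must be binary")


@dataclass
class _ResidueGroups:
    """Interaction-relevant sites per residue, resolved once per topology."""

    residues: np.ndarray  # (R,) residue ids in order
    donors: list[list[tuple[int, list[int]]]]  # per residue: (donor atom, its Hs)
    acceptors: list[list[int]]
    positive: list[list[list[int]]]  # per residue: list of atom-index groups
    negative: list[list[list[int]]]
    rings: list[list[list[int]]]
    heavy: list[list[int]]
    heavy_radii: list[np.ndarray]
    atom_indices: list[np.ndarray]  # all atoms per residue, for the pair gate


def _resolve_groups(topo: Topology) -> _ResidueGroups:
    residues = topo.residue_ids
    by_res = {int(r): np.flatnonzero(topo.residue_indices == r) for r in residues}
    donors, acceptors, positive, negative, rings, heavy, heavy_radii = (
        [],
        [],
        [],
        [],
        [],
        [],
        [],
    )

    def find(atom_idx, names) -> list[int]:
        return [int(i) for i in atom_idx if topo.atom_names[i] in names]

    for r in residues:
        idx = by_res[int(r)]
        resname = str(topo.residue_names[idx[0]])
        names = {str(topo.atom_names[i]): int(i) for i in idx}
        # hydrogens, mapped to the nearest heavy atom at bond range later
        h_atoms = [int(i) for i in idx if topo.elements[i] == "H"]
        res_donors: list[tuple[int, list[int]]] = []
        donor_names = set(_DONOR_ATOMS[None]) | _DONOR_ATOMS.get(resname, set())
        donor_names.add(_PSEUDO_DONOR)
        for nm in sorted(donor_names):
            if nm in names:
                res_donors.append((names[nm], h_atoms))
        donors.append(res_donors)
        acc_names = set(_ACCEPTOR_ATOMS[None]) | _ACCEPTOR_ATOMS.get(resname, set())
        acc_names.add(_PSEUDO_ACCEPTOR)
        acceptors.append(find(idx, acc_names))
        pos_groups: list[list[int]] = []
        grp = _POSITIVE_GROUPS.get(resname)
        if grp:
            members = find(idx, set(grp))
            if members:
                pos_groups.append(members)
        if _PSEUDO_POSITIVE in names:
            pos_groups.append([names[_PSEUDO_POSITIVE]])
        positive.append(pos_groups)
        neg_groups: list[list[int]] = []
        grp = _NEGATIVE_GROUPS.get(resname)
        if grp:
            members = find(idx, set(grp))
            if members:
                neg_groups.append(members)
        if _PSEUDO_NEGATIVE in names:
            neg_groups.append([names[_PSEUDO_NEGATIVE]])
        negative.append(neg_groups)
        ring_groups: list[list[int]] = []
        grp = _RING_GROUPS.get(resname)
        if grp:
            members = find(idx, set(grp))
            if len(members) >= 3:
                ring_groups.append(members)
        if _PSEUDO_RING in names:
            ring_groups.append([names[_PSEUDO_RING]])
        rings.append(ring_groups)
        hv = [
            int(i)
            for i in idx
            if str(topo.elements[i]) in _VDW_RADII
        ]
        heavy.append(hv)
        heavy_radii.append(np.array([_VDW_RADII[str(topo.elements[i])] for i in hv]))
    return _ResidueGroups(
        residues=residues,
        donors=donors,
        acceptors=acceptors,
        positive=positive,
        negative=negative,
        rings=rings,
        heavy=heavy,
        heavy_radii=heavy_radii,
        atom_indices=[by_res[int(r)] for r in residues],
    )


def _centroid(coords: np.ndarray, members: list[int]) -> np.ndarray:
    return coords[members].mean(axis=0)


def detect_interactions(
    coords: np.ndarray,
    topology: Topology,
    criteria: InteractionCriteria | None = None,
    _groups: _ResidueGroups | None = None,
) -> set[tuple[int, int, str]]:
    """Typed residue-pair edges of one frame.

    Returns a set of (res_i, res_j, type) with res_i < res_j and
    |res_i - res_j| >= the sequence-separation minimum.  Residues lacking
    the atoms a rule needs simply do not produce edges of that type.
    Detection is deterministic and invariant to global rotation and
    translation (all rules are distance/angle based).
    """
    criteria = criteria or InteractionCriteria()
    criteria.validate()
    groups = _groups if _groups is not None else _resolve_groups(topology)
    coords = np.asarray(coords, dtype=float)
    res = groups.residues
    n = len(res)
    edges: set[tuple[int, int, str]] = set()

    # conservative pair gate: residues whose atom clouds cannot come within
    # the largest cutoff of each other are skipped outright
    centroids = np.stack(
        [coords[idx].mean(axis=0) for idx in groups.atom_indices]
    )
    radii = np.array(
        [
            np.linalg.norm(coords[idx] - c, axis=1).max()
            for idx, c in zip(groups.atom_indices, centroids)
        ]
    )
    max_cut = max(
        criteria.hbond_distance,
        criteria.salt_bridge_distance,
        criteria.pi_pi_distance,
        criteria.cation_pi_distance,
        2 * max(_VDW_RADII.values()) + criteria.vdw_slack,
    )
    cdm = cdist(centroids, centroids)
    reach = radii[:, None] + radii[None, :] + max_cut

    def admissible(ri: int, rj: int) -> bool:
        return abs(int(res[ri]) - int(res[rj])) >= criteria.min_sequence_separation

    def add(ri: int, rj: int, kind: str) -> None:
        a, b = int(res[ri]), int(res[rj])
        edges.add((min(a, b), max(a, b), kind))

    for i in range(n):
        for j in range(i + 1, n):
            if cdm[i, j] > reach[i, j] or not admissible(i, j):
                continue
            # hydrogen bonds, both donor/acceptor assignments
            for di, ai in ((i, j), (j, i)):
                for donor, hs in groups.donors[di]:
                    for acc in groups.acceptors[ai]:
                        d = np.linalg.norm(coords[donor] - coords[acc])
                        if d > criteria.hbond_distance or d == 0:
                            continue
                        bonded_h = [
                            h
                            for h in hs
                            if np.linalg.norm(coords[h] - coords[donor]) < 1.3
                        ]
                        if bonded_h:
                            ok = any(
                                _dha_angle(coords[donor], coords[h], coords[acc])
                                >= criteria.hbond_angle
                                for h in bonded_h
                            )
                        else:
                            ok = True  # heavy-atom-only fallback
                        if ok:
                            add(i, j, "hbond")
            # salt bridges: charged-group centroids
            for pi_, ni_ in ((i, j), (j, i)):
                for pg in groups.positive[pi_]:
                    for ng in groups.negative[ni_]:
                        d = np.linalg.norm(
                            _centroid(coords, pg) - _centroid(coords, ng)
                        )
                        if d <= criteria.salt_bridge_distance:
                            add(i, j, "salt_bridge")
            # pi-pi stacking: ring centroids
            for ra in groups.rings[i]:
                for rb in groups.rings[j]:
                    d = np.linalg.norm(_centroid(coords, ra) - _centroid(coords, rb))
                    if d <= criteria.pi_pi_distance:
                        add(i, j, "pi_pi")
            # cation-pi
            for ci_, ri_ in ((i, j), (j, i)):
                for pg in groups.positive[ci_]:
                    for rb in groups.rings[ri_]:
                        d = np.linalg.norm(
                            _centroid(coords, pg) - _centroid(coords, rb)
                        )
                        if d <= criteria.cation_pi_distance:
                            add(i, j, "cation_pi")
            # van der Waals: heavy-atom contact
            hi, hj = groups.heavy[i], groups.heavy[j]
            if hi and hj:
                d = cdist(coords[hi], coords[hj])
                cut = (
                    groups.heavy_radii[i][:, None]
                    + groups.heavy_radii[j][None, :]
                    + criteria.vdw_slack
                )
                if (d <= cut).any():
                    add(i, j, "vdw")
    return edges


def _dha_angle(donor: np.ndarray, h: np.ndarray, acceptor: np.ndarray) -> float:
    u = donor - h
    v = acceptor - h
    denom = np.linalg.norm(u) * np.linalg.norm(v)
    if denom == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(u @ v / denom, -1.0, 1.0))))


def build_adjacency_series(
    traj: Trajectory, criteria: InteractionCriteria | None = None
) -> list[AdjacencySeries]:
    """Binary time series A_ij(t) per (type, pair) over a trajectory.

    One series per (interaction type, residue pair) that is on in at least
    one frame; pairs never on are implicit all-zero and omitted.  Per-frame
    re-detection of any frame equals the series sliced at that frame.
    """
    criteria = criteria or InteractionCriteria()
    groups = _resolve_groups(traj.topology)
    on_frames: dict[tuple[str, int, int], list[int]] = {}
    for f in range(traj.n_frames):
        for i, j, kind in detect_interactions(
            traj.coordinates[f], traj.topology, criteria, _groups=groups
        ):
            on_frames.setdefault((kind, i, j), []).append(f)
    out = []
    for (kind, i, j), frames in sorted(on_frames.items()):
        values = np.zeros(traj.n_frames, dtype=np.uint8)
        values[frames] = 1
        out.append(AdjacencySeries(kind=kind, pair=(i, j), values=values))
    return out


def write_sif(
    edges: set[tuple[int, int, str]] | list[tuple[int, int, str]],
    path: str | Path,
) -> Path:
    """Write one frame's typed edge list in SIF format (node type node)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, j, kind in sorted(edges):
            fh.write(f"{i}\t{kind}\t{j}\n")
    return path
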