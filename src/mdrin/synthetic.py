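"""Synthetic trajectories, feature samples and interaction schedules.

Every downstream stage of the package is testable without real MD data:
this module generates (i) rigid-domain hinge trajectories with thermal
jitter, (ii) per-state feature samples from specified Gaussian mixtures
(unimodal vs. bimodal), and (iii) scripted binary interaction time series
with a known longest run, realised as coordinates that the interaction
detector recovers exactly.

Domains are compact Gaussian blobs of Ca pseudo-atoms spaced on a line;
short linkers join consecutive domains, and the hinge axis passes through
the centroid of the terminal linker.  The generator produces coordinates
and atom types, not chemistry: no force field, no solvent, no
thermodynamically meaningful ensemble.

All randomness derives from a single integer seed expanded into
per-operation substreams, so identical spec + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io import DomainPartition, Topology, Trajectory

__all__ = [
    "FeatureSpec",
    "InteractionSchedule",
    "SyntheticSpec",
    "ScriptedTrajectory",
    "make_hinge_trajectory",
    "hinge_mode_vector",
    "make_anticorrelated_trajectory",
    "make_adjacency_schedule",
    "make_feature_samples",
    "make_scripted_interaction_trajectory",
    "default_partition",
    "write_spec",
    "read_spec",
]

# substream tags for seed expansion
_GEOMETRY, _JITTER, _SCHEDULE, _FEATURES = 11, 13, 17, 19

_DOMAIN_SPACING = 18.0  # A between domain centers
_BLOB_SD = 3.0  # A spread of Ca pseudo-atoms within a domain
_N_LINKER = 3  # residues per inter-domain linker


@dataclass
class FeatureSpec:
    """One scalar feature: a Gaussian mixture per state label.

    ``mixtures`` maps state label -> list of (weight, mean, sd)
    components; weights must sum to 1 and sds be non-negative.
    """

    name: str
    mixtures: dict[str, list[tuple[float, float, float]]]

    def validate(self) -> None:
        for state, comps in self.mixtures.items():
            weights = [w for w, _, _ in comps]
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(
                    f"mixture weights for '{self.name}'/{state} sum to "
                    f"{sum(weights)}, not 1"
                )
            for _, _, sd in comps:
                if sd < 0:
                    raise ValueError(f"negative sd in '{self.name}'/{state}")


@dataclass
class InteractionSchedule:
    """Scripted on/off pattern for one residue pair and interaction type."""

    residues: tuple[int, int] | None  # None -> auto-assigned
    kind: str  # interaction type (hbond, salt_bridge, ...)
    longest_run: int
    total_on: int | None = None  # None -> exactly longest_run on-frames


@dataclass
class SyntheticSpec:
    """Full description of a synthetic two-state fixture."""

    n_domains: int = 4
    residues_per_domain: int = 10
    n_frames: int = 1000
    hinge_amplitude: float = 20.0  # degrees
    hinge_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    jitter_sigma: float = 0.1  # A
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    interaction_schedule: list[InteractionSchedule] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.residues_per_domain < 1:
            raise ValueError("residues_per_domain must be >= 1")
        if self.n_domains < 2:
            raise ValueError("hinge geometry needs >= 2 domains")
        axis = np.asarray(self.hinge_axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
            raise ValueError("hinge_axis must be a unit vector")
        for fs in self.feature_specs:
            fs.validate()
        for entry in self.interaction_schedule:
            total = entry.total_on if entry.total_on is not None else entry.longest_run
            if not 0 <= entry.longest_run <= total <= self.n_frames:
                raise ValueError(
                    f"schedule for {entry.residues}/{entry.kind}: need "
                    f"longest_run <= total_on <= n_frames"
                )


# ---------------------------------------------------------------------------
# hinge trajectories
# ---------------------------------------------------------------------------


def _base_geometry(spec: SyntheticSpec):
    """Static Ca scaffold: domain blobs on a line joined by linkers.

    Returns (coords (N,3), residue_indices, domain_of_atom, pivot) where
    ``pivot`` is the centroid of the terminal linker (hinge point) and
    ``domain_of_atom`` holds domain numbers (0..n_domains-1) or -1 for
    linker atoms.
    """
    rng = np.random.default_rng([spec.seed, _GEOMETRY])
    coords, res_idx, dom = [], [], []
    res = 0
    centers = [np.array([i * _DOMAIN_SPACING, 0.0, 0.0]) for i in range(spec.n_domains)]
    for i, center in enumerate(centers):
        offs = rng.normal(scale=_BLOB_SD, size=(spec.residues_per_domain, 3))
        for off in offs:
            res += 1
            coords.append(center + off)
            res_idx.append(res)
            dom.append(i)
        if i < spec.n_domains - 1:
            nxt = centers[i + 1]
            for k in range(1, _N_LINKER + 1):
                res += 1
                frac = k / (_N_LINKER + 1)
                coords.append(center + frac * (nxt - center))
                res_idx.append(res)
                dom.append(-1)
    coords = np.asarray(coords)
    dom = np.asarray(dom)
    res_idx = np.asarray(res_idx)
    # hinge point: centroid of the last linker's residues
    last_linker = np.flatnonzero(dom == -1)[-_N_LINKER:]
    pivot = coords[last_linker].mean(axis=0)
    return coords, res_idx, dom, pivot


def _ca_topology(res_idx: np.ndarray) -> Topology:
    n = len(res_idx)
    return Topology(
        residue_indices=res_idx,
        residue_names=np.full(n, "GLY"),
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
    )


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis and angle in radians."""
    ux, uy, uz = axis
    k = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_hinge_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Rigid hinge motion of the terminal domain plus Gaussian jitter.

    The terminal domain rotates rigidly about ``spec.hinge_axis`` through
    the terminal-linker centroid by amplitude * sin(2*pi*t / n_frames);
    independent N(0, jitter_sigma^2) noise is added per atom per frame.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    base, res_idx, dom, pivot = _base_geometry(spec)
    axis = np.asarray(spec.hinge_axis, dtype=float)
    terminal = dom == spec.n_domains - 1
    t = np.arange(spec.n_frames)
    angles = np.deg2rad(spec.hinge_amplitude) * np.sin(2 * np.pi * t / spec.n_frames)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    centered = base[terminal] - pivot
    for f, ang in enumerate(angles):
        coords[f, terminal] = centered @ _rotation_about_axis(axis, ang).T + pivot
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng([spec.seed, _JITTER])
        coords += rng.normal(scale=spec.jitter_sigma, size=coords.shape)
    return Trajectory(topology=_ca_topology(res_idx), coordinates=coords)


def hinge_mode_vector(spec: SyntheticSpec) -> np.ndarray:
    """Planted displacement direction of the hinge, as a unit 3N vector.

    The instantaneous atomic velocity of a rotation about axis u through
    pivot c is u x (x - c); atoms outside the terminal domain do not move.
    """
    spec.validate()
    base, _, dom, pivot = _base_geometry(spec)
    axis = np.asarray(spec.hinge_axis, dtype=float)
    mode = np.zeros_like(base)
    terminal = dom == spec.n_domains - 1
    mode[terminal] = np.cross(axis, base[terminal] - pivot)
    flat = mode.ravel()
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise ValueError("degenerate hinge: terminal domain on the axis")
    return flat / norm


def make_anticorrelated_trajectory(
    n_frames: int = 1000,
    seed: int = 0,
    amplitude: float = 3.0,
    jitter_sigma: float = 0.1,
    n_domains: int = 4,
    residues_per_domain: int = 10,
) -> tuple[Trajectory, DomainPartition]:
    """Two terminal domains translating in exact anti-phase.

    The first domain moves +amplitude*sin(2*pi*t/T) along z while the last
    moves by the negative of that, emulating anti-correlated terminal
    domain motions on a static base.
    """
    spec = SyntheticSpec(
        n_domains=n_domains,
        residues_per_domain=residues_per_domain,
        n_frames=n_frames,
        jitter_sigma=jitter_sigma,
        seed=seed,
    )
    base, res_idx, dom, _ = _base_geometry(spec)
    t = np.arange(n_frames)
    disp = amplitude * np.sin(2 * np.pi * t / n_frames)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    coords[:, dom == 0, 2] += disp[:, None]
    coords[:, dom == n_domains - 1, 2] -= disp[:, None]
    if jitter_sigma > 0:
        rng = np.random.default_rng([seed, _JITTER])
        coords += rng.normal(scale=jitter_sigma, size=coords.shape)
    traj = Trajectory(topology=_ca_topology(res_idx), coordinates=coords)
    return traj, default_partition(spec)


def default_partition(spec: SyntheticSpec) -> DomainPartition:
    """Domain tags for the generated scaffold.

    Four domains get the thioredoxin-fold names a, b, b', a'; the first
    linker is L1, the terminal linker is the x-linker, interior linkers
    are "other".  Other domain counts fall back to d0, d1, ...
    """
    _, res_idx, dom, _ = _base_geometry(spec)
    if spec.n_domains == 4:
        names = ["a", "b", "b'", "a'"]
    else:
        names = [f"d{i}" for i in range(spec.n_domains)]
    assignment: dict[int, str] = {}
    linker_blocks: list[list[int]] = []
    current: list[int] = []
    for res, d in zip(res_idx, dom):
        if d >= 0:
            assignment[int(res)] = names[d]
            if current:
                linker_blocks.append(current)
                current = []
        else:
            if int(res) not in current:
                current.append(int(res))
    if current:
        linker_blocks.append(current)
    for k, block in enumerate(linker_blocks):
        if k == 0:
            tag = "L1"
        elif k == len(linker_blocks) - 1:
            tag = "x-linker"
        else:
            tag = "other"
        for res in block:
            assignment[res] = tag
    return DomainPartition(assignment)


# ---------------------------------------------------------------------------
# scripted binary interaction schedules
# ---------------------------------------------------------------------------


def make_adjacency_schedule(
    n_frames: int,
    longest_run: int,
    seed: int,
    total_on: int | None = None,
) -> np.ndarray:
    """Binary sequence whose maximum run of consecutive 1s is exact.

    ``total_on`` (default: ``longest_run``) requests the total number of
    on-frames; the extra on-frames are placed as additional runs no longer
    than ``longest_run``, separated by at least one zero.  Deterministic
    given the seed.
    """
    if not 0 <= longest_run <= n_frames:
        raise ValueError("need 0 <= longest_run <= n_frames")
    total = longest_run if total_on is None else total_on
    if not longest_run <= total <= n_frames:
        raise ValueError("need longest_run <= total_on <= n_frames")
    if longest_run == 0:
        if total != 0:
            raise ValueError("total_on must be 0 when longest_run is 0")
        return np.zeros(n_frames, dtype=np.uint8)
    # extra runs no longer than longest_run; >=1 zero between runs prevents merging
    runs = [longest_run]
    rem = total - longest_run
    while rem > 0:
        step = min(longest_run, rem)
        runs.append(step)
        rem -= step
    if sum(runs) + len(runs) - 1 > n_frames:
        raise ValueError(
            f"{total} on-frames in runs <= {longest_run} do not fit in "
            f"{n_frames} frames"
        )
    rng = np.random.default_rng([seed, _SCHEDULE])
    runs = [runs[i] for i in rng.permutation(len(runs))]
    spare = n_frames - sum(runs) - (len(runs) - 1)
    gaps = rng.multinomial(spare, np.full(len(runs) + 1, 1.0 / (len(runs) + 1)))
    seq = np.zeros(n_frames, dtype=np.uint8)
    pos = gaps[0]
    for k, run in enumerate(runs):
        seq[pos : pos + run] = 1
        pos += run + 1 + gaps[k + 1]
    return seq


# ---------------------------------------------------------------------------
# feature samples
# ---------------------------------------------------------------------------


def make_feature_samples(spec: SyntheticSpec, n_per_state: int):
    """Draw labeled per-frame feature values from the spec's mixtures.

    Returns a DataFrame with one column per feature plus a ``state``
    column, ``n_per_state`` rows per state.  Deterministic given the seed.
    """
    import pandas as pd

    spec.validate()
    if not spec.feature_specs:
        raise ValueError("spec has no feature_specs")
    states = sorted({s for fs in spec.feature_specs for s in fs.mixtures})
    if len(states) < 2:
        raise ValueError("need at least two state labels")
    columns: dict[str, np.ndarray] = {}
    labels = np.repeat(states, n_per_state)
    for fi, fs in enumerate(spec.feature_specs):
        vals = []
        for si, state in enumerate(states):
            if state not in fs.mixtures:
                raise ValueError(f"feature '{fs.name}' missing state '{state}'")
            comps = fs.mixtures[state]
            rng = np.random.default_rng([spec.seed, _FEATURES, fi, si])
            weights = np.array([w for w, _, _ in comps])
            means = np.array([m for _, m, _ in comps])
            sds = np.array([s for _, _, s in comps])
            which = rng.choice(len(comps), size=n_per_state, p=weights)
            vals.append(rng.normal(means[which], sds[which]))
        columns[fs.name] = np.concatenate(vals)
    columns["state"] = labels
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# scripted interaction trajectories (end-to-end ground truth)
# ---------------------------------------------------------------------------

# on-distance (A) per interaction type between the mobile group atom and
# its fixed partner; each satisfies the default detection rule with margin
_ON_DISTANCE = {
    "hbond": 2.9,
    "salt_bridge": 3.0,
    "vdw": 3.5,
    "pi_pi": 5.0,
    "cation_pi": 4.5,
}
_OFF_DISTANCE = 20.0
_SITE_SPACING = 60.0  # A between schedule entries: no cross-talk


@dataclass
class ScriptedTrajectory:
    """A trajectory realising scripted interactions, plus the ground truth."""

    trajectory: Trajectory
    # (res_i, res_j, kind) -> binary schedule actually encoded
    schedules: dict[tuple[int, int, str], np.ndarray]


def _entry_atoms(kind: str):
    """Atom (name, element) lists for the two residues of one entry.

    The first atom of each residue is its Ca; index 1 is the fixed group
    atom of residue i; the group atoms of residue j are the mobile ones.
    """
    if kind == "salt_bridge":
        return [("POSC", "X")], [("NEGC", "X")]
    if kind == "hbond":
        return [("DON", "N"), ("HD", "H")], [("ACC", "O")]
    if kind == "vdw":
        return [("CB", "C")], [("CB", "C")]
    if kind == "pi_pi":
        return [("RNGC", "X")], [("RNGC", "X")]
    if kind == "cation_pi":
        return [("POSC", "X")], [("RNGC", "X")]
    raise ValueError(f"unknown interaction type '{kind}'")


def make_scripted_interaction_trajectory(
    n_frames: int,
    schedule: list[InteractionSchedule],
    seed: int,
) -> ScriptedTrajectory:
    """Coordinates whose detected interactions follow the given schedules.

    Each schedule entry gets its own well-separated site holding two
    residues (sequence separation 3).  Residue i carries a fixed
    interaction group; residue j's group sits at the type's on-distance in
    on-frames and 20 A away otherwise, so geometric detection recovers the
    scripted binary series exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    res_idx, names, elements = [], [], []
    schedules: dict[tuple[int, int, str], np.ndarray] = {}
    base = []
    movers = []  # (atom index, on xyz, off xyz, series)
    for k, entry in enumerate(schedule):
        total = entry.total_on
        seq = make_adjacency_schedule(
            n_frames, entry.longest_run, seed=(seed * 1009 + k) % (2**31), total_on=total
        )
        if entry.residues is not None:
            ri, rj = entry.residues
        else:
            ri, rj = 10 * k + 1, 10 * k + 4
        if abs(ri - rj) < 2:
            raise ValueError(f"residues {ri},{rj} too close in sequence")
        z = k * _SITE_SPACING
        atoms_i, atoms_j = _entry_atoms(entry.kind)
        # residue i: Ca + fixed group
        res_idx.append(ri), names.append("CA"), elements.append("C")
        base.append([0.0, 0.0, z])
        group_x = 4.0
        for n, (nm, el) in enumerate(atoms_i):
            res_idx.append(ri), names.append(nm), elements.append(el)
            base.append([group_x + n * 1.0, 0.0, z])  # HD sits 1 A past DON
        # residue j: Ca + mobile group
        res_idx.append(rj), names.append("CA"), elements.append("C")
        base.append([14.0, 0.0, z])
        d_on = _ON_DISTANCE[entry.kind]
        ref_x = group_x  # distances measured from the heavy group atom of i
        for nm, el in atoms_j:
            res_idx.append(rj), names.append(nm), elements.append(el)
            idx = len(base)
            base.append([ref_x + _OFF_DISTANCE, 0.0, z])
            movers.append(
                (idx, np.array([ref_x + d_on, 0.0, z]), np.array(base[idx]), seq)
            )
        key = (min(ri, rj), max(ri, rj), entry.kind)
        schedules[key] = seq
    order = np.argsort(np.asarray(res_idx), kind="stable")
    base = np.asarray(base)[order]
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(len(order))
    topo = Topology(
        residue_indices=np.asarray(res_idx)[order],
        residue_names=np.full(len(order), "UNK"),
        atom_names=np.asarray(names)[order],
        elements=np.asarray(elements)[order],
    )
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    for idx, on_xyz, off_xyz, seq in movers:
        j = remap[idx]
        coords[:, j, :] = np.where(seq[:, None].astype(bool), on_xyz, off_xyz)
    return ScriptedTrajectory(
        trajectory=Trajectory(topology=topo, coordinates=coords),
        schedules=schedules,
    )


# ---------------------------------------------------------------------------
# spec (de)serialisation — every fixture ships its generating config
# ---------------------------------------------------------------------------


def write_spec(spec: SyntheticSpec, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)
    return path


def read_spec(path: str | Path) -> SyntheticSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["feature_specs"] = [
        FeatureSpec(
            name=fs["name"],
            mixtures={
                s: [tuple(c) for c in comps] for s, comps in fs["mixtures"].items()
            },
        )
        for fs in raw.get("feature_specs", [])
    ]
    raw["interaction_schedule"] = [
        InteractionSchedule(
            residues=tuple(e["residues"]) if e.get("residues") else None,
            kind=e["kind"],
            longest_run=e["longest_run"],
            total_on=e.get("total_on"),
        )
        for e in raw.get("interaction_schedule", [])
    ]
    raw["hinge_axis"] = tuple(raw["hinge_axis"])
    return SyntheticSpec(**raw)
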