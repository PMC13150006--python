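"""Residue-interaction networks and geometric observables from ensembles.

A coordinate ensemble (multi-model PDB or plain per-frame XYZ table) is
analysed residue-wise:

* **Contact network** — residues are nodes; an edge connects two residues
  when any heavy-atom pair is within 4.5 Å in at least 75% of frames
  (sequence-adjacent residues excluded).  Edges carry the dynamic
  cross-correlation ``C_ij`` of Cα displacements (computed after removing
  global rotation/translation by superposing every frame onto the first)
  and a communication weight ``w_ij = -log|C_ij|``, clamped for ``C_ij``
  near zero, so strongly correlated contacts are short.
* **Communities** — Girvan–Newman edge-betweenness removal with the
  partition chosen at maximum modularity; ties between equal-betweenness
  edges are broken lexicographically for determinism.
* **Shortest communication paths** — Floyd–Warshall over the weights for
  chosen source/sink residues.
* **Hydrogen bonds** — geometric criterion: donor–acceptor distance below
  3.5 Å and donor–hydrogen–acceptor angle of at least 120°; occupancy is
  the fraction of frames satisfying both.
* **χ1 dihedrals** — the N–Cα–Cβ–Cγ side-chain torsion per frame, signed,
  in (−180°, 180°].
* **Welch's t-test** — unequal-variance comparison of occupancy samples
  between conditions.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .errors import (
    DegenerateStatisticsError,
    DomainError,
    InputError,
    SelectionError,
)
from .structure_annotation import Atom, StructureModel, kabsch, parse_structure

# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """A topology plus per-frame coordinates of every atom."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise InputError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != len(self.topology.atoms):
            raise InputError(
                f"frames have {frames.shape[1]} atoms but topology has "
                f"{len(self.topology.atoms)}"
            )
        if frames.shape[0] < 1:
            raise InputError("need at least one frame")
        if not np.isfinite(frames).all():
            raise InputError("non-finite coordinates in trajectory")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ContactEdge:
    i: str
    j: str
    occupancy: float
    correlation: float
    weight: float


@dataclass(frozen=True)
class ContactNetwork:
    """Occupancy-filtered, correlation-weighted residue graph."""

    nodes: tuple[str, ...]
    edges: tuple[ContactEdge, ...]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.i, e.j, occupancy=e.occupancy,
                       correlation=e.correlation, weight=e.weight)
        return g


@dataclass(frozen=True)
class CommunityPartition:
    membership: Mapping[str, int]
    modularity: float

    def communities(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for node, label in self.membership.items():
            groups.setdefault(label, set()).add(node)
        return [groups[k] for k in sorted(groups)]


@dataclass(frozen=True)
class PathResult:
    source: str
    sink: str
    path: tuple[str, ...]
    total_weight: float


@dataclass(frozen=True)
class HBondOccupancy:
    donor: str  # "chain:seq:atom"
    acceptor: str
    occupancy: float


@dataclass(frozen=True)
class DihedralSeries:
    residue: str
    chi1: np.ndarray  # degrees, (-180, 180]


# ---------------------------------------------------------------------------
# Trajectory input


def read_multimodel_pdb(
    path: str | Path, ligand_selector: Iterable[str] | str = ()
) -> TrajectoryEnsemble:
    """Read a multi-model PDB: model 1 is the topology, all models frames."""
    import gemmi

    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    selector = (
        frozenset([ligand_selector]) if isinstance(ligand_selector, str)
        else frozenset(ligand_selector)
    )
    atoms: list[Atom] = []
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    Atom(chain.name, residue.seqid.num,
                         (residue.seqid.icode or "").strip(), residue.name,
                         atom.name, atom.element.name,
                         (atom.pos.x, atom.pos.y, atom.pos.z), atom.occ)
                )
    topology = StructureModel(tuple(atoms), selector)
    frames = np.empty((len(st), len(atoms), 3))
    for m, model in enumerate(st):
        k = 0
        for chain in model:
            for residue in chain:
                for atom in residue:
                    frames[m, k] = (atom.pos.x, atom.pos.y, atom.pos.z)
                    k += 1
        if k != len(atoms):
            raise InputError(f"{path}: model {m + 1} has {k} atoms, expected {len(atoms)}")
    return TrajectoryEnsemble(topology, frames)


def read_xyz_frames(topology: StructureModel, path: str | Path) -> TrajectoryEnsemble:
    """Read a plain-text per-frame XYZ table against an existing topology.

    Format: whitespace-separated ``x y z`` rows in topology atom order,
    frames concatenated (``n_frames * n_atoms`` rows); blank lines and
    ``#`` comments ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"frame table not found: {path}")
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        rows.append([float(p) for p in parts])
    n_atoms = len(topology.atoms)
    if not rows or len(rows) % n_atoms:
        raise InputError(
            f"{path}: {len(rows)} coordinate rows is not a multiple of "
            f"{n_atoms} topology atoms"
        )
    frames = np.array(rows).reshape(-1, n_atoms, 3)
    return TrajectoryEnsemble(topology, frames)


def write_xyz_frames(traj: TrajectoryEnsemble, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"# frame {m + 1}\n")
            for x, y, z in traj.frames[m]:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Contact network

_W_MAX_DEFAULT = 20.0


def _residue_layout(model: StructureModel):
    """Node labels, heavy-atom index lists, Cα indices and chain order index."""
    order: list[tuple[str, str]] = []
    heavy: dict[tuple[str, str], list[int]] = {}
    ca_index: dict[tuple[str, str], int] = {}
    for idx, a in enumerate(model.atoms):
        if a.residue_name in model.ligand_selector:
            continue
        key = a.residue_key
        if key not in heavy:
            heavy[key] = []
            order.append(key)
        if not a.is_hydrogen:
            heavy[key].append(idx)
        if a.atom_name == "CA" and not a.is_hydrogen:
            ca_index[key] = idx
    return order, heavy, ca_index


def node_label(key: tuple[str, str]) -> str:
    return f"{key[0]}:{key[1]}"


def cross_correlation(
    traj: TrajectoryEnsemble,
    ca_indices: Sequence[int],
    align: bool = True,
) -> np.ndarray:
    """Normalized equal-time cross-correlation of Cα displacement vectors.

    ``C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)`` with displacements
    about each residue's mean position, after rigid-body superposition of
    every frame onto the first (``align=False`` skips the fit).
    """
    if traj.n_frames < 2:
        raise DegenerateStatisticsError(
            "cross-correlation undefined for a single frame (zero variance)"
        )
    coords = traj.frames[:, list(ca_indices), :].copy()
    if align and coords.shape[1] >= 3:
        ref = coords[0]
        for m in range(1, coords.shape[0]):
            fit = kabsch(coords[m], ref)
            coords[m] = fit.apply(coords[m])
    disp = coords - coords.mean(axis=0, keepdims=True)
    inner = np.einsum("mik,mjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    if np.any(var <= 0):
        raise DegenerateStatisticsError(
            "a residue shows zero positional variance; correlation undefined"
        )
    return inner / np.sqrt(np.outer(var, var))


def contact_network(
    traj: TrajectoryEnsemble,
    cutoff: float = 4.5,
    occupancy_min: float = 0.75,
    *,
    exclude_adjacent: bool = True,
    w_max: float = _W_MAX_DEFAULT,
    numbering: Mapping[tuple[str, str], str] | None = None,
) -> ContactNetwork:
    """Build the occupancy-filtered, correlation-weighted residue network.

    Occupancy of a residue pair is the fraction of frames with any
    heavy-atom distance below ``cutoff``; edges are kept at occupancy ≥
    ``occupancy_min``.  Sequence-adjacent residues within a chain are
    excluded by default.  Edge weight is ``-log|C_ij|``, clamped at
    ``w_max``.  Node labels come from ``numbering`` (residue key → generic
    number) when given, otherwise ``chain:seq``.
    """
    order, heavy, ca_index = _residue_layout(traj.topology)
    if len(order) < 2:
        raise DomainError("need at least two receptor residues")
    missing_ca = [k for k in order if k not in ca_index]
    if missing_ca:
        raise SelectionError(
            f"residues without a Cα atom: {[node_label(k) for k in missing_ca[:5]]}"
        )
    labels = {
        key: (numbering.get(key, node_label(key)) if numbering else node_label(key))
        for key in order
    }
    corr = cross_correlation(traj, [ca_index[k] for k in order])
    # order index per chain for adjacency exclusion
    seq_pos: dict[tuple[str, str], tuple[str, int]] = {}
    for key in order:
        try:
            seq_pos[key] = (key[0], int(key[1]))
        except ValueError:
            seq_pos[key] = (key[0], -(10**9))
    edges: list[ContactEdge] = []
    for (ia, key_a), (ib, key_b) in itertools.combinations(enumerate(order), 2):
        if exclude_adjacent:
            ca_chain, ca_seq = seq_pos[key_a]
            cb_chain, cb_seq = seq_pos[key_b]
            if ca_chain == cb_chain and abs(ca_seq - cb_seq) <= 1:
                continue
        xa = traj.frames[:, heavy[key_a], :]
        xb = traj.frames[:, heavy[key_b], :]
        d = np.linalg.norm(xa[:, :, None, :] - xb[:, None, :, :], axis=-1)
        occ = float((d.min(axis=(1, 2)) < cutoff).mean())
        if occ < occupancy_min:
            continue
        c = float(corr[ia, ib])
        w = w_max if abs(c) < math.exp(-w_max) else min(-math.log(abs(c)), w_max)
        edges.append(ContactEdge(labels[key_a], labels[key_b], occ, c, w))
    return ContactNetwork(tuple(labels[k] for k in order), tuple(edges))


# ---------------------------------------------------------------------------
# Communities


def _most_valuable_edge(g: nx.Graph) -> tuple:
    """Highest edge betweenness; deterministic lexicographic tie-break."""
    centrality = nx.edge_betweenness_centrality(g)
    top = max(centrality.values())
    candidates = [e for e, v in centrality.items() if v == top]
    return min(candidates, key=lambda e: tuple(sorted((str(e[0]), str(e[1])))))


def communities(net: ContactNetwork | nx.Graph) -> CommunityPartition:
    """Girvan–Newman communities at the maximum-modularity dendrogram level.

    Edge betweenness is computed unweighted (interaction topology); the
    partition of maximal modularity over the removal hierarchy — including
    the trivial starting partition into connected components — is returned.
    """
    g = net.graph() if isinstance(net, ContactNetwork) else net
    if g.number_of_edges() == 0:
        raise DomainError("community detection needs at least one edge")
    base = [set(c) for c in nx.connected_components(g)]
    best_partition = base
    best_q = nx.community.modularity(g, base)
    for partition in nx.community.girvan_newman(
        g, most_valuable_edge=_most_valuable_edge
    ):
        q = nx.community.modularity(g, partition)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = [set(c) for c in partition]
    membership = {}
    for label, group in enumerate(
        sorted(best_partition, key=lambda c: min(str(n) for n in c))
    ):
        for node in group:
            membership[node] = label
    return CommunityPartition(membership, float(best_q))


# ---------------------------------------------------------------------------
# Shortest paths


def shortest_paths(
    net: ContactNetwork | nx.Graph,
    sources: Iterable[str],
    sinks: Iterable[str],
) -> list[PathResult]:
    """Minimal-weight communication path for every (source, sink) pair.

    All-pairs distances come from Floyd–Warshall over the edge weights;
    unreachable pairs are reported with an empty path and infinite weight.
    """
    g = net.graph() if isinstance(net, ContactNetwork) else net
    sources, sinks = list(sources), list(sinks)
    for node in itertools.chain(sources, sinks):
        if node not in g:
            raise SelectionError(f"node {node!r} not in network")
    pred, dist = nx.floyd_warshall_predecessor_and_distance(g, weight="weight")
    results = []
    for s in sources:
        for t in sinks:
            if s == t:
                results.append(PathResult(s, t, (s,), 0.0))
                continue
            if t not in dist[s] or math.isinf(dist[s][t]):
                results.append(PathResult(s, t, (), math.inf))
                continue
            path = nx.reconstruct_path(s, t, pred)
            results.append(PathResult(s, t, tuple(path), float(dist[s][t])))
    return results


# ---------------------------------------------------------------------------
# Hydrogen bonds


def _atom_index(model: StructureModel) -> dict[tuple[str, str, str], int]:
    return {
        (a.chain, f"{a.residue_seq}{a.icode}".strip(), a.atom_name): i
        for i, a in enumerate(model.atoms)
    }


def hbond_occupancy(
    traj: TrajectoryEnsemble,
    pairs: Sequence[tuple[tuple[str, str, str], tuple[str, str, str]]],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> list[HBondOccupancy]:
    """Hydrogen-bond occupancy for given (donor, acceptor) atom pairs.

    Atoms are addressed as ``(chain, seq, atom_name)``.  Hydrogens bonded to
    the donor are inferred from frame 1 (D–H distance ≤ 1.2 Å); a frame
    counts when the donor–acceptor distance is below ``distance_cutoff`` Å
    and any D–H–A angle is ≥ ``angle_cutoff`` degrees.
    """
    index = _atom_index(traj.topology)
    results = []
    for donor_key, acceptor_key in pairs:
        try:
            d_idx = index[donor_key]
            a_idx = index[acceptor_key]
        except KeyError as exc:
            raise SelectionError(f"atom {exc.args[0]} not in topology") from exc
        donor_atom = traj.topology.atoms[d_idx]
        # hydrogens covalently attached to the donor, from frame 1 geometry
        h_indices = [
            i for i, a in enumerate(traj.topology.atoms)
            if a.is_hydrogen and a.residue_key == donor_atom.residue_key
            and np.linalg.norm(traj.frames[0, i] - traj.frames[0, d_idx]) <= 1.2
        ]
        if not h_indices:
            raise SelectionError(
                f"donor {donor_key} has no attached hydrogen in residue "
                f"{donor_atom.residue_key} (explicit hydrogens required)"
            )
        d_xyz = traj.frames[:, d_idx, :]
        a_xyz = traj.frames[:, a_idx, :]
        da = np.linalg.norm(d_xyz - a_xyz, axis=1)
        angle_ok = np.zeros(traj.n_frames, dtype=bool)
        for h_idx in h_indices:
            h_xyz = traj.frames[:, h_idx, :]
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            angle_ok |= ang >= angle_cutoff
        detected = (da < distance_cutoff) & angle_ok
        results.append(
            HBondOccupancy(
                ":".join(donor_key), ":".join(acceptor_key),
                float(detected.mean()),
            )
        )
    return results


# ---------------------------------------------------------------------------
# χ1 dihedrals

#: γ-position atom per residue type (IUPAC first-listed branch for branched
#: side chains).
CHI1_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
}


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, range (−180, 180], IUPAC sign convention.

    Projects the outer bonds onto the plane normal to the central bond and
    measures the signed angle between the projections (the convention shared
    by the standard MD analysis libraries).
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def chi1_distribution(
    traj: TrajectoryEnsemble,
    residues: Iterable[tuple[str, str]],
) -> list[DihedralSeries]:
    """χ1 (N–Cα–Cβ–γ) time series for the named residues."""
    index = _atom_index(traj.topology)
    by_key: dict[tuple[str, str], str] = {}
    for a in traj.topology.atoms:
        by_key.setdefault(a.residue_key, a.residue_name)
    series = []
    for key in residues:
        if key not in by_key:
            raise SelectionError(f"residue {key} not in topology")
        resname = by_key[key]
        gamma = CHI1_GAMMA_ATOM.get(resname, "CG")
        needed = ["N", "CA", "CB", gamma]
        idx = []
        for name in needed:
            full = (key[0], key[1], name)
            if full not in index:
                raise SelectionError(
                    f"residue {key} ({resname}) lacks atom {name} needed for χ1"
                )
            idx.append(index[full])
        values = np.array(
            [
                dihedral_angle(*(traj.frames[m, i] for i in idx))
                for m in range(traj.n_frames)
            ]
        )
        series.append(DihedralSeries(node_label(key), values))
    return series


# ---------------------------------------------------------------------------
# Welch's t-test


def welch_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test; returns (t, Welch–Satterthwaite df, p).

    When both samples have zero variance and equal means, returns
    ``(0, n_a + n_b - 2, 1.0)`` by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("Welch's t-test needs at least 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateStatisticsError(
            "both samples have zero variance with unequal means; t undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Serialisation

NETWORK_SCHEMA_VERSION = 1


def network_to_json(
    net: ContactNetwork,
    partition: CommunityPartition | None = None,
    paths: Sequence[PathResult] = (),
) -> str:
    """Versioned JSON document with nodes, edges, communities and paths."""
    doc = {
        "schema_version": NETWORK_SCHEMA_VERSION,
        "nodes": list(net.nodes),
        "edges": [
            {"i": e.i, "j": e.j, "occupancy": e.occupancy,
             "correlation": e.correlation, "weight": e.weight}
            for e in net.edges
        ],
    }
    if partition is not None:
        doc["communities"] = {
            "membership": dict(partition.membership),
            "modularity": partition.modularity,
        }
    if paths:
        doc["paths"] = [
            {"source": p.source, "sink": p.sink, "path": list(p.path),
             "total_weight": p.total_weight if math.isfinite(p.total_weight)
             else "inf"}
            for p in paths
        ]
    return json.dumps(doc, indent=2)
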