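"""Receptor–ligand structure parsing and hotspot annotation.

Hotspot calls from the sequence comparison are interpreted in the context of
a receptor structure with its native agonist bound:

* the *orthosteric site* is defined geometrically as every receptor residue
  with a heavy atom within a cutoff (default 4.0 Å) of any ligand heavy atom;
* calls are classified into the three hotspot regions (orthosteric site,
  TM2-TM7 interface, TM3-TM4-TM5 interface) via an overridable lookup table;
* candidate positions can be deprioritized when they are strongly
  solvent-exposed (Shrake–Rupley sampled surface) or close to a marked
  intracellular reference set, mirroring the manual triage of positions
  unlikely to affect ligand binding or likely to perturb G-protein coupling;
* structures are compared by least-squares Cα superposition (Kabsch, proper
  rotation enforced) with the RMSD reported after fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import DomainError, InputError, SelectionError
from .hotspot_core import BINDING_SITE_POSITIONS, HotspotCall

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_seq: int
    icode: str
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def residue_key(self) -> tuple[str, str]:
        """(chain, seq+insertion-code) — uniquely names a residue."""
        return (self.chain, f"{self.residue_seq}{self.icode}".strip())

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass(frozen=True)
class StructureModel:
    """Atoms of one model, partitioned into receptor and ligand sets."""

    atoms: tuple[Atom, ...]
    ligand_selector: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "ligand_selector", frozenset(self.ligand_selector))
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise InputError(f"non-finite coordinates for atom {a}")

    @property
    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.residue_name in self.ligand_selector]

    @property
    def receptor_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.residue_name not in self.ligand_selector]

    def receptor_residues(self) -> dict[tuple[str, str], list[Atom]]:
        """Receptor atoms grouped by residue, in structure order."""
        groups: dict[tuple[str, str], list[Atom]] = {}
        for a in self.receptor_atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups

    def ca_atoms(self) -> dict[tuple[str, str], Atom]:
        return {
            a.residue_key: a
            for a in self.receptor_atoms
            if a.atom_name == "CA" and not a.is_hydrogen
        }


@dataclass(frozen=True)
class BindingSiteDefinition:
    """Distance criterion defining the orthosteric site (heavy atoms only)."""

    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise DomainError("binding-site cutoff must be positive")


#: Default region lookup: binding-site positions plus the two interhelical
#: interface regions implicated in selectivity.
DEFAULT_REGION_TABLE: dict[str, str] = {
    **{gn: "orthosteric" for gn in BINDING_SITE_POSITIONS},
    **{gn: "TM2-TM7" for gn in ("2x60", "2x64", "7x35", "7x39", "1x46", "7x43")},
    **{gn: "TM3-TM4-TM5" for gn in ("3x41", "3x42", "4x53", "5x46")},
}


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_atoms_matched: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Parsing


def parse_structure(
    path: str | Path,
    ligand_selector: str | Iterable[str],
    format: str | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The first model is used; for alternate locations only the
    highest-occupancy conformer of each atom is kept; hydrogens are retained
    when present.  ``ligand_selector`` names the ligand residue(s); matching
    nothing is an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    if isinstance(ligand_selector, str):
        selector = frozenset([ligand_selector])
    else:
        selector = frozenset(ligand_selector)
    fmt = (format or path.suffix.lstrip(".")).lower()
    try:
        if fmt in ("cif", "mmcif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise InputError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                    )
                )
    model_obj = StructureModel(tuple(atoms), selector)
    if not model_obj.ligand_atoms:
        raise SelectionError(
            f"ligand selector {sorted(selector)} matched no residue in {path}"
        )
    return model_obj


# ---------------------------------------------------------------------------
# Binding site


def binding_site_residues(
    model: StructureModel,
    defn: BindingSiteDefinition | None = None,
    numbering: Mapping[tuple[str, str] | int, str] | None = None,
) -> set[str]:
    """Generic numbers of receptor residues within the cutoff of the ligand.

    A residue is included iff any of its heavy atoms lies within
    ``defn.cutoff`` of any ligand heavy atom.  ``numbering`` maps residue
    keys ``(chain, seq)`` — or bare sequence numbers for single-chain
    structures — to generic numbers; residues in contact but missing from the
    map are reported by ``chain:seq`` with a warning.
    """
    defn = defn or BindingSiteDefinition()
    ligand_xyz = np.array(
        [a.xyz for a in model.ligand_atoms if not a.is_hydrogen], dtype=float
    )
    if ligand_xyz.size == 0:
        raise SelectionError("ligand partition has no heavy atoms")
    residues = model.receptor_residues()
    if not residues:
        raise SelectionError("receptor partition is empty")
    hits: set[str] = set()
    for key, atoms in residues.items():
        xyz = np.array([a.xyz for a in atoms if not a.is_hydrogen], dtype=float)
        if xyz.size == 0:
            continue
        d = np.linalg.norm(xyz[:, None, :] - ligand_xyz[None, :, :], axis=-1)
        if d.min() < defn.cutoff:
            label = _lookup_generic(numbering, key)
            if label is None:
                label = f"{key[0]}:{key[1]}"
                warnings.warn(
                    f"binding-site residue {label} has no generic number",
                    stacklevel=2,
                )
            hits.add(label)
    return hits


def _lookup_generic(
    numbering: Mapping | None, key: tuple[str, str]
) -> str | None:
    if numbering is None:
        return None
    if key in numbering:
        return numbering[key]
    # tolerate bare residue_seq keys (single-chain convenience)
    try:
        seq = int(key[1])
    except ValueError:
        return None
    return numbering.get(seq)


# ---------------------------------------------------------------------------
# Region classification


def classify_regions(
    calls: Sequence[HotspotCall],
    table: Mapping[str, str] | None = None,
) -> list[HotspotCall]:
    """Set each call's ``region`` from the lookup table (in place; returned).

    Positions absent from the table are labelled ``"unassigned"``.
    """
    table = DEFAULT_REGION_TABLE if table is None else table
    for call in calls:
        call.region = table.get(call.generic_number, "unassigned")
    return list(calls)


# ---------------------------------------------------------------------------
# Superposition


def kabsch(moving: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Classic SVD solution with the determinant sign corrected so the result
    is always a proper rotation (no reflection).
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise DomainError("kabsch expects matching (n, 3) coordinate arrays")
    n = moving.shape[0]
    if n < 3:
        raise DomainError(f"need at least 3 atom pairs, got {n}")
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(((moved - target) ** 2).sum() / n))
    return SuperpositionResult(rot, trans, rmsd, n)


def superpose_ca(
    model_a: StructureModel,
    model_b: StructureModel,
    numbering_a: Mapping[tuple[str, str], str] | None = None,
    numbering_b: Mapping[tuple[str, str], str] | None = None,
) -> SuperpositionResult:
    """Cα superposition of two receptors.

    Pairing is by shared generic number when both numbering maps are given,
    otherwise by residue key ``(chain, seq)``.  Residues lacking a Cα in
    either model are dropped (their count is the difference between the map
    size and ``n_atoms_matched``).
    """
    ca_a, ca_b = model_a.ca_atoms(), model_b.ca_atoms()
    if numbering_a is not None and numbering_b is not None:
        by_gn_a = {gn: key for key, gn in numbering_a.items() if key in ca_a}
        by_gn_b = {gn: key for key, gn in numbering_b.items() if key in ca_b}
        shared = sorted(set(by_gn_a) & set(by_gn_b))
        pairs = [(ca_a[by_gn_a[g]], ca_b[by_gn_b[g]]) for g in shared]
    else:
        shared_keys = sorted(set(ca_a) & set(ca_b))
        pairs = [(ca_a[k], ca_b[k]) for k in shared_keys]
    if len(pairs) < 3:
        raise DomainError(f"only {len(pairs)} paired Cα atoms; need at least 3")
    moving = np.array([p[0].xyz for p in pairs])
    target = np.array([p[1].xyz for p in pairs])
    return kabsch(moving, target)


# ---------------------------------------------------------------------------
# Solvent exposure (Shrake–Rupley sampled surface)

_VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def sampled_sasa(
    atoms: Sequence[Atom],
    probe_radius: float = 1.4,
    n_points: int = 480,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å² (heavy atoms only).

    Shrake–Rupley: each atom's expanded sphere (van der Waals + probe) is
    sampled at ``n_points`` quasi-uniform points; the accessible fraction is
    the share of points not inside any neighbour's expanded sphere.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    xyz = np.array([a.xyz for a in heavy], dtype=float)
    radii = np.array(
        [_VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS) + probe_radius
         for a in heavy]
    )
    unit = _sphere_points(n_points)
    areas = np.zeros(len(heavy))
    for i in range(len(heavy)):
        pts = xyz[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(heavy)):
            if j == i:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) > radii[i] + radii[j]:
                continue
            d = np.linalg.norm(pts - xyz[j], axis=1)
            accessible &= d > radii[j]
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    out = np.zeros(len(atoms))
    k = 0
    for idx, a in enumerate(atoms):
        if not a.is_hydrogen:
            out[idx] = areas[k]
            k += 1
    return out


def relative_sidechain_exposure(
    model: StructureModel, residue_key: tuple[str, str]
) -> float:
    """Side-chain SASA in context divided by side-chain SASA in isolation.

    A self-normalising proxy for relative solvent exposure that needs no
    per-residue reference table: 0 for a fully buried side chain, near 1 for
    a side chain as exposed as it would be free in solution.  Residues with
    no side-chain heavy atoms (e.g. glycine) return 0.
    """
    residues = model.receptor_residues()
    if residue_key not in residues:
        raise SelectionError(f"residue {residue_key} not in receptor")
    all_atoms = model.receptor_atoms
    context = sampled_sasa(all_atoms)
    is_target_side = [
        a.residue_key == residue_key and a.atom_name not in _BACKBONE_ATOMS
        and not a.is_hydrogen
        for a in all_atoms
    ]
    if not any(is_target_side):
        return 0.0
    in_context = float(np.array(context)[np.array(is_target_side)].sum())
    alone_atoms = residues[residue_key]
    alone = sampled_sasa(alone_atoms)
    side_alone = float(
        sum(
            s for a, s in zip(alone_atoms, alone)
            if a.atom_name not in _BACKBONE_ATOMS and not a.is_hydrogen
        )
    )
    if side_alone == 0.0:
        return 0.0
    return in_context / side_alone


# ---------------------------------------------------------------------------
# Prioritization


def prioritize(
    calls: Sequence[HotspotCall],
    model: StructureModel | None = None,
    *,
    deprioritize: Iterable[str] = (),
    numbering: Mapping[str, tuple[str, str]] | None = None,
    use_exposure: bool = False,
    exposure_threshold: float = 0.4,
    intracellular_reference: Iterable[str] = (),
    intracellular_distance: float = 8.0,
) -> list[HotspotCall]:
    """Set each call's ``priority`` field (in place; list returned).

    A call is *deprioritized* when (a) its generic number appears in the
    explicit ``deprioritize`` list, (b) ``use_exposure`` is on and the
    residue's relative side-chain exposure exceeds ``exposure_threshold``
    (surface-exposed, unlikely to shape the pocket), or (c) its Cα lies
    within ``intracellular_distance`` of any residue in
    ``intracellular_reference`` (generic numbers; proxy for proximity to the
    G-protein coupling interface).  Heuristics (b)/(c) need ``model`` and
    ``numbering`` (generic number → residue key).
    """
    explicit = set(deprioritize)
    intracellular = set(intracellular_reference)
    needs_structure = use_exposure or bool(intracellular)
    if needs_structure and (model is None or numbering is None):
        raise DomainError(
            "structural prioritization heuristics need a structure and a "
            "generic-number → residue mapping"
        )
    ca = model.ca_atoms() if model is not None else {}
    ref_xyz = None
    if intracellular:
        pts = []
        for gn in intracellular:
            key = numbering.get(gn)  # type: ignore[union-attr]
            if key is not None and key in ca:
                pts.append(ca[key].xyz)
        if not pts:
            raise SelectionError(
                "no intracellular reference residue resolved to a Cα atom"
            )
        ref_xyz = np.array(pts, dtype=float)
    for call in calls:
        reasons = []
        if call.generic_number in explicit:
            reasons.append("listed")
        key = numbering.get(call.generic_number) if numbering else None
        if use_exposure and key is not None:
            exposure = relative_sidechain_exposure(model, key)  # type: ignore[arg-type]
            if exposure > exposure_threshold:
                reasons.append("surface-exposed")
        if ref_xyz is not None and key is not None and key in ca:
            d = np.linalg.norm(ref_xyz - np.array(ca[key].xyz), axis=1).min()
            if d <= intracellular_distance:
                reasons.append("near-intracellular-site")
        call.priority = "deprioritized" if reasons else "prioritized"
        if reasons:
            call.flag = ";".join(reasons)
    return list(calls)
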