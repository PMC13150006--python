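"""Deterministic synthetic inputs with the structure each analysis assumes.

Three generators emulate the three kinds of input data:

* **Paired alignments** with planted selectivity hotspots: positions where
  each group is conserved on a different residue whose BLOSUM62 score is
  negative, among background positions that are identical between groups.
  Conservation is enforced exactly by count (``floor(c · n)`` consensus
  copies), so threshold behaviour is sharp, and the generator refuses
  planted pairs that do not actually score negative.
* **Trajectories** of point residues fluctuating about fixed positions,
  with planted contact pairs realised in an exact fraction of frames and
  correlated blocks sharing a common displacement mode scaled to a target
  cross-correlation.
* **Concentration–response tables** sampled from the 3-parameter logistic
  with seeded Gaussian noise; generator truths default to the wild-type
  β2-adrenergic/D1-dopaminergic potency values so the fold-selectivity
  pipeline can be exercised end to end.

Every generator is a pure function of its spec (including the seed): the
same spec yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SimulationSpecError
from .hotspot_core import BLOSUM62, SubstitutionMatrix
from .msa_numbering import (
    AMINO_ACIDS,
    Alignment,
    GenericNumberMap,
    SequenceRecord,
)
from .pharm_selectivity import logistic_response
from .structure_annotation import Atom, StructureModel
from .trajectory_network import TrajectoryEnsemble

# ---------------------------------------------------------------------------
# Alignments

#: The five prioritized hotspot residue pairs of the β-adrenergic vs D1-like
#: comparison (group A consensus, group B consensus); all score < 0 under
#: BLOSUM62.
DEFAULT_PLANTED_HOTSPOTS: tuple[tuple[str, str, str], ...] = (
    ("2x60", "G", "K"),
    ("3x36", "V", "S"),
    ("3x41", "E", "L"),
    ("45x52", "F", "S"),
    ("7x38", "N", "V"),
)


@dataclass(frozen=True)
class AlignmentSimSpec:
    """Recipe for a pair of subfamily alignments with planted hotspots.

    ``n_sequences_a``/``n_sequences_b`` default to the 515 β-adrenergic and
    401 D1-like dopaminergic sequence-set sizes of the motivating study.
    ``conservation`` applies to planted positions; ``background_conservation``
    to the remaining identical-consensus positions.
    """

    n_sequences_a: int = 515
    n_sequences_b: int = 401
    n_background: int = 50
    planted_hotspots: tuple[tuple[str, str, str], ...] = DEFAULT_PLANTED_HOTSPOTS
    conservation: float = 1.0
    background_conservation: float = 1.0
    seed: int = 0
    matrix: SubstitutionMatrix = field(default=BLOSUM62, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation <= 1.0:
            raise SimulationSpecError("conservation must be in (0, 1]")
        if not 0.0 < self.background_conservation <= 1.0:
            raise SimulationSpecError("background_conservation must be in (0, 1]")
        if min(self.n_sequences_a, self.n_sequences_b) < 1:
            raise SimulationSpecError("need at least one sequence per group")
        for gn, res_a, res_b in self.planted_hotspots:
            score = self.matrix.score(res_a, res_b)
            if score >= 0:
                raise SimulationSpecError(
                    f"planted pair {res_a}/{res_b} at {gn} scores {score} >= 0 "
                    "under the substitution matrix; it could never be a hotspot"
                )


def _background_generic_numbers(n: int, taken: set[str]) -> list[str]:
    """Deterministic injective generic numbers 1x30, 1x31, ... skipping taken."""
    out: list[str] = []
    seg, pos = 1, 30
    while len(out) < n:
        gn = f"{seg}x{pos}"
        if gn not in taken:
            out.append(gn)
        pos += 1
        if pos > 69:
            seg, pos = seg + 1, 30
    return out


def _conserved_column(
    rng: np.random.Generator, consensus: str, n: int, conservation: float
) -> list[str]:
    """A column with exactly floor(conservation*n) consensus copies.

    Minority residues are spread round-robin over a shuffled set of
    non-consensus residues so no minority residue can rival the consensus.
    """
    n_cons = int(np.floor(conservation * n))
    n_cons = max(n_cons, 1)
    minority_n = n - n_cons
    others = [aa for aa in AMINO_ACIDS if aa != consensus]
    rng.shuffle(others)
    minority = [others[k % len(others)] for k in range(minority_n)]
    if minority:
        worst = max(minority.count(aa) for aa in set(minority))
        if worst >= n_cons:
            raise SimulationSpecError(
                f"conservation {conservation} with n={n} makes the consensus "
                "ambiguous"
            )
    column = [consensus] * n_cons + minority
    rng.shuffle(column)
    return column


def simulate_alignments(
    spec: AlignmentSimSpec,
) -> tuple[Alignment, Alignment, GenericNumberMap, GenericNumberMap, pd.DataFrame]:
    """Generate two alignments, their numbering maps, and the truth table.

    The truth table has columns ``generic_number, residue_a, residue_b,
    is_planted``; downstream hotspot calls can be scored against
    ``is_planted`` directly.
    """
    rng = np.random.default_rng(spec.seed)
    planted = sorted(spec.planted_hotspots)
    taken = {gn for gn, _, _ in planted}
    background_gn = _background_generic_numbers(spec.n_background, taken)
    # interleave positions deterministically: planted scattered among background
    all_positions: list[tuple[str, str, str, bool]] = [
        (gn, res_a, res_b, True) for gn, res_a, res_b in planted
    ]
    for gn in background_gn:
        res = rng.choice(list(AMINO_ACIDS))
        all_positions.append((gn, res, res, False))
    order = rng.permutation(len(all_positions))
    columns_a: list[list[str]] = []
    columns_b: list[list[str]] = []
    records_truth = []
    gmap_entries: dict[int, str] = {}
    for col, idx in enumerate(order):
        gn, res_a, res_b, is_planted = all_positions[idx]
        cons = spec.conservation if is_planted else spec.background_conservation
        columns_a.append(_conserved_column(rng, res_a, spec.n_sequences_a, cons))
        columns_b.append(_conserved_column(rng, res_b, spec.n_sequences_b, cons))
        gmap_entries[col] = gn
        records_truth.append(
            {"generic_number": gn, "residue_a": res_a, "residue_b": res_b,
             "is_planted": is_planted}
        )
    aln_a = Alignment(
        tuple(
            SequenceRecord(f"groupA_{i:04d}", "".join(col[i] for col in columns_a))
            for i in range(spec.n_sequences_a)
        )
    )
    aln_b = Alignment(
        tuple(
            SequenceRecord(f"groupB_{i:04d}", "".join(col[i] for col in columns_b))
            for i in range(spec.n_sequences_b)
        )
    )
    gmap_a = GenericNumberMap(gmap_entries, reference_id="groupA_0000")
    gmap_b = GenericNumberMap(gmap_entries, reference_id="groupB_0000")
    truth = pd.DataFrame(records_truth)
    return aln_a, aln_b, gmap_a, gmap_b, truth


# ---------------------------------------------------------------------------
# Trajectories


@dataclass(frozen=True)
class TrajectorySimSpec:
    """Recipe for a point-residue trajectory with planted structure.

    Residues are single Cα pseudo-atoms on a 20 Å grid.  ``contact_pairs``
    lists ``(i, j, occupancy)`` (0-based residue indices, non-adjacent);
    ``correlated_blocks`` lists ``(residue-index tuple, target_correlation)``.
    ``noise_amplitude`` is the isotropic positional noise in Å.
    """

    n_residues: int = 12
    n_frames: int = 1000
    contact_pairs: tuple[tuple[int, int, float], ...] = ()
    correlated_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    noise_amplitude: float = 0.1
    contact_distance: float = 3.5
    apart_distance: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 2 or self.n_frames < 1:
            raise SimulationSpecError("need >= 2 residues and >= 1 frame")
        if self.noise_amplitude < 0:
            raise SimulationSpecError("noise_amplitude must be >= 0")
        for i, j, occ in self.contact_pairs:
            if not (0 <= i < self.n_residues and 0 <= j < self.n_residues):
                raise SimulationSpecError(f"contact pair ({i},{j}) out of range")
            if abs(i - j) <= 1:
                raise SimulationSpecError(
                    f"contact pair ({i},{j}) is sequence-adjacent; the network "
                    "excludes such edges"
                )
            if not 0.0 <= occ <= 1.0:
                raise SimulationSpecError("target occupancy must be in [0, 1]")
        for block, corr in self.correlated_blocks:
            if len(block) < 2:
                raise SimulationSpecError("correlated block needs >= 2 residues")
            if not -1.0 <= corr <= 1.0:
                raise SimulationSpecError("target correlation must be in [-1, 1]")


def _project_out_rigid(u: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Remove the rigid-body (translation + infinitesimal rotation) component
    of a per-residue displacement field over the given base geometry."""
    n = base.shape[0]
    centred = base - base.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    for k in range(3):
        w = np.zeros(3)
        w[k] = 1.0
        basis.append(np.cross(np.broadcast_to(w, centred.shape), centred).ravel())
    q, _ = np.linalg.qr(np.stack(basis, axis=1))
    flat = u.ravel()
    return (flat - q @ (q.T @ flat)).reshape(n, 3)


def simulate_trajectory(
    spec: TrajectorySimSpec,
) -> tuple[TrajectoryEnsemble, pd.DataFrame]:
    """Generate the ensemble and a truth table of planted features.

    Contact pairs are realised in exactly ``round(occupancy * n_frames)``
    randomly chosen frames (residue ``j`` is moved next to residue ``i``;
    otherwise it sits far away).  Correlated blocks share a common
    z-displacement mode with amplitude chosen so the expected equal-time
    cross-correlation matches the target given the isotropic noise.
    """
    rng = np.random.default_rng(spec.seed)
    # 3-D grid layout (20 Å spacing): a degenerate (e.g. collinear) point set
    # would let the per-frame rigid-body fit absorb planted displacement
    # modes into a global rotation, biasing the cross-correlation
    k = np.arange(spec.n_residues)
    base = 20.0 * np.column_stack((k % 3, (k // 3) % 3, k // 9)).astype(float)
    if len({tuple(b) for b in np.round(base, 6)}) != spec.n_residues:
        raise SimulationSpecError("overlapping residue base positions")
    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    truth_rows = []
    # planted contacts: move residue j near i in an exact fraction of frames
    for i, j, occ in spec.contact_pairs:
        n_contact = int(round(occ * spec.n_frames))
        contact_frames = rng.choice(spec.n_frames, size=n_contact, replace=False)
        near = base[i] + np.array([spec.contact_distance, 0.0, 0.0])
        far = base[i] + np.array([spec.apart_distance, 0.0, 0.0])
        frames[:, j, :] = far
        frames[contact_frames, j, :] = near
        truth_rows.append(
            {"feature": "contact", "i": i, "j": j,
             "target": occ, "realized": n_contact / spec.n_frames}
        )
    # correlated blocks: shared displacement mode on top of the noise.  The
    # network's correlation is computed after rigid-body superposition, which
    # removes the best-fit translation/rotation of any displacement field, so
    # the planted mode is projected onto the complement of the rigid subspace
    # and its amplitude solved to hit the target correlation exactly.
    sigma_n = max(spec.noise_amplitude, 1e-9)
    nu = 3.0 * sigma_n**2
    for block, target in spec.correlated_blocks:
        u = np.zeros((spec.n_residues, 3))
        sign = 1.0 if target >= 0 else -1.0
        for rank, res in enumerate(block):
            u[res, 2] = 1.0 if rank == 0 else sign
        u = _project_out_rigid(u, base)
        i, j = block[0], block[-1]
        g = abs(float(u[i] @ u[j]))
        hi, hj = float(u[i] @ u[i]), float(u[j] @ u[j])
        c = min(abs(target), 0.999 * g / np.sqrt(hi * hj))
        # solve  g s / sqrt((hi s + nu)(hj s + nu)) = c  for s = sigma_m^2
        a2 = g * g - c * c * hi * hj
        bq = c * c * nu * (hi + hj)
        s = (bq + np.sqrt(bq * bq + 4.0 * a2 * c * c * nu * nu)) / (2.0 * a2)
        mode = rng.normal(0.0, np.sqrt(s), size=spec.n_frames)
        frames += mode[:, None, None] * u[None, :, :]
        truth_rows.append(
            {"feature": "correlation", "i": i, "j": j,
             "target": target, "realized": np.nan}
        )
    if spec.noise_amplitude > 0:
        frames += rng.normal(0.0, spec.noise_amplitude, size=frames.shape)
    else:
        # avoid exactly zero variance, which makes correlation undefined
        frames += rng.normal(0.0, 1e-9, size=frames.shape)
    atoms = tuple(
        Atom("A", k + 1, "", "ALA", "CA", "C", tuple(base[k]))
        for k in range(spec.n_residues)
    )
    topology = StructureModel(atoms, frozenset())
    return TrajectoryEnsemble(topology, frames), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Concentration-response curves

#: Wild-type cAMP potencies used as default generator truths
#: (receptor, ligand, pEC50).
DEFAULT_CURVE_TRUTHS: tuple[tuple[str, str, float], ...] = (
    ("B2R-WT", "ADR", 8.69),
    ("B2R-WT", "NA", 7.09),
    ("B2R-WT", "DA", 5.29),
    ("D1R-WT", "DA", 8.48),
    ("D1R-WT", "ADR", 7.00),
    ("D1R-WT", "NA", 7.22),
)


@dataclass(frozen=True)
class CurveSimSpec:
    """Recipe for noisy logistic concentration-response tables.

    ``truths`` rows are ``(receptor, ligand, pec50)``; ``noise_sd`` is the
    Gaussian response noise as a percentage of ``emax``.  The default
    concentration grid spans 10 half-log steps from 0.1 nM to 100 µM.
    """

    truths: tuple[tuple[str, str, float], ...] = DEFAULT_CURVE_TRUTHS
    basal: float = 0.0
    emax: float = 100.0
    concentrations: tuple[float, ...] = tuple(
        float(c) for c in np.logspace(-10, -4, 13)
    )
    noise_sd: float = 5.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations)
        if conc.size < 4:
            raise SimulationSpecError("need at least 4 concentrations")
        span = np.log10(conc.max() / conc.min())
        if span < 3.0:
            raise SimulationSpecError(
                f"concentration grid spans {span:.1f} log units; need >= 3"
            )
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise SimulationSpecError("need at least one replicate")


def simulate_curves(spec: CurveSimSpec) -> pd.DataFrame:
    """Tidy curve table: receptor, ligand, replicate, concentration_M, response."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    sd = spec.noise_sd / 100.0 * spec.emax
    for receptor, ligand, pec50 in spec.truths:
        clean = logistic_response(
            np.asarray(spec.concentrations), spec.basal, spec.emax, pec50
        )
        for rep in range(1, spec.replicates + 1):
            noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
            for c, r in zip(spec.concentrations, noisy):
                rows.append(
                    {"receptor": receptor, "ligand": ligand, "replicate": rep,
                     "concentration_M": c, "response": float(r)}
                )
    return pd.DataFrame(rows)
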