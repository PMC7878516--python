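"""Coarse-grained cage model building by restrained rigid-body annealing.

Each CC-forming peptide segment is an ideal α-helical CA trace treated
as a rigid body.  A cage model is assembled by a staged, seeded
Metropolis Monte-Carlo protocol: coiled-coil pairing restraints are
switched on one dimer at a time, and at every stage the rigid bodies
are annealed under the currently active energy

    E = pairing restraints  (registry-matched CA pairs at a target
        distance; registry index-reversed for antiparallel dimers)
      + linker springs      (flat-bottom, capping the junction gap at
        the contour length of the loop)
      + soft-sphere clashes (quadratic below the clash radius, between
        beads of non-adjacent segments),

followed by a zero-temperature quench.  The protocol is a deterministic
function of its seed, so ensembles are bitwise reproducible.  Repeating
the build with independent sub-seeds yields a conformational ensemble
whose spread reflects the real flexibility left by the loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

import pandas as pd

from .topology import ChainTopology, PARALLEL
from .peptides import SegmentAssignment, CCPair, packaged_library

__all__ = [
    "BuildParams", "RigidSegment", "CGModel", "make_ideal_segment",
    "build_model", "generate_ensemble", "cavity_radius", "write_pdb",
]

HELIX_RISE = 1.5        # Å per residue
HELIX_RADIUS = 2.3      # Å
HELIX_TWIST = 100.0     # degrees per residue


def make_ideal_segment(length: int) -> np.ndarray:
    """Ideal straight α-helix CA trace, centred at the origin, axis = z.

    1.5 Å rise and 100° twist per residue on a 2.3 Å radius give a
    consecutive-CA distance of ~3.8 Å and an axial extent of
    1.5 (length − 1) Å.
    """
    if length < 7:
        raise ValueError("helical segments need at least 7 residues")
    i = np.arange(length)
    phi = np.deg2rad(HELIX_TWIST * i)
    xyz = np.stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * i,
    ], axis=1)
    return xyz - xyz.mean(axis=0)


@dataclass
class RigidSegment:
    """A rigid helical segment: local template + pose."""

    template: np.ndarray                 # (n, 3) CA coords, local frame
    position: np.ndarray                 # (3,)
    rotation: Rotation
    chain: int
    index: int                           # global segment index
    residue_span: tuple[int, int] = (0, 0)

    def coords(self) -> np.ndarray:
        return self.rotation.apply(self.template) + self.position

    @property
    def n_residues(self) -> int:
        return len(self.template)


@dataclass(frozen=True)
class BuildParams:
    """Tunable constants of the model-building protocol (Å, kT units)."""

    pairing_target_distance: float = 10.0   # CA-CA distance inside a CC dimer
    pairing_force_constant: float = 1.0
    linker_residues: int = 5
    linker_bond_length: float = 3.8         # contour length per loop residue
    linker_force_constant: float = 1.0
    clash_radius: float = 4.0
    clash_force_constant: float = 1.0
    t_start: float = 4.0
    t_end: float = 0.25
    n_temps: int = 10
    sweeps_per_temp: int = 10
    quench_sweeps: int = 200
    step_translation: float = 3.0           # Å, at t_start
    step_rotation: float = 0.35             # rad, at t_start
    convergence_rms: float = 1.0            # Å, per-pair restraint RMS
    include_linker_beads: bool = True
    replicas: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.replicas < 1:
            raise ValueError("replicas must be >= 1")
        for name in ("pairing_target_distance", "pairing_force_constant",
                     "linker_bond_length", "clash_radius", "t_start", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CGModel:
    """A built cage: per-chain CA beads plus build diagnostics."""

    chains: list[np.ndarray]
    segments: list[RigidSegment]
    restraint_residuals: np.ndarray      # per-pair RMS deviation (Å)
    clash_count: int
    converged: bool
    pair_names: list[str]
    metadata: dict = field(default_factory=dict)

    def coords(self) -> np.ndarray:
        return np.vstack(self.chains)

    def rg(self) -> float:
        x = self.coords()
        return float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean()))

    def dmax(self) -> float:
        return float(pdist(self.coords()).max())


# ---------------------------------------------------------------------------
# Energy terms
# ---------------------------------------------------------------------------

def _dimer_targets(n: int, orientation: str, d0: float) -> np.ndarray:
    """Per-residue CA-CA target distances of an ideal CC dimer.

    Parallel: helices in phase at axis distance d0, so every
    registry-matched CA pair sits exactly at d0.  Antiparallel: targets
    are measured on an explicit ideal arrangement (partner helix flipped
    about the inter-axis direction), which makes the zero of the
    restraint energy geometrically attainable.
    """
    if orientation == PARALLEL:
        return np.full(n, d0)
    a = make_ideal_segment(n)
    b = a * np.array([1.0, -1.0, -1.0]) + np.array([d0, 0.0, 0.0])
    return np.linalg.norm(a - b[::-1], axis=1)


class _Energy:
    """Incremental energy over rigid segments (only the moved segment's
    interactions are recomputed)."""

    def __init__(self, topology: ChainTopology, segments: list[RigidSegment],
                 params: BuildParams):
        self.p = params
        self.segments = segments
        self.coords = [s.coords() for s in segments]
        self.pairs = topology.pairs()
        self.orient = {p: topology.orientations[p] for p in self.pairs}
        self.targets = {}
        for key in self.pairs:
            i, j = key
            n = min(segments[i].n_residues, segments[j].n_residues)
            self.targets[key] = _dimer_targets(n, self.orient[key],
                                               params.pairing_target_distance)
        self.active: set[tuple[int, int]] = set()
        # chain neighbours (linker springs)
        self.neighbours: list[tuple[int, int]] = []
        for sl in topology.chain_slices():
            for i in range(sl.start, sl.stop - 1):
                self.neighbours.append((i, i + 1))
        self.adjacent = {frozenset(nb) for nb in self.neighbours}
        self.linker_max = params.linker_residues * params.linker_bond_length

    # -- term evaluations ------------------------------------------------
    def pair_deviations(self, key) -> np.ndarray:
        i, j = key
        a, b = self.coords[i], self.coords[j]
        n = len(self.targets[key])
        if self.orient[key] == PARALLEL:
            d = np.linalg.norm(a[:n] - b[:n], axis=1)
        else:
            d = np.linalg.norm(a[:n] - b[len(b) - n:][::-1], axis=1)
        return d - self.targets[key]

    def _e_pair(self, key) -> float:
        if key not in self.active:
            return 0.0
        dev = self.pair_deviations(key)
        return self.p.pairing_force_constant * float(np.sum(dev ** 2))

    def _e_linker(self, nb) -> float:
        i, j = nb
        gap = float(np.linalg.norm(self.coords[i][-1] - self.coords[j][0]))
        excess = gap - self.linker_max
        return self.p.linker_force_constant * excess ** 2 if excess > 0 else 0.0

    def _e_clash_between(self, i, j) -> float:
        if frozenset((i, j)) in self.adjacent:
            return 0.0
        d = cdist(self.coords[i], self.coords[j])
        close = d[d < self.p.clash_radius]
        if close.size == 0:
            return 0.0
        return self.p.clash_force_constant * float(
            np.sum((self.p.clash_radius - close) ** 2))

    # -- per-segment energy (all terms touching segment k) ---------------
    def segment_energy(self, k: int) -> float:
        return self.group_energy((k,))

    def group_energy(self, ks) -> float:
        """Energy of every term touching at least one segment in ``ks``."""
        ks = set(ks)
        e = 0.0
        for key in self.pairs:
            if ks.intersection(key):
                e += self._e_pair(key)
        for nb in self.neighbours:
            if ks.intersection(nb):
                e += self._e_linker(nb)
        n = len(self.coords)
        for k in ks:
            for j in range(n):
                if j not in ks or j > k:
                    if j != k:
                        e += self._e_clash_between(min(j, k), max(j, k))
        return e

    def total_energy(self) -> float:
        e = sum(self._e_pair(key) for key in self.pairs)
        e += sum(self._e_linker(nb) for nb in self.neighbours)
        n = len(self.coords)
        for i in range(n):
            for j in range(i + 1, n):
                e += self._e_clash_between(i, j)
        return e

    def clash_count(self) -> int:
        n = len(self.coords)
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((i, j)) in self.adjacent:
                    continue
                d = cdist(self.coords[i], self.coords[j])
                count += int(np.count_nonzero(d < self.p.clash_radius))
        return count


# ---------------------------------------------------------------------------
# Build protocol
# ---------------------------------------------------------------------------

def _segment_lengths(topology: ChainTopology, assignment: SegmentAssignment,
                     library: Sequence[CCPair]) -> list[int]:
    lib = {p.name: p for p in library}
    out = []
    for i in range(topology.n_segments):
        name, role = assignment.by_segment[i]
        out.append(len(lib[name].sequence(role)))
    return out


def _initial_placement(topology, lengths, params, rng) -> list[RigidSegment]:
    """Chain-following random-walk initialisation (loose, non-clashing)."""
    segments = []
    for c, sl in enumerate(topology.chain_slices()):
        pos = rng.normal(scale=20.0, size=3)
        for i in range(sl.start, sl.stop):
            tpl = make_ideal_segment(lengths[i])
            rot = Rotation.from_rotvec(rng.normal(scale=1.0, size=3))
            step = rng.normal(size=3)
            step *= (HELIX_RISE * lengths[i] + 8.0) / np.linalg.norm(step)
            pos = pos + step
            segments.append(RigidSegment(template=tpl, position=pos.copy(),
                                         rotation=rot, chain=c, index=i))
    return segments


def _dock_partner(energy: _Energy, key, params, rng) -> None:
    """Place the later segment of a freshly activated pair next to its
    partner (ideal dimer geometry plus noise) to speed convergence."""
    ref, mov = key
    segs = energy.segments
    rot_ref = segs[ref].rotation
    axis = rot_ref.apply([0.0, 0.0, 1.0])
    perp = np.cross(axis, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    offset = perp * params.pairing_target_distance
    if energy.orient[key] == PARALLEL:
        rot_new = rot_ref
    else:
        flip = Rotation.from_rotvec(np.pi * perp)
        rot_new = flip * rot_ref
    segs[mov].rotation = rot_new * Rotation.from_rotvec(
        rng.normal(scale=0.1, size=3))
    segs[mov].position = (segs[ref].position + offset
                          + rng.normal(scale=1.0, size=3))
    energy.coords[mov] = segs[mov].coords()


def _anneal(energy: _Energy, movable: set[int], params: BuildParams,
            rng: np.random.Generator, temps: np.ndarray, sweeps: int) -> None:
    segs = energy.segments
    order = sorted(movable)
    partner_of = {}
    for key in energy.pairs:
        if key in energy.active:
            partner_of[key[0]] = key[1]
            partner_of[key[1]] = key[0]
    for t in temps:
        frac = min(t / params.t_start, 1.0)
        st = params.step_translation * max(frac, 0.05)
        sr = params.step_rotation * max(frac, 0.05)
        for _ in range(sweeps):
            for k in rng.permutation(order):
                k = int(k)
                group = [k]
                # sometimes move a formed dimer as one rigid unit, so
                # packing can relax without breaking the pairing
                if k in partner_of and rng.random() < 0.35:
                    group.append(partner_of[k])
                e_old = energy.group_energy(group)
                saved = [(segs[g].position.copy(), segs[g].rotation,
                          energy.coords[g]) for g in group]
                shift = rng.normal(scale=st, size=3)
                spin = Rotation.from_rotvec(rng.normal(scale=sr, size=3))
                if len(group) == 1:
                    g = group[0]
                    segs[g].position = segs[g].position + shift
                    segs[g].rotation = spin * segs[g].rotation
                    energy.coords[g] = segs[g].coords()
                else:
                    centre = np.mean([segs[g].position for g in group], axis=0)
                    for g in group:
                        segs[g].position = (spin.apply(segs[g].position
                                                       - centre)
                                            + centre + shift)
                        segs[g].rotation = spin * segs[g].rotation
                        energy.coords[g] = segs[g].coords()
                dE = energy.group_energy(group) - e_old
                accept = dE <= 0 or (t > 0 and rng.random() < math.exp(-dE / t))
                if not accept:
                    for g, (pos, rot, xyz) in zip(group, saved):
                        segs[g].position = pos
                        segs[g].rotation = rot
                        energy.coords[g] = xyz


def build_model(
    topology: ChainTopology,
    assignment: SegmentAssignment,
    params: BuildParams | None = None,
    seed: int | None = None,
    library: Sequence[CCPair] | None = None,
) -> CGModel:
    """Build one coarse-grained cage model (deterministic under ``seed``).

    Stages activate one CC pair at a time in chain order; each stage
    anneals all segments whose restraints are already active, then a
    final quench polishes the full restraint set.  A model whose worst
    per-pair restraint RMS exceeds ``params.convergence_rms`` is still
    returned, flagged ``converged=False``.
    """
    params = params or BuildParams()
    if seed is None:
        seed = params.seed
    library = library if library is not None else packaged_library()
    rng = np.random.default_rng(seed)
    lengths = _segment_lengths(topology, assignment, library)
    segments = _initial_placement(topology, lengths, params, rng)
    energy = _Energy(topology, segments, params)

    stage_pairs = sorted(topology.pairs(), key=lambda p: p[0])
    stage_temps = np.geomspace(params.t_start, params.t_end, params.n_temps)
    touched: set[int] = set()
    for key in stage_pairs:
        energy.active.add(key)
        _dock_partner(energy, key, params, rng)
        touched.update(key)
        _anneal(energy, touched, params, rng, stage_temps,
                params.sweeps_per_temp)
    # final polish: moderate re-anneal of everything, then a greedy
    # quench (downhill only); badly formed dimers are re-docked and the
    # polish repeated a few times before giving up
    everything = set(range(len(segments)))
    for repair in range(3):
        _anneal(energy, everything, params, rng,
                np.geomspace(params.t_end * 4, params.t_end / 4, 6),
                params.sweeps_per_temp)
        _anneal(energy, everything, params, rng,
                np.full(4, 0.0), params.quench_sweeps // 4)
        bad = [key for key in stage_pairs
               if np.sqrt(np.mean(energy.pair_deviations(key) ** 2))
               > params.convergence_rms]
        if not bad:
            break
        for key in bad:
            _dock_partner(energy, key, params, rng)

    residuals = np.array([
        float(np.sqrt(np.mean(energy.pair_deviations(key) ** 2)))
        for key in stage_pairs])
    clashes = energy.clash_count()
    converged = bool(residuals.max() <= params.convergence_rms)

    chains = _chain_coordinates(topology, energy, params)
    pair_names = [f"{i}-{j}" for i, j in stage_pairs]
    meta = {"seed": int(seed), "params": params, "lengths": lengths}
    for c, sl in enumerate(topology.chain_slices()):
        start = 0
        for i in range(sl.start, sl.stop):
            segments[i].residue_span = (start, start + lengths[i])
            start += lengths[i] + (params.linker_residues
                                   if i < sl.stop - 1 else 0)
    return CGModel(chains=chains, segments=segments,
                   restraint_residuals=residuals, clash_count=clashes,
                   converged=converged, pair_names=pair_names, metadata=meta)


def _chain_coordinates(topology, energy: _Energy,
                       params: BuildParams) -> list[np.ndarray]:
    """Concatenate segment beads per chain, optionally interpolating
    straight-line linker beads so the bead count matches the sequence."""
    chains = []
    for sl in topology.chain_slices():
        parts = []
        for i in range(sl.start, sl.stop):
            parts.append(energy.coords[i])
            if params.include_linker_beads and i < sl.stop - 1:
                a = energy.coords[i][-1]
                b = energy.coords[i + 1][0]
                frac = np.linspace(0, 1, params.linker_residues + 2)[1:-1]
                parts.append(a[None, :] + frac[:, None] * (b - a)[None, :])
        chains.append(np.vstack(parts))
    return chains


def generate_ensemble(
    topology: ChainTopology,
    assignment: SegmentAssignment,
    params: BuildParams | None = None,
    library: Sequence[CCPair] | None = None,
) -> tuple[list[CGModel], pd.DataFrame]:
    """Independent seeded builds plus a per-replica summary table.

    Sub-seeds are spawned deterministically from ``params.seed``, so the
    whole ensemble is bitwise reproducible.
    """
    params = params or BuildParams()
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(params.seed).spawn(params.replicas)]
    models = [build_model(topology, assignment, params=params, seed=s,
                          library=library)
              for s in seeds]
    rows = []
    for s, m in zip(seeds, models):
        rows.append({
            "seed": s,
            "restraint_rms": float(m.restraint_residuals.mean()),
            "restraint_rms_max": float(m.restraint_residuals.max()),
            "clashes": m.clash_count,
            "converged": m.converged,
            "rg_nm": m.rg() / 10.0,
            "dmax_nm": m.dmax() / 10.0,
            "cavity_radius_nm": cavity_radius(m) / 10.0,
        })
    return models, pd.DataFrame(rows)


def cavity_radius(model: CGModel, probe: float = 2.0) -> float:
    """Radius (Å) of the largest bead-free sphere centred at the centroid.

    Returns 0 for degenerate (e.g. collinear or centroid-touching)
    bead sets.
    """
    x = model.coords() if isinstance(model, CGModel) else np.asarray(model)
    if len(x) < 4:
        raise ValueError("cavity radius needs at least 4 beads")
    centre = x.mean(axis=0)
    dmin = float(np.linalg.norm(x - centre, axis=1).min())
    return max(0.0, dmin - probe)


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def write_pdb(models: CGModel | Sequence[CGModel], path,
              assignment: SegmentAssignment | None = None) -> None:
    """CA-trace PDB writer (one chain ID per topology chain).

    Multiple models become a multi-MODEL file.  REMARK 300 lines record
    segment/pair assignments; the B-factor column carries the restraint
    RMS of the segment's dimer.
    """
    if isinstance(models, CGModel):
        models = [models]
    with open(path, "w") as fh:
        fh.write("REMARK 300 coarse-grained CCPO cage model (CA trace)\n")
        if assignment is not None:
            for i in sorted(assignment.by_segment):
                name, role = assignment.by_segment[i]
                fh.write(f"REMARK 300 SEGMENT {i:3d} {name} role {role}\n")
        multi = len(models) > 1
        for nm, model in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {nm:4d}\n")
            res_rms = _per_segment_rms(model)
            serial = 1
            for c, xyz in enumerate(model.chains):
                chain_id = chr(ord("A") + c)
                bvals = res_rms.get(c, np.zeros(len(xyz)))
                for r, (x, y, z) in enumerate(xyz, start=1):
                    b = float(bvals[r - 1]) if r - 1 < len(bvals) else 0.0
                    fh.write(
                        f"ATOM  {serial:5d}  CA  ALA {chain_id}{r:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                        f"          C  \n")
                    serial += 1
                fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _per_segment_rms(model: CGModel) -> dict[int, np.ndarray]:
    pair_rms = {}
    for name, rms in zip(model.pair_names, model.restraint_residuals):
        i, j = map(int, name.split("-"))
        pair_rms[i] = pair_rms[j] = float(rms)
    out: dict[int, np.ndarray] = {}
    chain_segs: dict[int, list[RigidSegment]] = {}
    for seg in model.segments:
        chain_segs.setdefault(seg.chain, []).append(seg)
    for c, xyz in enumerate(model.chains):
        vals = np.zeros(len(xyz))
        for seg in chain_segs.get(c, []):
            a, b = seg.residue_span
            vals[a:min(b, len(vals))] = pair_rms.get(seg.index, 0.0)
        out[c] = vals
    return out
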