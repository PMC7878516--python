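"""CC-pair library handling, segment assignment and sequence assembly.

The building blocks of a CCPO design are orthogonal coiled-coil dimer
modules: pairs of peptides (heterodimers) or self-pairing peptides
(homodimers), parallel or antiparallel, drawn from a characterised
toolkit.  This module loads such a library, assigns a module to every
edge-dimer of a chain topology under orthogonality constraints, and
concatenates the assigned peptides — with linkers, terminal tags and
protease sites — into annotated full-length protein sequences.

The packaged library (``data/cc_library.tsv``) is a *synthetic* stand-in
with idealised heptad sequences; it mirrors the composition of the real
toolkit (six parallel heterodimer modules with higher-helicity "SH"
variants, one parallel and two antiparallel homodimer modules) but not
its published sequences.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

from .topology import ChainTopology, PARALLEL, ANTIPARALLEL, TopologyError

__all__ = [
    "CCPair", "SegmentAssignment", "AnnotatedSequence", "AssignmentError",
    "load_cc_library", "save_cc_library", "packaged_library",
    "assign_segments", "assemble_sequence", "molecular_weight", "tev_cleave",
    "write_fasta", "read_fasta",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
LIBRARY_COLUMNS = ["name", "seq_a", "seq_b", "orientation", "group", "variant"]

#: Default TEV protease recognition/cleavage convention: ENLYFQ | (G or S).
TEV_MOTIF = re.compile(r"ENLYFQ[GS]")
TEV_SITE_SEQ = "ENLYFQS"

DEFAULT_LINKER = "GSGPG"
DEFAULT_TAGS = {"N": "MHHHHHHHHGS", "C": ""}  # His8 purification tag stand-in

WATER_DA = 18.0153


class AssignmentError(ValueError):
    """Infeasible or inconsistent segment-to-module assignment."""


@dataclass(frozen=True)
class CCPair:
    """One coiled-coil dimer module of the library."""

    name: str
    seq_a: str
    seq_b: str
    orientation: str
    group: str
    variant: str = "SN"

    def __post_init__(self) -> None:
        for seq in (self.seq_a, self.seq_b):
            if not seq:
                raise AssignmentError(f"{self.name}: empty peptide sequence")
            bad = set(seq) - AA20
            if bad:
                raise AssignmentError(
                    f"{self.name}: non-standard residues {sorted(bad)}")
        if self.orientation not in (PARALLEL, ANTIPARALLEL):
            raise AssignmentError(
                f"{self.name}: orientation must be parallel/antiparallel")

    @property
    def homodimer(self) -> bool:
        return self.seq_a == self.seq_b

    @property
    def member_names(self) -> tuple[str, str]:
        if ":" in self.name:
            a, b = self.name.split(":", 1)
            return a, b
        return self.name, self.name

    def sequence(self, role: str) -> str:
        if role == "a":
            return self.seq_a
        if role == "b":
            return self.seq_b
        raise AssignmentError(f"role must be 'a' or 'b', got {role!r}")


def load_cc_library(source) -> list[CCPair]:
    """Read a CC-pair library from TSV (path, buffer or text)."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise AssignmentError(f"library table missing columns {missing}")
    pairs = []
    for _, row in df.iterrows():
        if row[LIBRARY_COLUMNS].isna().any():
            raise AssignmentError(f"malformed library row: {row.to_dict()}")
        pairs.append(CCPair(name=row["name"], seq_a=row["seq_a"],
                            seq_b=row["seq_b"], orientation=row["orientation"],
                            group=row["group"], variant=row["variant"]))
    return pairs


def save_cc_library(pairs: Iterable[CCPair], path) -> None:
    df = pd.DataFrame([{c: getattr(p, c if c.startswith("seq") else c)
                        for c in LIBRARY_COLUMNS} for p in pairs])
    df.to_csv(path, sep="\t", index=False)


def packaged_library() -> list[CCPair]:
    """The synthetic fixture library shipped with the package."""
    text = resources.files("ccpo.data").joinpath("cc_library.tsv").read_text()
    return load_cc_library(io.StringIO(text))


# ---------------------------------------------------------------------------
# Segment assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssignmentPolicy:
    """Rules steering module selection.

    mirror_reuse
        Assign identical modules to mirrored pairs of the two halves of a
        pseudo-symmetric design (each half folds independently, so
        orthogonality only has to hold within a half).
    interface_variant
        When set (e.g. ``"SH"``), interface pairs are switched to the
        higher-helicity variant of the chosen module group if the
        library provides one.
    scopes
        Explicit orthogonality scopes as sets of pair keys; within one
        scope no module group may appear twice.  Default: derived from
        the topology (per half-plus-interface for mirrored designs, a
        single global scope otherwise).
    """

    mirror_reuse: bool = False
    interface_variant: str | None = None
    scopes: tuple[frozenset, ...] | None = None


@dataclass(frozen=True)
class SegmentAssignment:
    """Module assignment for every segment of a topology."""

    by_segment: Mapping[int, tuple[str, str]]  # index -> (pair name, role)
    linkers: Mapping[int, str] = field(default_factory=dict)  # global junction -> linker
    tags: Mapping[tuple[int, str], str] = field(default_factory=dict)
    cleavage_sites: tuple[tuple[int, int, str], ...] = ()  # (chain, junction, motif)

    def pair_name(self, i: int) -> str:
        return self.by_segment[i][0]

    def validate(self, topology: ChainTopology,
                 library: Sequence[CCPair]) -> None:
        lib = {p.name: p for p in library}
        for i, j in topology.pairs():
            (na, ra), (nb, rb) = self.by_segment[i], self.by_segment[j]
            if na != nb:
                raise AssignmentError(f"pair ({i},{j}) assigned different modules")
            pair = lib[na]
            if {ra, rb} != {"a", "b"} and not pair.homodimer:
                raise AssignmentError(
                    f"pair ({i},{j}) must take complementary roles of {na}")
            want = topology.orientations[tuple(sorted((i, j)))]
            if pair.orientation != want:
                raise AssignmentError(
                    f"module {na} is {pair.orientation}, edge needs {want}")


def _default_scopes(topology: ChainTopology) -> list[set]:
    pairs = topology.pairs()
    interface = set(topology.interface_pairs())
    n = topology.n_segments
    if topology.n_chains == 1 and n % 2 == 0:
        m = n // 2
        half_a = {p for p in pairs if p[1] < m}
        half_b = {p for p in pairs if p[0] >= m}
        crossing = {p for p in pairs if p[0] < m <= p[1]}
        if half_a and half_b:
            return [half_a | crossing, half_b | crossing]
    if topology.n_chains == 2:
        sl = topology.chain_slices()
        half_a = {p for p in pairs
                  if p not in interface and p[1] < sl[0].stop}
        half_b = {p for p in pairs
                  if p not in interface and p[0] >= sl[1].start}
        return [half_a | interface, half_b | interface]
    return [set(pairs)]


def _mirror_map(topology: ChainTopology) -> dict | None:
    """Map each half-B intra pair to its half-A mirror twin, if mirrored.

    Tries index translation first, then reflection, matching the two
    pseudo-mirror conventions recognised by the topology design search.
    """
    n = topology.n_segments
    if n % 2:
        return None
    m = n // 2
    intra_a = {p for p in topology.pairs() if p[1] < m}
    intra_b = [p for p in topology.pairs() if p[0] >= m]
    for twin_of in (lambda i, j: (i - m, j - m),
                    lambda i, j: tuple(sorted((m - 1 - (i - m), m - 1 - (j - m))))):
        mapping = {}
        for i, j in intra_b:
            twin = tuple(sorted(twin_of(i, j)))
            if twin not in intra_a:
                mapping = None
                break
            mapping[(i, j)] = twin
        if mapping is not None:
            return mapping
    return None


def assign_segments(
    topology: ChainTopology,
    library: Sequence[CCPair],
    policy: AssignmentPolicy | None = None,
) -> SegmentAssignment:
    """Assign a library module to every dimer of a topology.

    Backtracking constraint search: every pair receives a module of
    matching orientation; within each orthogonality scope a module group
    is used at most once; with ``mirror_reuse`` mirrored pairs of a
    pseudo-symmetric design share a module.  Deterministic for a given
    library order.  Raises :class:`AssignmentError` naming the violated
    constraint when infeasible.
    """
    policy = policy or AssignmentPolicy()
    pairs = topology.pairs()
    # unpaired segments (e.g. the exposed interface edge of the masked
    # switch design) are assignable through their latent intermolecular
    # pairing; without one the request is genuinely infeasible
    unassigned = [i for i in topology.unpaired_segments()
                  if i not in topology.latent_pairing]
    if unassigned:
        raise AssignmentError(f"segments {unassigned} are unpaired and have "
                              "no latent partner; cannot choose a module")
    latent = sorted({tuple(sorted((i, j)))
                     for i, j in topology.latent_pairing.items()
                     if i not in topology.pairing})
    pairs = sorted(set(pairs) | set(latent))
    scopes = ([set(s) for s in policy.scopes] if policy.scopes is not None
              else _default_scopes(topology))
    mirror = _mirror_map(topology) if policy.mirror_reuse else None
    interface = set(topology.interface_pairs())
    if not interface and topology.n_chains == 1 and mirror is not None:
        m = topology.n_segments // 2
        interface = {p for p in pairs if p[0] < m <= p[1]}

    lib_by_name = {p.name: p for p in library}

    def candidates(pair_key) -> list[CCPair]:
        want = topology.orientations[pair_key]
        cands = [p for p in library if p.orientation == want]
        if policy.interface_variant and pair_key in interface:
            pref = [p for p in cands if p.variant == policy.interface_variant]
            rest = [p for p in cands if p.variant != policy.interface_variant]
            cands = pref + rest
        return cands

    order = [p for p in pairs if mirror is None or p not in mirror]
    choice: dict[tuple[int, int], str] = {}

    def group_free(pair_key, group) -> bool:
        covered = [pair_key] + ([k for k, v in mirror.items() if v == pair_key]
                                if mirror else [])
        for scope in scopes:
            used = {lib_by_name[choice[p]].group
                    for p in choice if p in scope}
            for ck in covered:
                if ck in scope and group in used:
                    return False
            # groups chosen at this step must also not collide between the
            # covered slots themselves if they land in one scope (they share
            # one module, which is fine — same group by construction)
        return True

    def search(k: int) -> bool:
        if k == len(order):
            return True
        pk = order[k]
        for cand in candidates(pk):
            if not group_free(pk, cand.group):
                continue
            choice[pk] = cand.name
            if mirror:
                for bk, ak in mirror.items():
                    if ak == pk:
                        choice[bk] = cand.name
            if search(k + 1):
                return True
            del choice[pk]
            if mirror:
                for bk, ak in list(mirror.items()):
                    if ak == pk and bk in choice:
                        del choice[bk]
        return False

    if not search(0):
        want = {topology.orientations[p] for p in pairs}
        raise AssignmentError(
            "no orthogonal assignment exists for this topology with the "
            f"given library (needed orientations: {sorted(want)}; "
            f"scopes: {len(scopes)})")

    by_segment: dict[int, tuple[str, str]] = {}
    for (i, j) in pairs:
        name = choice[tuple(sorted((i, j)))]
        pair = lib_by_name[name]
        # first-traversed segment takes role 'a'
        by_segment[i] = (name, "a")
        by_segment[j] = (name, "b" if not pair.homodimer else "a")

    linkers = {k: DEFAULT_LINKER for k in range(topology.n_segments - 1)}
    tags = {}
    for c in range(topology.n_chains):
        tags[(c, "N")] = DEFAULT_TAGS["N"]
        tags[(c, "C")] = DEFAULT_TAGS["C"]
    sites = tuple((c, j, TEV_SITE_SEQ) for c, j in topology.cleavage_sites)
    return SegmentAssignment(by_segment=by_segment, linkers=linkers,
                             tags=tags, cleavage_sites=sites)


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedSequence:
    """A protein chain with labelled intervals (segment/linker/tag/cleavage).

    Annotations are ``(start, stop, label, detail)`` with 0-based
    half-open intervals tiling the sequence without overlap.
    """

    residues: str
    annotations: tuple[tuple[int, int, str, str], ...]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        pos = 0
        for start, stop, _, _ in self.annotations:
            if start != pos or stop < start:
                raise AssignmentError("annotations must tile the sequence")
            pos = stop
        if pos != len(self.residues):
            raise AssignmentError("annotations must cover the full sequence")

    def intervals(self, label: str) -> list[tuple[int, int, str]]:
        return [(a, b, d) for a, b, lab, d in self.annotations if lab == label]

    def segment_sequences(self) -> list[str]:
        return [self.residues[a:b] for a, b, _ in self.intervals("segment")]


def assemble_sequence(
    assignment: SegmentAssignment,
    topology: ChainTopology,
    library: Sequence[CCPair],
) -> list[AnnotatedSequence]:
    """Concatenate assigned peptides into one annotated sequence per chain."""
    lib = {p.name: p for p in library}
    chains: list[AnnotatedSequence] = []
    site_lookup = {(c, j): motif for c, j, motif in assignment.cleavage_sites}
    for c, sl in enumerate(topology.chain_slices()):
        parts: list[str] = []
        anns: list[tuple[int, int, str, str]] = []
        pos = 0

        def emit(seq: str, label: str, detail: str):
            nonlocal pos
            if seq:
                anns.append((pos, pos + len(seq), label, detail))
                parts.append(seq)
                pos += len(seq)

        emit(assignment.tags.get((c, "N"), ""), "tag", "N")
        for local, i in enumerate(range(sl.start, sl.stop)):
            if local > 0:
                junction = i - 1  # global junction index
                motif = site_lookup.get((c, local))
                if motif is not None:
                    emit("SG", "linker", f"junction{junction}")
                    emit(motif, "cleavage", TEV_SITE_SEQ)
                else:
                    if junction not in assignment.linkers:
                        raise AssignmentError(
                            f"no linker defined for junction {junction}")
                    emit(assignment.linkers[junction], "linker",
                         f"junction{junction}")
            name, role = assignment.by_segment[i]
            emit(lib[name].sequence(role), "segment",
                 f"{name}|{role}|seg{i}")
        emit(assignment.tags.get((c, "C"), ""), "tag", "C")
        chains.append(AnnotatedSequence(residues="".join(parts),
                                        annotations=tuple(anns),
                                        chain_id=chr(ord("A") + c)))
    return chains


def molecular_weight(seq: str, monoisotopic: bool = False) -> float:
    """Theoretical protein mass in kDa (average isotopic by default)."""
    bad = set(seq) - AA20
    if bad:
        raise AssignmentError(f"unknown residue symbols {sorted(bad)}")
    return _bio_mw(seq, seq_type="protein", monoisotopic=monoisotopic) / 1000.0


def tev_cleave(seq: AnnotatedSequence) -> list[AnnotatedSequence]:
    """Cleave at every annotated TEV site (between Q and the following G/S).

    Without sites the input is returned unchanged (in a 1-list).  An
    annotation whose underlying residues do not match ``ENLYFQ(G|S)``
    raises, guarding against stale annotations.
    """
    cuts = []
    for a, b, _ in seq.intervals("cleavage"):
        window = seq.residues[a:b + 1]
        m = TEV_MOTIF.search(window)
        if m is None or m.start() != 0:
            raise AssignmentError(
                f"cleavage annotation at {a} does not match ENLYFQ(G|S): "
                f"{window!r}")
        cuts.append(a + 6)  # after the Q
    if not cuts:
        return [seq]
    fragments = []
    bounds = [0, *sorted(cuts), len(seq.residues)]
    for f, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        anns = []
        pos = 0
        for a, b, lab, det in seq.annotations:
            a2, b2 = max(a, lo), min(b, hi)
            if a2 >= b2:
                continue
            anns.append((a2 - lo, b2 - lo, lab, det))
            pos = b2 - lo
        fragments.append(AnnotatedSequence(
            residues=seq.residues[lo:hi],
            annotations=tuple(anns),
            chain_id=f"{seq.chain_id}{f + 1}"))
    return fragments


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def write_fasta(chains: Iterable[AnnotatedSequence], path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(f">{ch.chain_id}\n")
            for k in range(0, len(ch.residues), 60):
                fh.write(ch.residues[k:k + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
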