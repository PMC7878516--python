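"""CC library handling, orthogonal assignment, assembly, masses, TEV."""

import io
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ccpo import topology as topo
from ccpo import peptides as pep
from ccpo.peptides import (
    CCPair, AssignmentError, AssignmentPolicy, load_cc_library,
    save_cc_library, assign_segments, assemble_sequence, molecular_weight,
    tev_cleave, AnnotatedSequence, SegmentAssignment, WATER_DA,
)

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def test_packaged_library_composition(library):
    names = {p.name for p in library}
    members = {m for p in library for m in p.member_names}
    # peptides named in the cage designs are all present
    for peptide in ["P4SN", "P6SN", "P5SH", "P6SH", "P10SH", "BCRSH",
                    "BCR", "P7SH"]:
        assert peptide in members | names
    homos = [p for p in library if p.homodimer]
    assert {p.orientation for p in homos} >= {"antiparallel"}
    # SH variants share an orthogonality group with their SN parents
    groups = {}
    for p in library:
        groups.setdefault(p.group, set()).add(p.variant)
    assert any({"SN", "SH"} <= v for v in groups.values())


def test_homodimer_flag_set_on_equal_sequences():
    text = ("name\tseq_a\tseq_b\torientation\tgroup\tvariant\n"
            "X\tAAAAKEL\tAAAAKEL\tantiparallel\tX\tSN\n")
    pairs = load_cc_library(io.StringIO(text))
    assert pairs[0].homodimer


def test_library_round_trip(tmp_path, library):
    path = tmp_path / "lib.tsv"
    save_cc_library(library, path)
    back = load_cc_library(path)
    assert back == library


@pytest.mark.parametrize("row", [
    "X\tAAXA\tAAAA\tparallel\tg\tSN",        # bad residue
    "X\tAAAA\tAAAA\tsideways\tg\tSN",        # bad orientation
    "X\t\tAAAA\tparallel\tg\tSN",            # empty sequence
])
def test_malformed_library_rows_raise(row):
    text = "name\tseq_a\tseq_b\torientation\tgroup\tvariant\n" + row + "\n"
    with pytest.raises(AssignmentError):
        load_cc_library(io.StringIO(text))


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def test_antiparallel_homodimer_assignment():
    t = topo.ChainTopology(segments=((0, 1), (1, 0)), pairing={0: 1, 1: 0},
                           orientations={(0, 1): "antiparallel"})
    lib = [CCPair("H", "ASEIAALEK", "ASEIAALEK", "antiparallel", "H")]
    asn = assign_segments(t, lib)
    seqs = {lib[0].sequence(asn.by_segment[i][1]) for i in (0, 1)}
    assert seqs == {"ASEIAALEK"}


def test_reference_assignment_valid(bipyramid_topology, bipyramid_assignment,
                                    library):
    bipyramid_assignment.validate(bipyramid_topology, library)
    # mirrored halves reuse identical modules
    pairs = bipyramid_topology.pairs()
    m = 9
    half_a = {p: bipyramid_assignment.pair_name(p[0])
              for p in pairs if p[1] < m}
    half_b = {p: bipyramid_assignment.pair_name(p[0])
              for p in pairs if p[0] >= m}
    assert sorted(half_a.values()) == sorted(half_b.values())
    # interface uses three distinct parallel SH heterodimers
    lib = {p.name: p for p in library}
    iface = [bipyramid_assignment.pair_name(p[0])
             for p in pairs if p[0] < m <= p[1]]
    assert len(set(iface)) == 3
    assert all(lib[n].variant == "SH" and lib[n].orientation == "parallel"
               for n in iface)


def brute_force_feasible(topology, lib):
    """Exhaustive search over module choices (oracle for small graphs)."""
    pairs = topology.pairs()
    for combo in itertools.product(lib, repeat=len(pairs)):
        if any(c.orientation != topology.orientations[p]
               for c, p in zip(combo, pairs)):
            continue
        if len({c.group for c in combo}) != len(combo):
            continue
        return True
    return False


@pytest.mark.parametrize("orients", list(itertools.product(
    ["parallel", "antiparallel"], repeat=3)))
def test_assignment_feasibility_matches_brute_force(orients):
    # triangle double trace -> 6 segments, pairs (0,3), (1,4), (2,5)
    segments = [("u", "v"), ("v", "w"), ("w", "u")] * 2
    pairing = {0: 3, 3: 0, 1: 4, 4: 1, 2: 5, 5: 2}
    orientations = {(0, 3): orients[0], (1, 4): orients[1], (2, 5): orients[2]}
    t = topo.ChainTopology(segments=tuple(segments), pairing=pairing,
                           orientations=orientations)
    lib = [
        CCPair("PA:PB", "ASEIAALEK", "ASKIAALEE", "parallel", "g1"),
        CCPair("PC:PD", "ASEIQALEK", "ASKIQALEE", "parallel", "g2"),
        CCPair("APH", "ASEIAKLEK", "ASEIAKLEK", "antiparallel", "g3"),
    ]
    expect = brute_force_feasible(t, lib)
    if expect:
        asn = assign_segments(t, lib)
        asn.validate(t, lib)
    else:
        with pytest.raises(AssignmentError):
            assign_segments(t, lib)


def test_infeasible_assignment_names_constraint():
    t = topo.ChainTopology(segments=((0, 1), (0, 1)), pairing={0: 1, 1: 0},
                           orientations={(0, 1): "parallel"})
    lib = [CCPair("APH", "ASEIAKLEK", "ASEIAKLEK", "antiparallel", "g")]
    with pytest.raises(AssignmentError, match="orientations"):
        assign_segments(t, lib)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_two_segment_assembly_without_linkers():
    t = topo.ChainTopology(segments=((0, 1), (0, 1)), pairing={0: 1, 1: 0},
                           orientations={(0, 1): "parallel"})
    lib = [CCPair("PA:PB", "ASEIAALEK", "ASKIAALEE", "parallel", "g")]
    asn = SegmentAssignment(by_segment={0: ("PA:PB", "a"), 1: ("PA:PB", "b")},
                            linkers={0: ""}, tags={})
    chains = assemble_sequence(asn, t, lib)
    assert len(chains) == 1
    assert chains[0].residues == "ASEIAALEK" + "ASKIAALEE"


def test_assembly_annotations_tile_and_round_trip(
        bipyramid_topology, bipyramid_assignment, library):
    chains = assemble_sequence(bipyramid_assignment, bipyramid_topology,
                               library)
    assert len(chains) == 1
    ch = chains[0]
    assert ch.annotations[-1][1] == len(ch.residues)
    # segment extraction returns the library peptides verbatim
    lib = {p.name: p for p in library}
    for (a, b, det) in ch.intervals("segment"):
        name, role, _ = det.split("|")
        assert ch.residues[a:b] == lib[name].sequence(role)


def test_masked_assembly_has_cleavage_between_9th_and_10th_segment(
        bipyramid_topology, library):
    masked = topo.split_topology(bipyramid_topology, "masked_switch")
    asn = assign_segments(masked, library,
                          AssignmentPolicy(interface_variant="SH"))
    chains = assemble_sequence(asn, masked, library)
    assert len(chains) == 2
    for ch in chains:
        (a, b, det), = ch.intervals("cleavage")
        segs_before = sum(1 for (s, e, _) in ch.intervals("segment") if e <= a)
        assert segs_before == 9


def test_missing_linker_raises():
    t = topo.ChainTopology(segments=((0, 1), (0, 1)), pairing={0: 1, 1: 0},
                           orientations={(0, 1): "parallel"})
    lib = [CCPair("PA:PB", "ASEIAALEK", "ASKIAALEE", "parallel", "g")]
    asn = SegmentAssignment(by_segment={0: ("PA:PB", "a"), 1: ("PA:PB", "b")},
                            linkers={}, tags={})
    with pytest.raises(AssignmentError, match="linker"):
        assemble_sequence(asn, t, lib)


# ---------------------------------------------------------------------------
# molecular weight
# ---------------------------------------------------------------------------

def test_molecular_weight_of_glycine_peptides():
    assert molecular_weight("G") == pytest.approx(0.07507, abs=5e-5)
    assert molecular_weight("GG") == pytest.approx(0.13212, abs=5e-5)


@settings(max_examples=40, deadline=None)
@given(AA, AA)
def test_mass_additivity(s1, s2):
    total = molecular_weight(s1) + molecular_weight(s2) - WATER_DA / 1000.0
    assert molecular_weight(s1 + s2) == pytest.approx(total, abs=1e-9)


def test_unknown_residue_raises():
    with pytest.raises(AssignmentError):
        molecular_weight("GXG")


# ---------------------------------------------------------------------------
# TEV cleavage
# ---------------------------------------------------------------------------

def _annotated(seq, cleav_spans=()):
    anns, pos = [], 0
    spans = sorted(cleav_spans)
    for a, b in spans:
        if pos < a:
            anns.append((pos, a, "segment", "x"))
        anns.append((a, b, "cleavage", "ENLYFQS"))
        pos = b
    if pos < len(seq):
        anns.append((pos, len(seq), "segment", "x"))
    return AnnotatedSequence(residues=seq, annotations=tuple(anns))


def test_tev_no_site_is_identity():
    seq = _annotated("MKKLAAAEEL")
    assert tev_cleave(seq) == [seq]


def test_tev_single_site_conserves_residues_and_mass():
    left, right = "MKKLAA", "GSAEELRR"
    seq = _annotated(left + "ENLYFQS" + right,
                     cleav_spans=[(len(left), len(left) + 7)])
    frags = tev_cleave(seq)
    assert len(frags) == 2
    assert frags[0].residues.endswith("ENLYFQ")
    assert frags[1].residues.startswith("S")
    assert sum(len(f.residues) for f in frags) == len(seq.residues)
    total = sum(molecular_weight(f.residues) for f in frags)
    assert total == pytest.approx(
        molecular_weight(seq.residues) + WATER_DA / 1000.0, abs=1e-9)


def test_tev_mismatched_annotation_raises():
    seq = _annotated("MKKLAAENLYFASGSAEEL", cleav_spans=[(6, 13)])
    with pytest.raises(AssignmentError, match="ENLYFQ"):
        tev_cleave(seq)


def test_masked_chain_cleaves_into_core_and_masks(bipyramid_topology,
                                                  library):
    masked = topo.split_topology(bipyramid_topology, "masked_switch")
    asn = assign_segments(masked, library,
                          AssignmentPolicy(interface_variant="SH"))
    chains = assemble_sequence(asn, masked, library)
    frags = tev_cleave(chains[0])
    assert len(frags) == 2
    n_segs = [len(f.intervals("segment")) for f in frags]
    assert n_segs == [9, 2]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_fasta_round_trip(tmp_path, bipyramid_topology, bipyramid_assignment,
                          library):
    chains = assemble_sequence(bipyramid_assignment, bipyramid_topology,
                               library)
    path = tmp_path / "chains.fasta"
    pep.write_fasta(chains, path)
    back = pep.read_fasta(path)
    assert back == {c.chain_id: c.residues for c in chains}
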