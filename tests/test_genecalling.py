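"""Six-frame ORF calling against an exhaustive oracle; mapping; counting."""

import numpy as np
import pytest

from metatx.assembler import Contig, revcomp
from metatx.formats import SequenceRecord
from metatx.genecalling import (
    Orf,
    Placement,
    call_orfs,
    map_reads,
    quantify,
    resolve_overlaps,
    translate,
)

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _oracle_orfs(seq, min_orf_aa, min_partial_aa):
    """Independent six-frame enumeration: list every stop codon per frame
    and derive the expected (start, end, strand, partial flags) set."""
    out = set()
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codon_starts = list(range(frame, L - 2, 3))
            stops = [i for i in codon_starts if s[i : i + 3] in STOPS]
            boundaries = [None] + stops + [None]
            for a, b in zip(boundaries[:-1], boundaries[1:]):
                begin = frame if a is None else a + 3
                if b is None:
                    end_coding = codon_starts[-1] + 3 if codon_starts else frame
                    if end_coding <= begin:
                        continue
                    coding = (begin, end_coding)
                    p3 = True
                else:
                    coding = (begin, b)
                    p3 = False
                p5 = a is None
                first, last = coding
                if not p5:
                    starts_in = [
                        i for i in range(first, last, 3) if s[i : i + 3] in STARTS
                    ]
                    if not starts_in:
                        continue
                    first = starts_in[0]
                aa = (last - first) // 3
                min_aa = min_partial_aa if (p5 or p3) else min_orf_aa
                if aa < min_aa:
                    continue
                lo, hi = first, last + (0 if p3 else 3)
                if strand == "-":
                    lo, hi = L - hi, L - lo
                out.add((lo, hi, strand, p5, p3))
    return out


def test_call_orfs_matches_exhaustive_oracle_on_random_contigs():
    rng = np.random.default_rng(0)
    for i in range(60):
        seq = _random_seq(rng, int(rng.integers(90, 700)))
        got = {
            (o.start, o.end, o.strand, o.partial5, o.partial3)
            for o in call_orfs(Contig("c", seq), min_orf_aa=30, min_partial_aa=15)
        }
        want = _oracle_orfs(seq, 30, 15)
        assert got == want, f"contig {i}"


def test_single_complete_orf_is_found():
    rng = np.random.default_rng(1)
    codons = []
    while len(codons) < 119:
        c = _random_seq(rng, 3)
        if c not in STOPS and c not in STARTS:
            codons.append(c)
    orf = "ATG" + "".join(codons) + "TAA"  # 120 codons + stop
    # pad so the flanks are stop-terminated and won't extend the frame
    seq = "CCTAA" + orf + "TAACC"
    orfs = [
        o
        for o in call_orfs(Contig("c", seq), min_orf_aa=100, min_partial_aa=100)
        if not (o.partial5 or o.partial3)
    ]
    assert len(orfs) == 1
    o = orfs[0]
    assert len(o.protein) == 120
    assert o.protein[0] == "M"
    assert "*" not in o.protein


def test_stop_saturated_contig_yields_no_complete_orfs():
    # no ATG anywhere and plus-strand frames are wall-to-wall stops
    orfs = call_orfs(Contig("c", "TAATAA" * 30))
    assert all(o.partial5 or o.partial3 for o in orfs)
    assert call_orfs(Contig("c", "TAATAA" * 30), min_partial_aa=100) == []


def test_uninterrupted_frame_is_double_partial():
    rng = np.random.default_rng(2)
    codons = []
    while len(codons) < 134:
        c = _random_seq(rng, 3)
        if c not in STOPS:
            codons.append(c)
    seq = "".join(codons)[:400]
    orfs = call_orfs(Contig("c", seq), min_orf_aa=60, min_partial_aa=60)
    frame0 = [o for o in orfs if o.strand == "+" and o.start == 0]
    assert frame0
    assert frame0[0].partial5 and frame0[0].partial3
    assert frame0[0].end >= 398  # last complete codon


def test_translate_table11_start_codons():
    assert translate("ATGAAA") == "MK"
    assert translate("GTGAAA") == "VK"
    assert translate("GTGAAA", as_start=True) == "MK"


def _contig(seq):
    return Contig("c1", seq)


def test_exact_read_maps_with_zero_mismatches():
    rng = np.random.default_rng(3)
    contig = _contig(_random_seq(rng, 400))
    read = SequenceRecord("r1", contig.seq[100:175])
    pl = map_reads([read], [contig])["r1"]
    assert pl is not None
    assert (pl.contig_id, pl.start, pl.strand, pl.mismatches) == ("c1", 100, "+", 0)


def test_reverse_complement_read_maps_on_minus_strand():
    rng = np.random.default_rng(4)
    contig = _contig(_random_seq(rng, 400))
    read = SequenceRecord("r1", revcomp(contig.seq[50:125]))
    pl = map_reads([read], [contig])["r1"]
    assert pl is not None and pl.strand == "-" and pl.start == 50


def test_unrelated_read_is_unmapped():
    rng = np.random.default_rng(5)
    contig = _contig(_random_seq(rng, 400))
    read = SequenceRecord("r1", _random_seq(rng, 75))
    assert map_reads([read], [contig])["r1"] is None


def test_mismatched_read_matches_exhaustive_alignment_oracle():
    """Reads with up to 3 substitutions must land where a brute-force
    scan over every (offset, strand) finds the fewest mismatches."""
    rng = np.random.default_rng(6)
    contig = _contig(_random_seq(rng, 500))
    for trial in range(25):
        start = int(rng.integers(0, len(contig.seq) - 75))
        frag = list(contig.seq[start : start + 75])
        for _ in range(int(rng.integers(0, 3))):
            j = int(rng.integers(5, 70))
            frag[j] = "ACGT"[int(rng.integers(4))]
        seq = "".join(frag)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        pl = map_reads([SequenceRecord("r", seq)], [contig], max_mismatch=3)["r"]
        best = 75
        for oriented in (seq, revcomp(seq)):
            for off in range(len(contig.seq) - 75 + 1):
                mm = sum(
                    a != b
                    for a, b in zip(oriented, contig.seq[off : off + 75])
                )
                best = min(best, mm)
        if best <= 3:
            assert pl is not None and pl.mismatches == best
        else:
            assert pl is None


def test_soft_clipped_read_maps_at_contig_end():
    rng = np.random.default_rng(7)
    contig = _contig(_random_seq(rng, 300))
    # read overhangs the contig start by 10 bases
    read = SequenceRecord("r1", _random_seq(rng, 10) + contig.seq[:65])
    pl = map_reads([read], [contig])["r1"]
    assert pl is not None
    assert pl.start == 0 and pl.length == 65


def _orf(oid, start, end, contig="c1"):
    return Orf(oid, contig, start, end, "+", 0, False, False, "M" * ((end - start) // 3))


def test_quantify_counts_contained_reads():
    orfs = [_orf("o1", 100, 400)]
    placements = {
        f"r{i}": Placement("c1", 150 + i, "+", 0, 75) for i in range(10)
    }
    expr = quantify(placements, orfs)
    assert expr.counts["o1"] == 10
    assert expr.table.loc[0, "reads_per_kb"] == pytest.approx(10 / 0.3)


def test_quantify_assigns_read_to_largest_overlap():
    orfs = [_orf("a", 0, 160), _orf("b", 205, 400)]
    # read at 100..175: overlaps a by 60, b by 0; read at 145..220: a 15, b 15
    placements = {
        "r1": Placement("c1", 100, "+", 0, 75),
        "r2": Placement("c1", 190, "+", 0, 75),  # a 0, b 60
        "r3": Placement("c1", 145, "+", 0, 75),  # a 15, b 0
    }
    expr = quantify(placements, orfs)
    assert expr.read_orf["r1"] == "a"
    assert expr.read_orf["r2"] == "b"
    assert expr.read_orf["r3"] == "a"


def test_quantify_tie_goes_to_smaller_start():
    orfs = [_orf("late", 100, 200), _orf("early", 50, 150)]
    placements = {"r1": Placement("c1", 75, "+", 0, 75)}  # 50bp overlap with both
    expr = quantify(placements, orfs)
    assert expr.read_orf["r1"] == "early"


def test_quantify_conservation():
    orfs = [_orf("o1", 0, 150)]
    placements = {
        "r1": Placement("c1", 10, "+", 0, 75),
        "r2": Placement("c1", 300, "+", 0, 75),  # intergenic
        "r3": None,  # unmapped
    }
    expr = quantify(placements, orfs)
    total = sum(expr.counts.values()) + expr.n_intergenic + expr.n_unmapped
    assert total == 3
    assert expr.n_intergenic == 1 and expr.n_unmapped == 1


def test_resolve_overlaps_prefers_annotated_then_longer():
    spurious = _orf("x", 0, 300)
    true_orf = _orf("y", 2, 296)
    kept = resolve_overlaps([spurious, true_orf], annotated={"y"})
    assert [o.id for o in kept] == ["y"]
    # without annotation evidence the longer one wins
    kept = resolve_overlaps([spurious, true_orf])
    assert [o.id for o in kept] == ["x"]
    # disjoint ORFs are both kept
    far = _orf("z", 500, 800)
    assert len(resolve_overlaps([spurious, far])) == 2
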