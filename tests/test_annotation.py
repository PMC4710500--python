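"""Local alignment scoring, search ranking, SBH transfer, SRV, COG lumping."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from metatx import annotation
from metatx.annotation import (
    ReferenceProteinDB,
    annotate_sbh,
    lump_cog_categories,
    search,
    smith_waterman,
    srv,
)

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def sw_oracle(a, b, gap_open=11, gap_extend=1):
    """Independent affine-gap local alignment by explicit 3-matrix DP.

    BLAST convention: a gap of length L costs gap_open + L * gap_extend.
    """
    NEG = -(10**9)
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (left moves)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (up moves)
    best = 0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def test_identical_tripeptide_scores_diagonal_sum():
    hit = smith_waterman("ARN", "ARN")
    assert hit.raw_score == 15  # 4 + 5 + 6 on the BLOSUM62 diagonal


def test_self_alignment_scores_diagonal_sum():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list(AA), size=40))
    hit = smith_waterman(seq, seq)
    assert hit.raw_score == sum(int(B62[c, c]) for c in seq)
    assert hit.identity_fraction == 1.0


def test_all_negative_pair_scores_zero():
    hit = smith_waterman("AAAA", "WWWW")
    assert hit.raw_score == 0
    assert hit.identity_fraction == 0.0


def test_bit_score_and_evalue_formulas():
    hit = smith_waterman("ARNDCQEGHILK", "ARNDCQEGHILK")
    expect_bit = (0.267 * hit.raw_score - math.log(0.041)) / math.log(2)
    assert hit.bit_score == pytest.approx(expect_bit)
    assert hit.evalue == pytest.approx(12 * 12 * 2 ** (-expect_bit))


def test_smith_waterman_matches_brute_force_dp():
    """Score identity with an independent 3-matrix DP on random pairs,
    including related pairs (mutated copies) to exercise gaps."""
    rng = np.random.default_rng(1)
    for trial in range(80):
        la, lb = int(rng.integers(5, 45)), int(rng.integers(5, 45))
        a = "".join(rng.choice(list(AA), size=la))
        if trial % 2:
            b = "".join(rng.choice(list(AA), size=lb))
        else:  # homolog with substitutions and an indel
            b = list(a)
            for _ in range(int(rng.integers(0, 6))):
                b[int(rng.integers(0, len(b)))] = str(rng.choice(list(AA)))
            if len(b) > 10:
                del b[int(rng.integers(0, len(b)))]
            b = "".join(b)
        assert smith_waterman(a, b).raw_score == sw_oracle(a, b), (a, b)


def test_unknown_residue_scored_as_x():
    assert smith_waterman("AJA", "AXA").raw_score == smith_waterman(
        "AXA", "AXA"
    ).raw_score


def _db(seqs, **labels):
    df = pd.DataFrame(labels, index=list(seqs))
    return ReferenceProteinDB(seqs, df)


@pytest.fixture(scope="module")
def paralog_db():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list(AA), size=80))

    def mutate(frac):
        out = list(base)
        idx = rng.choice(80, size=int(80 * frac), replace=False)
        for i in idx:
            out[i] = str(rng.choice([c for c in AA if c != out[i]]))
        return "".join(out)

    seqs = {"p100": base, "p90": mutate(0.10), "p80": mutate(0.20)}
    return base, _db(
        seqs,
        taxid=[1, 1, 1],
        ko=["K00001", "K00002", "K00003"],
        cog=["COG1", "COG2", "COG3"],
        categories=["J", "K", "T"],
    )


def test_search_ranks_by_identity(paralog_db):
    base, db = paralog_db
    hits = search({"q": base}, db, prefilter=False)["q"]
    assert [h.subject_id for h in hits] == ["p100", "p90", "p80"]
    assert hits[0].bit_score > hits[1].bit_score > hits[2].bit_score


def test_search_returns_nothing_below_threshold(paralog_db):
    _, db = paralog_db
    assert search({"q": "WWWW"}, db, prefilter=False)["q"] == []


def test_sbh_transfers_only_from_best_hit(paralog_db):
    base, db = paralog_db
    hits = search({"q": base}, db, prefilter=False)
    ann = annotate_sbh(hits, db)["q"]
    assert ann.ko == "K00001" and ann.cog == "COG1"


def test_sbh_unlabeled_best_hit_means_unannotated():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list(AA), size=60))
    near = list(base)
    near[0] = "W" if near[0] != "W" else "Y"
    db = _db(
        {"best": base, "second": "".join(near)},
        taxid=[1, 1],
        ko=["", "K00009"],
    )
    hits = search({"q": base}, db, prefilter=False)
    assert hits["q"][0].subject_id == "best"
    assert annotate_sbh(hits, db)["q"].ko == ""


def test_sbh_bit_tie_breaks_to_smaller_subject_id():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list(AA), size=50))
    db = _db(
        {"b_copy": seq, "a_copy": seq}, taxid=[1, 1], ko=["K2", "K1"]
    )
    hits = search({"q": seq}, db, prefilter=False)
    assert hits["q"][0].subject_id == "a_copy"
    assert annotate_sbh(hits, db)["q"].ko == "K1"


def test_srv_is_one_for_verbatim_and_zero_for_no_hit(paralog_db):
    base, db = paralog_db
    hits = search({"q": base}, db, prefilter=False)
    assert srv(base, hits["q"]).srv == pytest.approx(1.0)
    assert srv(base, []).srv == 0.0


def test_srv_equals_hand_computed_bit_ratio(paralog_db):
    base, db = paralog_db
    homolog_hits = search({"q": base}, db.subset(["p80"]), prefilter=False)["q"]
    score = srv(base, homolog_hits).srv
    expect = (
        smith_waterman(base, db.seqs["p80"]).bit_score
        / smith_waterman(base, base).bit_score
    )
    assert 0.0 < score < 1.0
    assert score == pytest.approx(expect)


def test_srv_monotone_under_mutation_ladder():
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(list(AA), size=100))
    prev = 1.0
    seq = list(base)
    for _ in range(8):
        for _ in range(5):
            i = int(rng.integers(0, 100))
            seq[i] = str(rng.choice([c for c in AA if c != seq[i]]))
        db = _db({"h": "".join(seq)}, taxid=[1])
        hits = search({"q": base}, db, prefilter=False, max_evalue=1e9)["q"]
        score = srv(base, hits).srv if hits else 0.0
        assert score <= prev + 1e-12
        prev = score


def test_prefilter_does_not_change_strong_hits():
    rng = np.random.default_rng(6)
    seqs = {
        f"p{i:03d}": "".join(rng.choice(list(AA), size=60)) for i in range(60)
    }
    db = _db(seqs, taxid=[1] * 60)
    q = seqs["p007"]
    with_pf = search({"q": q}, db, prefilter=True)["q"]
    without = search({"q": q}, db, prefilter=False)["q"]
    assert with_pf[0].subject_id == without[0].subject_id == "p007"


def test_lump_cog_categories_fractions_and_split():
    from metatx.annotation import Annotation

    anns = {
        "o1": Annotation("o1", "s1", categories="J"),
        "o2": Annotation("o2", "s2", categories="J"),
        "o3": Annotation("o3", "s3", categories="K"),
        "o4": Annotation("o4", "s4", categories="KT"),
    }
    counts = {"o1": 200, "o2": 100, "o3": 100, "o4": 100}
    df = lump_cog_categories(counts, anns)
    by = dict(zip(df["category"], df["reads"]))
    assert by == {"J": 300, "K": 150, "T": 50}
    fr = dict(zip(df["category"], df["fraction"]))
    assert fr["J"] == pytest.approx(0.6)
    assert sum(fr.values()) == pytest.approx(1.0)


def test_lump_single_category_is_everything():
    from metatx.annotation import Annotation

    df = lump_cog_categories(
        {"o": 10}, {"o": Annotation("o", "s", categories="J")}
    )
    assert df["fraction"].tolist() == [1.0]
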