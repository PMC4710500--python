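"""Contig classification, read-level PR, profile correlation, coverage
curves and tetranucleotide signatures."""

import math

import numpy as np
import pytest

from metatx.assembler import Contig, revcomp
from metatx.evaluation import (
    classify_contigs,
    coverage_curve,
    functional_pr,
    profile_correlation,
    taxonomic_pr,
    tetranucleotide_regression,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def two_genomes():
    rng = np.random.default_rng(0)
    return {"orgA": _random_seq(rng, 20000), "orgB": _random_seq(rng, 20000)}


def test_exact_substring_contig_is_clean(two_genomes):
    contig = Contig("c1", two_genomes["orgA"][5000:5600])
    (cls,) = classify_contigs([contig], two_genomes)
    assert cls.cls == "clean_full_length"
    assert cls.best_ref == "orgA"


def test_reverse_complement_substring_is_clean(two_genomes):
    contig = Contig("c1", revcomp(two_genomes["orgB"][3000:3700]))
    (cls,) = classify_contigs([contig], two_genomes)
    assert cls.cls == "clean_full_length" and cls.best_ref == "orgB"


def test_constructed_chimera_is_flagged(two_genomes):
    contig = Contig(
        "c1", two_genomes["orgA"][1000:1300] + two_genomes["orgB"][8000:8300]
    )
    (cls,) = classify_contigs([contig], two_genomes)
    assert cls.cls == "chimeric"
    assert cls.n_ref_segments == 2


def test_random_contig_is_unaligned(two_genomes):
    rng = np.random.default_rng(1)
    (cls,) = classify_contigs([Contig("c1", _random_seq(rng, 500))], two_genomes)
    assert cls.cls == "unaligned"


def test_end_mismatches_are_distinguished_from_clean(two_genomes):
    rng = np.random.default_rng(2)
    core = two_genomes["orgA"][2000:2600]
    noisy = list(core)
    for i in list(range(0, 40)) + list(range(560, 600)):
        noisy[i] = "ACGT"[int(rng.integers(4))]
    (cls,) = classify_contigs([Contig("c1", "".join(noisy))], two_genomes)
    assert cls.cls == "end_mismatch"
    assert cls.best_ref == "orgA"


def test_functional_pr_hand_counted_example():
    """10 reads: 8 correct, 1 wrong, 1 unassigned -> P 8/9, R 8/10."""
    truth = {f"r{i}": "K1" for i in range(10)}
    predicted = {f"r{i}": "K1" for i in range(8)}
    predicted["r8"] = "K2"
    predicted["r9"] = None
    rep = functional_pr(truth, predicted)
    assert (rep.tp, rep.fp, rep.fn) == (8, 1, 2)
    assert rep.precision == pytest.approx(8 / 9)
    assert rep.recall == pytest.approx(0.8)


def test_functional_pr_all_correct():
    truth = {"a": "K1", "b": "K2"}
    rep = functional_pr(truth, dict(truth))
    assert rep.precision == rep.recall == 1.0


def test_functional_pr_rejects_label_leak():
    with pytest.raises(ValueError, match="not in truth"):
        functional_pr({"a": "K1"}, {"a": "K1", "ghost": "K9"})


def test_functional_pr_excludes_reads_without_truth_label():
    truth = {"a": "K1", "b": ""}
    rep = functional_pr(truth, {"a": "K1", "b": None})
    assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)


def test_taxonomic_pr_rank_semantics(toy_tree):
    """Truth at genus; prediction only at family level: TP at family,
    FN at genus."""
    truth = {"r1": 15}  # species under genus 14, family 13
    predicted = {"r1": 13}  # family-level call
    reps = taxonomic_pr(truth, predicted, toy_tree, ranks=("family", "genus"))
    assert (reps["family"].tp, reps["family"].fn) == (1, 0)
    assert (reps["genus"].tp, reps["genus"].fn) == (0, 1)


def test_taxonomic_pr_matches_brute_force_confusion(toy_tree):
    rng = np.random.default_rng(3)
    species = [15, 17, 25]
    choices = species + [13, 23, 2, None]
    truth = {f"r{i}": int(rng.choice(species)) for i in range(20)}
    predicted = {
        rid: (lambda c: None if c is None else int(c))(rng.choice(choices))
        for rid in truth
    }
    ranks = ("phylum", "order", "family", "genus")
    reps = taxonomic_pr(truth, predicted, toy_tree, ranks)
    for rank in ranks:
        tp = fp = fn = 0
        for rid, t in truth.items():
            t_anc = toy_tree.rank_ancestor(t, rank)
            if t_anc is None:
                continue
            p = predicted[rid]
            p_anc = toy_tree.rank_ancestor(p, rank) if p is not None else None
            if p_anc is None:
                fn += 1
            elif p_anc == t_anc:
                tp += 1
            else:
                fp += 1
                fn += 1
        assert (reps[rank].tp, reps[rank].fp, reps[rank].fn) == (tp, fp, fn)
        # tp + fn partitions the evaluable truth set; fp is a subset of fn
        n_evaluable = sum(
            toy_tree.rank_ancestor(t, rank) is not None for t in truth.values()
        )
        assert tp + fn == n_evaluable and fp <= fn


def test_profile_correlation_identity_and_antiorder():
    a = {"a": 1.0, "b": 2.0, "c": 3.0}
    assert profile_correlation(a, dict(a)) == pytest.approx(1.0)
    b = {"a": 3.0, "b": 2.0, "c": 1.0}
    assert profile_correlation(a, b, log_transform=False) == pytest.approx(-1.0)


def test_profile_correlation_matches_textbook_formula():
    rng = np.random.default_rng(4)
    keys = [f"K{i}" for i in range(40)]
    a = {k: float(rng.integers(0, 500)) for k in keys}
    b = {k: float(rng.integers(0, 500)) for k in keys[10:]}
    got = profile_correlation(a, b)
    union = sorted(set(a) | set(b))
    x = np.log10(np.array([a.get(k, 0.0) for k in union]) + 1)
    y = np.log10(np.array([b.get(k, 0.0) for k in union]) + 1)
    xc, yc = x - x.mean(), y - y.mean()
    expect = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    assert got == pytest.approx(expect, abs=1e-12)


def test_coverage_curve_threshold_detection():
    coverage = {}
    assembled = {}
    for i in range(10):
        coverage[f"lo{i}"] = 0.5
        assembled[f"lo{i}"] = False
        coverage[f"hi{i}"] = 10.0
        assembled[f"hi{i}"] = True
        coverage[f"mid{i}"] = 3.0
        assembled[f"mid{i}"] = i < 6  # 60% assembled at 3x
    curve = coverage_curve(coverage, assembled, bins=(0.5, 1, 2, 3, 5, 10), q=0.5)
    assert curve.fractions[0] == 0.0
    assert curve.fractions[-1] == 1.0
    assert curve.threshold == 3


def test_coverage_curve_all_assembled_threshold_is_first_bin():
    coverage = {f"g{i}": float(i + 1) for i in range(10)}
    assembled = {g: True for g in coverage}
    curve = coverage_curve(coverage, assembled, bins=(0.5, 2, 5), q=0.5)
    assert curve.threshold == 0.5


def test_tetranucleotide_self_regression_is_one():
    rng = np.random.default_rng(5)
    g = _random_seq(rng, 20000)
    assert tetranucleotide_regression(g, g) == pytest.approx(1.0)


def test_tetranucleotide_matches_direct_formula():
    from itertools import product

    rng = np.random.default_rng(6)
    a, b = _random_seq(rng, 15000), _random_seq(rng, 15000)
    got = tetranucleotide_regression(a, b)

    def freqs(seq):
        idx = {"".join(p): i for i, p in enumerate(product("ACGT", repeat=4))}
        v = np.zeros(256)
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - 3):
                v[idx[s[i : i + 4]]] += 1
        return v / v.sum()

    x, y = freqs(a), freqs(b)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
    assert got == pytest.approx(r * r, abs=1e-12)


def test_tetranucleotide_orders_relatedness():
    """A genome is more signature-similar to its lightly mutated copy
    than to an unrelated genome."""
    rng = np.random.default_rng(7)
    a = _random_seq(rng, 30000)
    mutated = list(a)
    for i in rng.choice(30000, size=300, replace=False):
        mutated[i] = "ACGT"[int(rng.integers(4))]
    unrelated = _random_seq(rng, 30000)
    assert tetranucleotide_regression(a, "".join(mutated)) > (
        tetranucleotide_regression(a, unrelated)
    )
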