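"""The filter cascade: rRNA screening, adapter discard, edge trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metatx import preprocess
from metatx.assembler import canonical, revcomp
from metatx.formats import SequenceRecord
from metatx.preprocess import (
    FilterConfig,
    filter_length,
    handle_adapters,
    run_filters,
    screen_rrna,
    trim_edges,
)


def _read(seq, rid="r", qual=38):
    return SequenceRecord(rid, seq, [qual] * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def rrna_ref():
    rng = np.random.default_rng(11)
    return _random_seq(rng, 1500)


def _brute_force_is_rrna(seq, refs, k, fraction):
    """Independent oracle: count k-mers (canonical) occurring anywhere in
    the references by substring search."""
    n = len(seq) - k + 1
    if n <= 0:
        return False
    hits = 0
    for i in range(n):
        kmer = seq[i : i + k]
        rc = revcomp(kmer)
        if any(kmer in ref or rc in ref for ref in refs):
            hits += 1
    return hits / n >= fraction


def test_exact_rrna_substring_is_screened(rrna_ref):
    read = _read(rrna_ref[100:175])
    mrna, rrna, _ = screen_rrna([read], [rrna_ref], k=31, fraction=0.5)
    assert len(rrna) == 1 and not mrna
    assert _brute_force_is_rrna(read.seq, [rrna_ref], 31, 0.5)


def test_reverse_complement_of_rrna_is_screened(rrna_ref):
    read = _read(revcomp(rrna_ref[400:475]))
    mrna, rrna, _ = screen_rrna([read], [rrna_ref], k=31, fraction=0.5)
    assert len(rrna) == 1


def test_random_read_is_kept_as_mrna(rrna_ref):
    rng = np.random.default_rng(5)
    read = _read(_random_seq(rng, 75))
    mrna, rrna, _ = screen_rrna([read], [rrna_ref], k=31, fraction=0.25)
    assert len(mrna) == 1 and not rrna


def test_read_shorter_than_k_is_kept_and_counted(rrna_ref):
    read = _read("ACGTACGT")
    mrna, rrna, n_short = screen_rrna([read], [rrna_ref], k=31, fraction=0.25)
    assert len(mrna) == 1 and n_short == 1


def test_screen_rrna_equals_brute_force_on_mixed_reads(rrna_ref):
    rng = np.random.default_rng(21)
    reads = []
    for i in range(300):
        if i % 3 == 0:
            start = int(rng.integers(0, len(rrna_ref) - 75))
            seq = rrna_ref[start : start + 75]
        elif i % 3 == 1:  # half rRNA, half random
            start = int(rng.integers(0, len(rrna_ref) - 40))
            seq = rrna_ref[start : start + 40] + _random_seq(rng, 35)
        else:
            seq = _random_seq(rng, 75)
        reads.append(_read(seq, rid=f"r{i}"))
    mrna, rrna, _ = screen_rrna(reads, [rrna_ref], k=31, fraction=0.25)
    flagged = {r.id for r in rrna}
    for read in reads:
        expect = _brute_force_is_rrna(read.seq, [rrna_ref], 31, 0.25)
        assert (read.id in flagged) == expect


ADAPTER = preprocess.DEFAULT_ADAPTER


def test_read_with_full_internal_adapter_is_discarded():
    rng = np.random.default_rng(2)
    seq = _random_seq(rng, 40) + ADAPTER + _random_seq(rng, 5)
    kept, n = handle_adapters([_read(seq)], FilterConfig())
    assert not kept and n == 1


def test_adapter_free_read_is_kept_unchanged():
    rng = np.random.default_rng(3)
    read = _read(_random_seq(rng, 75))
    kept, n = handle_adapters([read], FilterConfig())
    assert kept == [read] and n == 0


def test_suffix_prefix_overlap_is_detected():
    """A read ending in the adapter's first 12 nt with min_overlap=10 is
    discarded — the oracle scans every suffix/prefix overlap length."""
    rng = np.random.default_rng(4)
    seq = _random_seq(rng, 63) + ADAPTER[:12]
    config = FilterConfig(adapter_min_overlap=10)
    kept, n = handle_adapters([_read(seq)], config)
    assert n == 1
    found = any(
        sum(a != b for a, b in zip(seq[-ov:], ADAPTER[:ov])) <= 1
        for ov in range(10, min(len(ADAPTER), len(seq)) + 1)
    )
    assert found


def test_adapter_trim_mode_trims_at_match_start():
    rng = np.random.default_rng(6)
    prefix = _random_seq(rng, 40)
    seq = prefix + ADAPTER + "ACGTA"
    config = FilterConfig(drop_adapter_reads=False)
    kept, n = handle_adapters([_read(seq)], config)
    assert n == 0
    assert kept[0].seq == prefix


def test_quality_edge_trimming_keeps_interior():
    read = SequenceRecord("r", "ACGTT", [40, 40, 40, 2, 2])
    out = trim_edges(read, qual_threshold=30, polya_min_run=5)
    assert out.seq == "ACG" and out.qual == [40, 40, 40]


def test_polya_tail_is_removed():
    read = _read("ACGT" + "A" * 8)
    out = trim_edges(read, qual_threshold=30, polya_min_run=5)
    assert out.seq == "ACGT"


def test_leading_t_tail_is_removed():
    read = _read("T" * 6 + "GCGC")
    out = trim_edges(read, qual_threshold=30, polya_min_run=5)
    assert out.seq == "GCGC"


def test_clean_read_is_unchanged():
    read = _read("ACGTGCA")
    assert trim_edges(read, 30, 5) is read


def test_fully_trimmed_read_returns_none():
    read = SequenceRecord("r", "ACGT", [2, 2, 2, 2])
    assert trim_edges(read, 30, 5) is None


@settings(max_examples=60, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=80),
    st.lists(st.integers(0, 41), min_size=1, max_size=80),
)
def test_trim_edges_is_idempotent(seq, quals):
    quals = (quals * 80)[: len(seq)]
    read = SequenceRecord("r", seq, quals)
    once = trim_edges(read, 30, 5)
    if once is not None:
        twice = trim_edges(once, 30, 5)
        assert twice is not None
        assert twice.seq == once.seq and twice.qual == once.qual


def test_filter_length_boundary():
    reads = [_read("A" * 49, "a"), _read("C" * 50, "b")]
    kept = filter_length(reads, 50)
    assert [r.id for r in kept] == ["b"]
    assert filter_length([], 50) == []


def test_run_filters_conserves_every_read(rrna_ref):
    rng = np.random.default_rng(9)
    reads = []
    for i in range(200):
        kind = i % 4
        if kind == 0:
            start = int(rng.integers(0, len(rrna_ref) - 75))
            seq = rrna_ref[start : start + 75]
            reads.append(_read(seq, f"r{i}"))
        elif kind == 1:
            reads.append(_read(_random_seq(rng, 60) + ADAPTER[:15], f"r{i}"))
        elif kind == 2:
            reads.append(
                SequenceRecord(f"r{i}", _random_seq(rng, 75), [2] * 40 + [38] * 35)
            )
        else:
            reads.append(_read(_random_seq(rng, 75), f"r{i}"))
    clean, report = run_filters(reads, [rrna_ref])
    report.check()  # input = rrna + adapter + short + passed
    assert report.input == 200
    assert report.removed_rrna == 50
    assert report.removed_adapter >= 50  # all injected adapters found
    ids = {r.id for r in clean}
    assert len(ids) == len(clean) == report.passed


def test_run_filters_is_idempotent(rrna_ref):
    rng = np.random.default_rng(10)
    reads = [_read(_random_seq(rng, 75), f"r{i}") for i in range(100)]
    clean, _ = run_filters(reads, [rrna_ref])
    again, report = run_filters(clean, [rrna_ref])
    assert [(r.id, r.seq) for r in again] == [(r.id, r.seq) for r in clean]
    assert report.passed == report.input


def test_all_rrna_input_passes_nothing(rrna_ref):
    reads = [
        _read(rrna_ref[i : i + 75], f"r{i}") for i in range(0, 500, 50)
    ]
    clean, report = run_filters(reads, [rrna_ref])
    assert not clean
    assert report.removed_rrna == report.input
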