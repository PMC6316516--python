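"""Quality filtering, bisulfite-space matching and allele assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossmeth import (
    SimParams,
    assign_allele,
    assign_pair,
    bisulfite_mismatches,
    filter_mapping_error,
    quality_filter,
    simulate_reads,
    summarize_assignments,
)
from crossmeth.reads import (
    AMBIGUOUS,
    UNMAPPED,
    FastqRead,
    MappingSummary,
    ReadPairRecord,
    reverse_complement,
    trim_trailing,
)
from crossmeth.reference import CONTEXTS

from conftest import SEED

Q37 = chr(37 + 33)
Q12 = chr(12 + 33)


def _pair(seq1, qual1, seq2=None, qual2=None):
    r1 = FastqRead("r/1", seq1, qual1)
    r2 = FastqRead("r/2", seq2 or seq1, qual2 or qual1)
    return ReadPairRecord(r1, r2)


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------


def test_high_quality_read_unchanged():
    pair = _pair("A" * 150, Q37 * 150)
    kept, dropped = quality_filter([pair])
    assert dropped == 0
    assert kept[0].r1.sequence == "A" * 150


def test_trailing_low_quality_trimmed():
    pair = _pair("A" * 150, Q37 * 140 + Q12 * 10)
    kept, _ = quality_filter([pair])
    assert len(kept[0].r1) == 140


def test_short_after_trim_drops_both_mates():
    bad = _pair("A" * 150, Q37 * 90 + Q12 * 60)  # 90 < 100 after trim
    kept, dropped = quality_filter([bad])
    assert kept == [] and dropped == 1
    # one failing mate takes its partner with it
    mixed = ReadPairRecord(
        FastqRead("r/1", "A" * 150, Q37 * 150),
        FastqRead("r/2", "A" * 150, Q37 * 50 + Q12 * 100),
    )
    kept, dropped = quality_filter([mixed])
    assert kept == [] and dropped == 1


def test_interior_low_quality_not_trimmed():
    read = FastqRead("r", "A" * 10, Q37 * 3 + Q12 * 4 + Q37 * 3)
    assert len(trim_trailing(read, 20)) == 10


@given(
    qual=st.text(
        alphabet=st.characters(min_codepoint=33, max_codepoint=74), min_size=1, max_size=80
    )
)
@settings(max_examples=100, deadline=None)
def test_quality_filter_never_lengthens_reads(qual):
    read = FastqRead("r", "A" * len(qual), qual)
    assert len(trim_trailing(read, 20)) <= len(read)


# ---------------------------------------------------------------------------
# bisulfite-space mismatch counting
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref, read, expected",
    [
        ("ACGA", "ATGA", 0),  # C->T conversion tolerated
        ("ACGA", "ACAA", 1),  # G vs A is a real mismatch
        ("ACGA", "ACGA", 0),
        ("ACGA", "ACCA", 1),  # read C against ref G
        ("TTTT", "CCCC", 4),  # read C against ref T is NOT tolerated
    ],
)
def test_bisulfite_mismatches(ref, read, expected):
    assert bisulfite_mismatches(read, ref) == expected


def test_read_beyond_reference_rejected():
    with pytest.raises(ValueError):
        bisulfite_mismatches("ACGTA", "ACGT")
    with pytest.raises(ValueError):
        bisulfite_mismatches("AC", "ACGT", offset=3)


# ---------------------------------------------------------------------------
# allele assignment
# ---------------------------------------------------------------------------


def test_assign_perfect_col_read(toy_region):
    read = toy_region.col.sequence  # untreated read, 0 mismatches vs Col
    a = assign_allele(read, 0, toy_region)
    assert a.allele == "Col"
    assert a.mm_col == 0 and a.mm_ler == 1
    # observed bases recorded at the shared sites only
    assert set(a.site_bases) == {s.position for s in toy_region.shared_sites}


def test_assign_tie_is_ambiguous(toy_region):
    # mutate the informative SNP position to a base unlike either allele
    read = list(toy_region.col.sequence)
    read[5] = "T"  # Col has A, Ler has G at position 6
    a = assign_allele("".join(read), 0, toy_region)
    assert a.mm_col == a.mm_ler == 1
    assert a.allele == AMBIGUOUS and a.site_bases == {}


def test_assign_without_informative_snp_is_ambiguous(toy_region):
    # a read covering only positions 1..4 sees no SNP
    a = assign_allele(toy_region.col.sequence[:4], 0, toy_region)
    assert a.allele == AMBIGUOUS


def test_assign_unmapped_when_too_distant(toy_region):
    a = assign_allele("G" * 12, 0, toy_region, max_mismatch=5)
    assert a.allele == UNMAPPED


def test_disagreeing_mates_become_ambiguous(toy_region):
    r1 = FastqRead("x/1", toy_region.col.sequence, Q37 * 12)
    r2 = FastqRead("x/2", reverse_complement(toy_region.ler.sequence), Q37 * 12)
    a1, a2 = assign_pair(ReadPairRecord(r1, r2), [toy_region], max_mismatch=5)
    assert a1.allele == AMBIGUOUS and a2.allele == AMBIGUOUS


def test_error_free_simulated_reads_assign_perfectly(region1, rng):
    """With no sequencing error every simulated read lands on its true
    allele (oracle: the simulator's per-read truth)."""
    probs = {a: {m: 0.3 for m in CONTEXTS} for a in ("Col", "Ler")}
    params = SimParams(coverage=200, seq_error=0.0)
    pairs = simulate_reads("i", "CL", region1, probs, params, rng)
    for p in pairs:
        r1 = FastqRead("x/1", p.seq1, p.qual1)
        r2 = FastqRead("x/2", p.seq2, p.qual2)
        a1, a2 = assign_pair(ReadPairRecord(r1, r2), [region1])
        assert a1.allele == p.allele
        assert a2.allele == p.allele


# ---------------------------------------------------------------------------
# mapping-error rule
# ---------------------------------------------------------------------------


def _summary(n_col, n_ler):
    return MappingSummary("i", "r", n_col=n_col, n_ler=n_ler)


def test_minor_allele_below_threshold_discarded():
    s = filter_mapping_error(_summary(9900, 60))
    assert s.excluded_allele == "Ler"
    assert s.n_discarded == 60 and s.n_ler == 0
    assert s.n_col == 9900  # majority count never changes


def test_both_alleles_retained_above_threshold():
    s = filter_mapping_error(_summary(5000, 4800))
    assert s.excluded_allele is None and s.n_discarded == 0


def test_exact_threshold_boundary_is_retained():
    # fraction exactly 0.05 is not "smaller than" the threshold
    s = filter_mapping_error(_summary(950, 50))
    assert s.excluded_allele is None
    assert s.n_ler == 50


def test_zero_mapped_reads_fails_qc():
    s = filter_mapping_error(_summary(0, 0))
    assert s.failed_qc


def test_summarize_assignments_accounting(toy_region):
    reads = [
        assign_allele(toy_region.col.sequence, 0, toy_region),
        assign_allele(toy_region.ler.sequence, 0, toy_region),
        assign_allele("G" * 12, 0, toy_region),
    ]
    s = summarize_assignments("i", "toy", reads)
    assert (s.n_col, s.n_ler, s.n_unmapped) == (1, 1, 1)
    assert s.total_mapped == 2
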