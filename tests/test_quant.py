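"""Site counts, the weighted and fractional estimators, site-table ingestion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossmeth import (
    extract_calls,
    fractional_methylation,
    ingest_sitetable,
    methylation_levels,
    region_fractional_levels,
    weighted_methylation,
)
from crossmeth.reads import AssignedRead


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([(3, 1), (1, 3)], 0.5),
        ([(0, 5), (0, 7)], 0.0),
        ([(9, 1), (1, 1)], 10 / 12),  # coverage-weighted, not the site mean 0.7
        ([(4, 0)], 1.0),
    ],
)
def test_weighted_methylation_hand_values(counts, expected):
    assert weighted_methylation(counts) == pytest.approx(expected, abs=1e-15)


def test_weighted_methylation_undefined_on_zero_coverage():
    assert math.isnan(weighted_methylation([(0, 0), (0, 0)]))
    with pytest.raises(ValueError):
        weighted_methylation([(-1, 2)])


@pytest.mark.parametrize(
    "levels, expected",
    [
        ([1.0, 0.0], 0.5),
        ([0.9, 0.5], 0.7),  # counts (9,1),(1,1): per-site mean, not 10/12
        ([1.0], 1.0),
    ],
)
def test_fractional_methylation_hand_values(levels, expected):
    assert fractional_methylation(levels) == pytest.approx(expected, abs=1e-15)


def test_fractional_methylation_skips_nan_and_empty():
    assert fractional_methylation([0.5, float("nan")]) == 0.5
    assert math.isnan(fractional_methylation([]))


@given(
    per_site=st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=20
    )
)
@settings(max_examples=200, deadline=None)
def test_weighted_bounded_and_equals_fractional_under_uniform_coverage(per_site):
    w = weighted_methylation(per_site)
    if not math.isnan(w):
        assert 0.0 <= w <= 1.0
    # force identical coverage across sites: the two estimators coincide
    cov = 10
    uniform = [(c if c <= cov else cov, 0) for c, _ in per_site]
    uniform = [(c, cov - c) for c, _ in uniform]
    w_u = weighted_methylation(uniform)
    f_u = fractional_methylation([c / cov for c, _ in uniform])
    assert w_u == pytest.approx(f_u, abs=1e-12)


# ---------------------------------------------------------------------------
# extract_calls
# ---------------------------------------------------------------------------


def _read(allele, site_bases):
    return AssignedRead(
        read_id="r", mate=1, region_id="toy", allele=allele,
        mm_col=0, mm_ler=1, offset=0, site_bases=site_bases,
    )


def test_extract_calls_c_t_and_error_bases(toy_region):
    reads = [
        _read("Col", {2: "C", 9: "T"}),
        _read("Col", {2: "T", 9: "G"}),  # G is a sequencing-error observation
        _read("Ler", {2: "C"}),
        _read("ambiguous", {2: "C"}),  # excluded entirely
    ]
    counts = extract_calls(reads, toy_region.shared_sites, individual="i")
    col2 = counts[(counts["allele"] == "Col") & (counts["position"] == 2)].iloc[0]
    assert (col2["n_meth"], col2["n_unmeth"], col2["n_other"]) == (1, 1, 0)
    col9 = counts[(counts["allele"] == "Col") & (counts["position"] == 9)].iloc[0]
    assert (col9["n_meth"], col9["n_unmeth"], col9["n_other"]) == (0, 1, 1)
    assert counts[counts["allele"] == "Ler"]["n_meth"].sum() == 1
    # conservation: every observation lands in exactly one tally
    n_obs = sum(len(r.site_bases) for r in reads if r.allele in ("Col", "Ler"))
    assert int(counts[["n_meth", "n_unmeth", "n_other"]].to_numpy().sum()) == n_obs


def test_methylation_levels_long_format(toy_region):
    reads = [_read("Col", {2: "C", 9: "T"}), _read("Col", {2: "C", 9: "T"})]
    counts = extract_calls(reads, toy_region.shared_sites, individual="i")
    levels = methylation_levels(counts)
    cpg = levels[levels["motif"] == "CpG"].iloc[0]
    assert cpg["level"] == 1.0 and cpg["coverage"] == 2
    chg = levels[levels["motif"] == "CpHpG"].iloc[0]
    assert chg["level"] == 0.0


# ---------------------------------------------------------------------------
# external per-site tables
# ---------------------------------------------------------------------------


TOY_TABLE = """\
chrom\tpos\tcontext\tmeth\ttotal
Chr3\t16574340\tCpG\t2\t4
Chr3\t16574341\tCG\t1\t4
Chr3\t16574350\tCHG\t3\t4
Chr3\t16574351\tCHH\t0\t5
Chr3\t16574352\tCHH\t0\t0
Chr3\t16574000\tCpG\t9\t9
Chr5\t16574340\tCpG\t9\t9
"""


def test_ingest_sitetable_filters_and_fractional(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text(TOY_TABLE)
    table = ingest_sitetable(path, "Chr3", 16574335, 16574467)
    # two rows outside the span (wrong position / wrong chromosome) dropped
    assert len(table) == 5
    levels = region_fractional_levels(table)
    assert levels["CpG"] == pytest.approx((0.5 + 0.25) / 2)  # hand computation
    assert levels["CpHpG"] == pytest.approx(0.75)
    # zero-coverage CHH row is excluded from the mean
    assert levels["CpHpH"] == pytest.approx(0.0)


def test_ingest_sitetable_skips_malformed_and_keeps_last_duplicate(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text(
        "Chr3\t16574340\tCpG\t2\t4\n"
        "Chr3\tnot_a_number\tCpG\t1\t4\n"
        "Chr3\t16574340\tCpG\t4\t4\n"  # duplicate: last wins
    )
    table = ingest_sitetable(path, "Chr3", 16574335, 16574467)
    assert len(table) == 1
    assert table.iloc[0]["n_meth"] == 4


def test_ingest_sitetable_rejects_empty_span(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text("")
    with pytest.raises(ValueError):
        ingest_sitetable(path, "Chr3", 10, 5)
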