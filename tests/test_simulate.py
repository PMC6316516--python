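"""Pedigree, methylation-profile draws and read generation."""

import numpy as np
import pytest
from scipy import stats as sps

from crossmeth import (
    CrossDesign,
    MethylationProfile,
    Population,
    SimParams,
    default_design,
    default_profiles,
    draw_individual_profiles,
    simulate_pedigree,
    simulate_reads,
)
from crossmeth.reference import CONTEXTS
from crossmeth.simulate import ConfigError, beta_shapes

from conftest import SEED


def test_default_design_matches_study_sample_sizes():
    design = default_design()
    assert [p.n for p in design.populations] == [2, 2, 18, 19, 30, 28, 30, 30]
    assert design.n_individuals == 159


def test_design_validation():
    with pytest.raises(ConfigError):
        CrossDesign(populations=(Population("F2_x", "F2", 5, founder="nope"),))
    with pytest.raises(ConfigError):
        Population("p", "P", 0, strain="Col")


def test_pedigree_parents_and_f1_are_fixed(tiny_design):
    ped = simulate_pedigree(tiny_design, SEED)
    by_gen = ped.groupby("generation")["genotype"].unique()
    assert set(by_gen["F1"]) == {"CL"}
    parents = ped[ped["generation"] == "P"]
    assert list(parents["genotype"]) == ["CC", "LL"]


def test_pedigree_deterministic_under_seed(tiny_design):
    a = simulate_pedigree(tiny_design, SEED)
    b = simulate_pedigree(tiny_design, SEED)
    assert a.equals(b)


def test_f2_segregation_frequency():
    """CC frequency over 100,000 F2 draws sits within 3 binomial s.d.
    of the Mendelian 0.25."""
    design = CrossDesign(
        populations=(
            Population("F1_x", "F1", 1, maternal="Col"),
            Population("F2_big", "F2", 100_000, founder="F1_x"),
        )
    )
    ped = simulate_pedigree(design, SEED)
    f2 = ped[ped["generation"] == "F2"]["genotype"]
    frac_cc = (f2 == "CC").mean()
    assert abs(frac_cc - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 100_000)


def test_beta_shapes_roundtrip():
    a, b = beta_shapes(0.3, 0.1)
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    assert mean == pytest.approx(0.3)
    assert np.sqrt(var) == pytest.approx(0.1)
    with pytest.raises(ConfigError):
        beta_shapes(0.5, 0.6)  # sd incompatible with a beta law


def _single_group_profile(rho):
    levels = {
        ("F2_CL", allele, motif): (0.4, 0.15)
        for allele in ("Col", "Ler")
        for motif in CONTEXTS
    }
    return MethylationProfile("r", levels, rho={m: rho for m in CONTEXTS})


def test_near_point_mass_hyperparameters_collapse_draws():
    profile = MethylationProfile(
        "r",
        {("P", "Col", m): (0.3, None) for m in CONTEXTS},
        rho={m: 0.0 for m in CONTEXTS},
    )
    draws = draw_individual_profiles("P", ["CC"] * 200, profile, SEED)
    values = [d["Col"]["CpG"] for d in draws]
    assert np.std(values) < 0.02
    assert np.mean(values) == pytest.approx(0.3, abs=0.01)


@pytest.mark.parametrize("rho", [0.0, 0.9])
def test_heterozygote_coupling_rank_correlation(rho):
    """The Gaussian-copula draw reproduces the requested Spearman
    correlation: near 0 for rho=0, above 0.8 for rho=0.9."""
    profile = _single_group_profile(rho)
    draws = draw_individual_profiles("F2", ["CL"] * 10_000, profile, SEED)
    col = [d["Col"]["CpG"] for d in draws]
    ler = [d["Ler"]["CpG"] for d in draws]
    observed = sps.spearmanr(col, ler).statistic
    if rho == 0.0:
        assert abs(observed) < 0.03
    else:
        assert observed > 0.8


def test_complete_conversion_reads_every_c_as_t(region1, rng):
    probs = {"Col": {m: 0.0 for m in CONTEXTS}}
    params = SimParams(coverage=20, conversion_efficiency=1.0, seq_error=0.0)
    pairs = simulate_reads("i", "CC", region1, probs, params, rng)
    assert pairs
    for p in pairs:
        assert "C" not in p.seq1
        assert "G" not in p.seq2  # mate 2 is reverse-complemented


def test_complete_protection_keeps_every_shared_c(region1, rng):
    probs = {"Col": {m: 1.0 for m in CONTEXTS}}
    params = SimParams(
        coverage=20, conversion_efficiency=1.0, methylated_protection=1.0, seq_error=0.0
    )
    ref = region1.col.sequence
    pairs = simulate_reads("i", "CC", region1, probs, params, rng)
    for p in pairs:
        for site in region1.shared_sites:
            assert p.seq1[site.position - 1] == "C"
        # non-site positions untouched
        assert all(
            p.seq1[i] == ref[i] for i in range(len(p.seq1)) if ref[i] != "C"
        )


def test_heterozygote_allele_balance(region1, rng):
    """Fragments split binomial(n, 1/2) between alleles; the observed
    fraction stays within 3 s.d. at coverage 10^4."""
    probs = {a: {m: 0.5 for m in CONTEXTS} for a in ("Col", "Ler")}
    params = SimParams(coverage=10_000, seq_error=0.0)
    pairs = simulate_reads("i", "CL", region1, probs, params, rng)
    n = len(pairs)
    frac_col = sum(p.allele == "Col" for p in pairs) / n
    assert abs(frac_col - 0.5) < 3 * np.sqrt(0.25 / n)


def test_truncation_to_amplicon(region1, rng):
    probs = {"Col": {m: 0.0 for m in CONTEXTS}}
    params = SimParams(coverage=5, read_length=500)
    pairs = simulate_reads("i", "CC", region1, probs, params, rng)
    assert all(len(p.seq1) == region1.length for p in pairs)


def test_default_profiles_cover_all_groups():
    profiles = default_profiles()
    assert set(profiles) == {"region1", "region2"}
    for profile in profiles.values():
        groups = {g for g, _, _ in profile.levels}
        assert groups == {"P", "F1", "F2_CC", "F2_CL", "F2_LL"}
    assert profiles["region1"].rho == {"CpG": 0.57, "CpHpG": 0.75, "CpHpH": 0.97}


def test_sim_params_validation():
    with pytest.raises(ConfigError):
        SimParams(conversion_efficiency=1.2)
    with pytest.raises(ConfigError):
        SimParams(coverage=0)
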