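"""Inbreeding estimators: hand arithmetic, identities and null behaviour."""

import numpy as np
import pandas as pd
import pytest

from autozyg import (allele_frequencies, cohort_f_summary,
                     excess_homozygosity_by_maf, f_grm, f_roh, f_snp,
                     f_snp_outside_roh, inbreeding_profile)
from autozyg.genotypes import AlleleFrequencies
from autozyg.inbreeding import InbreedingProfile
from autozyg.roh import ROHSegment

from conftest import GENOME_BP, make_matrix


def _summary_row(kb_total, kb_lt5, kb_gt5):
    return pd.DataFrame({"sample_id": ["a"], "n_segments": [1],
                         "kb_total": [kb_total], "n_lt5": [0], "n_gt5": [0],
                         "kb_lt5": [kb_lt5], "kb_gt5": [kb_gt5]})


def test_f_roh_hand_arithmetic():
    """2.5 + 1.6 Mb of ROH over a 3 Gb genome."""
    out = f_roh(_summary_row(4100.0, 4100.0, 0.0), genome_size_bp=3e9)
    assert out["f_roh"][0] == pytest.approx(4.1e6 / 3e9)
    assert out["f_roh_lt5"][0] == pytest.approx(4.1e6 / 3e9)
    assert out["f_roh_gt5"][0] == 0.0
    out2 = f_roh(_summary_row(6000.0, 0.0, 6000.0), genome_size_bp=3e9)
    assert out2["f_roh"][0] == pytest.approx(0.002)
    assert out2["f_roh_gt5"][0] == pytest.approx(0.002)
    out3 = f_roh(_summary_row(0.0, 0.0, 0.0))
    assert float(out3[["f_roh", "f_roh_lt5", "f_roh_gt5"]].sum(axis=1)) == 0.0
    with pytest.raises(ValueError):
        f_roh(_summary_row(1.0, 1.0, 0.0), genome_size_bp=0)


def test_length_class_identity_every_sample(consang_profile):
    """The split into <5 Mb and >=5 Mb components is exact, not approximate."""
    _, _, prof = consang_profile
    t = prof.table
    np.testing.assert_array_equal(t["f_roh"].to_numpy(),
                                  (t["f_roh_lt5"] + t["f_roh_gt5"]).to_numpy())
    assert ((t["f_roh"] >= 0) & (t["f_roh"] <= 1)).all()
    with pytest.raises(ValueError):
        InbreedingProfile(pd.DataFrame({"f_roh": [0.3], "f_roh_lt5": [0.1],
                                        "f_roh_gt5": [0.1]}))


def test_f_snp_hand_arithmetic():
    """3 SNPs at p = 0.5: all-hom gives +1, all-het gives -1."""
    g = make_matrix([[2, 2, 0], [1, 1, 1], [0, 1, 2], [2, 1, 0]])
    freqs = AlleleFrequencies(np.full(3, 0.5), np.full(3, 4))
    vals = f_snp(g, freqs)
    assert vals[0] == pytest.approx((3 - 1.5) / (3 - 1.5))   # = 1
    assert vals[1] == pytest.approx((0 - 1.5) / 1.5)          # = -1


def test_f_snp_near_zero_under_random_mating(random_mating_cohort):
    g = random_mating_cohort.genotypes
    vals = f_snp(g)
    assert abs(np.nanmean(vals)) < 0.01


def test_f_snp_outside_roh_hand_arithmetic():
    """10 SNPs at p = 0.5, 4 inside ROH (hom), 4 of the 6 outside hom."""
    calls = np.array([[2, 2, 2, 2, 0, 0, 2, 2, 1, 1]], dtype=np.int8)
    pos = np.array([1_000_000 + i * 10_000 for i in range(4)] +
                   [8_000_000 + i * 10_000 for i in range(6)])
    g = make_matrix(calls, pos=pos)
    freqs = AlleleFrequencies(np.full(10, 0.5), np.full(10, 100))
    seg = [ROHSegment("S0", "1", 1_000_000, 1_030_000, 4)]
    val = f_snp_outside_roh(g, seg, freqs)
    # O' = 8-4 = 4, N' = 6, E' = (6/10)*5 = 3 -> (4-3)/(6-3) = 1/3
    assert val[0] == pytest.approx(1.0 / 3.0)


def test_f_snp_outside_roh_degenerate_cases():
    calls = np.array([[2, 0, 1, 2]], dtype=np.int8)
    g = make_matrix(calls)
    freqs = AlleleFrequencies(np.full(4, 0.5), np.full(4, 100))
    # no ROH: reduces exactly to f_snp
    assert f_snp_outside_roh(g, [], freqs)[0] == pytest.approx(f_snp(g, freqs)[0])
    # everything inside ROH: undefined
    seg = [ROHSegment("S0", "1", 1, 10_000, 4)]
    assert np.isnan(f_snp_outside_roh(g, seg, freqs)[0])


def test_outside_roh_approximates_f_snp_minus_f_roh(consang_profile):
    """The subtraction identity holds approximately on simulated cohorts."""
    _, _, prof = consang_profile
    t = prof.table
    resid = t["f_snp_outside_roh"] - (t["f_snp"] - t["f_roh"])
    assert np.nanmax(np.abs(resid)) < 0.05
    assert abs(np.nanmean(resid)) < 0.01


def test_f_grm_hand_arithmetic():
    freqs = AlleleFrequencies(np.array([0.5]), np.array([100]))
    assert f_grm(make_matrix([[2]]), freqs)[0] == pytest.approx(1.0)
    assert f_grm(make_matrix([[1]]), freqs)[0] == pytest.approx(-1.0)
    assert f_grm(make_matrix([[0]]), freqs)[0] == pytest.approx(1.0)


def test_f_grm_near_zero_under_random_mating(random_mating_cohort):
    vals = f_grm(random_mating_cohort.genotypes)
    assert abs(np.nanmean(vals)) < 0.01


def test_f_grm_requires_polymorphic_snps():
    g = make_matrix([[2, 2], [2, 2]])
    with pytest.raises(ValueError):
        f_grm(g)


@pytest.mark.parametrize("estimator", [f_snp, f_grm])
def test_allele_swap_invariance(estimator, random_mating_cohort):
    """Counting the other allele (x -> 2 - x, p -> 1 - p) changes nothing."""
    g = random_mating_cohort.genotypes
    calls2 = np.where(g.calls >= 0, 2 - g.calls, -1).astype(np.int8)
    g2 = make_matrix(calls2, pos=g.variant_map.pos_bp, chrom=g.variant_map.chrom,
                     sample_ids=g.samples.sample_id)
    np.testing.assert_allclose(estimator(g), estimator(g2), atol=1e-10)


def test_maf_bin_restriction_is_identity_on_full_range(random_mating_cohort):
    g = random_mating_cohort.genotypes
    fm = excess_homozygosity_by_maf(g, [(0.0, 0.5)])
    np.testing.assert_allclose(fm.iloc[:, 1].to_numpy(), f_snp(g), atol=1e-12)


def test_maf_bin_monomorphic_flagged():
    g = make_matrix([[2, 0], [2, 1], [2, 2]])   # first SNP monomorphic
    fm = excess_homozygosity_by_maf(g, [(0.4, 0.5)], freqs=AlleleFrequencies(
        np.array([1.0, 0.5]), np.array([3, 3])))
    assert not np.isnan(fm.iloc[:, 1]).all()
    fm2 = excess_homozygosity_by_maf(g, [(0.6, 0.9)])
    assert fm2.attrs["empty_bins"] == [(0.6, 0.9)]


def test_rare_homozygosity_loads_on_roh_common_on_grm(consang_cohort):
    """Bivariate decomposition: rare-SNP excess homozygosity follows F_ROH,
    common-SNP excess homozygosity follows the GRM estimator."""
    import statsmodels.api as sm
    from autozyg import call_roh, roh_sample_summary
    from autozyg.pipeline import cohort_config_from_dict
    from autozyg.simulate import simulate_cohort
    cfg = cohort_config_from_dict({
        "design": {"unrelated": 30, "first_cousin": 40, "full_sib": 20},
        "n_chrom": 20, "chrom_length_bp": 30_000_000, "snps_per_chrom": 1500,
        "maf_spectrum": ("beta", 0.5, 0.5)})
    b = simulate_cohort(cfg, seed=11)
    g = b.genotypes                      # unfiltered: rare SNPs retained
    segs = call_roh(g)                   # the caller applies its own MAF floor
    summary = roh_sample_summary(segs, g.samples.sample_id)
    prof = inbreeding_profile(g, segs, summary, GENOME_BP)
    t = prof.table
    fm = excess_homozygosity_by_maf(g, [(0.0, 0.05), (0.35, 0.5)])
    D = sm.add_constant(np.column_stack([t["f_roh"], t["f_grm"]]))
    rare = sm.OLS(fm.iloc[:, 1], D).fit().params
    common = sm.OLS(fm.iloc[:, 2], D).fit().params
    assert rare.iloc[1] > abs(rare.iloc[2])          # rare bin: F_ROH dominates
    assert common.iloc[2] > abs(common.iloc[1])      # common bin: F_GRM dominates


def test_cohort_summary_consanguinity_geometry(consang_profile):
    """In a consanguineous cohort mean F_ROH tracks F_IS (unity line)."""
    _, _, prof = consang_profile
    s = cohort_f_summary(prof)
    assert s["mean_f_roh"] == pytest.approx(s["f_is"], abs=0.02)


def test_cohort_summary_random_mating_null(random_mating_cohort):
    from autozyg import call_roh, qc_filter, roh_sample_summary
    g, _ = qc_filter(random_mating_cohort.genotypes)
    segs = call_roh(g)
    prof = inbreeding_profile(g, segs, roh_sample_summary(segs, g.samples.sample_id),
                              10 * 30_000_000)
    s = cohort_f_summary(prof)
    assert abs(s["f_is"]) < 0.02 and s["mean_f_roh"] < 0.02


def test_wahlund_pattern_in_admixed_pool():
    """Two merged subpopulations show F_IS > 0 without any ROH signal."""
    rng = np.random.default_rng(21)
    nv = 2000
    p1 = rng.uniform(0.1, 0.9, nv)
    p2 = np.clip(p1 + rng.choice([-0.35, 0.35], nv), 0.05, 0.95)
    calls = np.vstack([rng.binomial(2, p1, size=(100, nv)),
                       rng.binomial(2, p2, size=(100, nv))]).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 10**8), nv, replace=False))
    g = make_matrix(calls, pos=pos)
    vals = f_snp(g)
    assert np.nanmean(vals) > 0.02      # excess homozygosity from structure
    from autozyg import call_roh
    segs = call_roh(g)
    assert len(segs) == 0               # ...but no runs of homozygosity
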