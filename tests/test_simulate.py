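"""Properties of the synthetic cohort generator."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicemr.psi import compute_psi_table
from splicemr.simulate import (CovariateSpec, SimulationConfig, simulate_genotypes,
                               simulate_phenotypes, simulate_splicing,
                               simulate_summary_stats)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(maf_range=(0.05, 0.6))
    with pytest.raises(ValueError):
        SimulationConfig(cis_r2=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(ld_decay=1.0)
    # contradictory: no causal variants cannot explain positive cis variance
    with pytest.raises(ValueError):
        SimulationConfig(cis_r2=0.4, n_causal_variants_per_event=0)
    with pytest.raises(ValueError):
        SimulationConfig(cis_r2=0.0, n_causal_variants_per_event=2)


def test_seed_determinism():
    cfg = SimulationConfig(seed=5, n_families=30, n_events=2, variants_per_window=10)
    out = []
    for _ in range(2):
        panel, ped = simulate_genotypes(cfg)
        counts, truth = simulate_splicing(panel, cfg, pedigree=ped)
        pheno = simulate_phenotypes(truth, cfg)
        ss = simulate_summary_stats(cfg, n_gwas=500)
        out.append((panel.dosages, counts, pheno, ss))
    pd.testing.assert_frame_equal(out[0][0], out[1][0])
    pd.testing.assert_frame_equal(out[0][1], out[1][1])
    pd.testing.assert_frame_equal(out[0][2], out[1][2])
    pd.testing.assert_frame_equal(out[0][3], out[1][3])


def test_cohort_id_shares_architecture_not_individuals():
    """Same seed, different cohort_id: identical causal variants and
    effect sizes, independent genotype draws."""
    import dataclasses

    a_cfg = SimulationConfig(seed=5, n_families=50, offspring_range=(0, 0),
                             n_events=2, variants_per_window=10)
    b_cfg = dataclasses.replace(a_cfg, cohort_id=1)
    a_panel, a_ped = simulate_genotypes(a_cfg)
    b_panel, b_ped = simulate_genotypes(b_cfg)
    _ca, a_truth = simulate_splicing(a_panel, a_cfg, pedigree=a_ped)
    _cb, b_truth = simulate_splicing(b_panel, b_cfg, pedigree=b_ped)
    assert a_truth.causal_variants == b_truth.causal_variants
    assert a_truth.mu == b_truth.mu
    assert not a_panel.dosages.equals(b_panel.dosages)
    # gamma is rescaled on each cohort's empirical variance: close, not equal
    for event_id, g in a_truth.gamma.items():
        for key, val in g.items():
            assert np.sign(b_truth.gamma[event_id][key]) == np.sign(val)


def test_mendelian_transmission(family_cohort):
    """Child dosages are consistent with one allele from each parent."""
    panel = family_cohort["panel"]
    ped = family_cohort["pedigree"]
    d = panel.dosages
    kids = ped[ped["role"] == "offspring"]
    for _, row in kids.iterrows():
        dc = d.loc[row["sample_id"]].to_numpy()
        df_ = d.loc[row["father_id"]].to_numpy()
        dm = d.loc[row["mother_id"]].to_numpy()
        lo = (df_ == 2).astype(int) + (dm == 2).astype(int)
        hi = (df_ > 0).astype(int) + (dm > 0).astype(int)
        assert np.all(dc >= lo) and np.all(dc <= hi)


def test_no_ld_gives_uncorrelated_adjacent_variants():
    cfg = SimulationConfig(seed=9, n_families=1500, offspring_range=(0, 0),
                           n_events=1, variants_per_window=20, ld_decay=0.0,
                           cis_r2=0.0, n_causal_variants_per_event=0)
    panel, _ = simulate_genotypes(cfg)
    d = panel.dosages.to_numpy()
    r = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)]
    assert np.max(np.abs(r)) < 0.1


def test_ld_decay_induces_adjacent_correlation():
    cfg = SimulationConfig(seed=9, n_families=1500, offspring_range=(0, 0),
                           n_events=1, variants_per_window=20, ld_decay=0.8,
                           cis_r2=0.0, n_causal_variants_per_event=0)
    panel, _ = simulate_genotypes(cfg)
    d = panel.dosages.to_numpy()
    r = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)]
    assert np.median(r) > 0.3


def test_founder_hardy_weinberg():
    cfg = SimulationConfig(seed=13, n_families=2000, offspring_range=(0, 0),
                           n_events=1, variants_per_window=40,
                           cis_r2=0.0, n_causal_variants_per_event=0)
    panel, _ = simulate_genotypes(cfg)
    d = panel.dosages.to_numpy()
    pvals = []
    for j in range(d.shape[1]):
        n = d.shape[0]
        counts = np.array([(d[:, j] == g).sum() for g in (0, 1, 2)])
        q = d[:, j].mean() / 2
        expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        pvals.append(stats.chi2.sf(chi2, df=1))
    assert np.mean(np.asarray(pvals) < 0.01) < 0.1


def test_splicing_counts_and_psi_bounds(ref_cohort):
    counts = ref_cohort["counts"]
    truth = ref_cohort["truth"]
    assert (counts[["IJC", "SJC"]] >= 0).to_numpy().all()
    psi_true = truth.psi_true.to_numpy()
    assert np.all((psi_true > 0) & (psi_true < 1))


def test_fixed_depth_totals_and_deep_reads_recover_psi():
    cfg = SimulationConfig(seed=17, n_families=40, offspring_range=(0, 0),
                           n_events=2, variants_per_window=8,
                           read_depth_law=("fixed", 1_000_000))
    panel, ped = simulate_genotypes(cfg)
    counts, truth = simulate_splicing(panel, cfg, pedigree=ped)
    assert ((counts["IJC"] + counts["SJC"]) == 1_000_000).all()
    psi = compute_psi_table(counts, truth.events)
    diff = np.abs(psi.T.to_numpy() - truth.psi_true.to_numpy())
    assert np.nanmax(diff) < 0.01


def test_single_causal_variant_monotone_dosage_groups():
    cfg = SimulationConfig(seed=19, n_families=1000, offspring_range=(0, 0),
                           n_events=1, variants_per_window=10,
                           cis_r2=0.6, n_causal_variants_per_event=1)
    panel, ped = simulate_genotypes(cfg)
    _counts, truth = simulate_splicing(panel, cfg, pedigree=ped)
    event = truth.events[0].event_id
    key = truth.causal_variants[event][0]
    gamma = truth.gamma[event][key]
    x = panel.dosages[key]
    means = [truth.psi_true[event][x == g].mean() for g in (0, 1, 2)]
    if gamma < 0:
        means = means[::-1]
    assert means[0] < means[1] < means[2]


def test_null_cis_r2_no_dosage_correlation():
    cfg = SimulationConfig(seed=23, n_families=2000, offspring_range=(0, 0),
                           n_events=1, variants_per_window=10,
                           cis_r2=0.0, n_causal_variants_per_event=0)
    panel, ped = simulate_genotypes(cfg)
    _counts, truth = simulate_splicing(panel, cfg, pedigree=ped)
    psi_true = truth.psi_true.iloc[:, 0].to_numpy()
    r = [np.corrcoef(panel.dosages.iloc[:, j], psi_true)[0, 1]
         for j in range(panel.dosages.shape[1])]
    assert np.max(np.abs(r)) < 0.08


def test_binary_prevalence_matches_logistic_intercept():
    cfg = SimulationConfig(seed=29, n_families=3000, offspring_range=(0, 0),
                           n_events=1, variants_per_window=5,
                           cis_r2=0.0, n_causal_variants_per_event=0,
                           psi_effect_on_trait=0.0, trait_kind="binary",
                           trait_intercept=-2.0, family_effect_sd=0.0,
                           covariates=())
    panel, ped = simulate_genotypes(cfg)
    _c, truth = simulate_splicing(panel, cfg, pedigree=ped)
    pheno = simulate_phenotypes(truth, cfg)
    prevalence = pheno["trait"].mean()
    assert prevalence == pytest.approx(0.119, abs=0.02)


def test_family_effect_creates_within_family_correlation():
    cfg = SimulationConfig(seed=31, n_families=400, offspring_range=(2, 2),
                           n_events=1, variants_per_window=5,
                           cis_r2=0.0, n_causal_variants_per_event=0,
                           trait_kind="continuous", family_effect_sd=1.0,
                           psi_effect_on_trait=0.0, covariates=())
    panel, ped = simulate_genotypes(cfg)
    _c, truth = simulate_splicing(panel, cfg, pedigree=ped)
    pheno = simulate_phenotypes(truth, cfg)
    overall = pheno["trait"].mean()
    within_cov = []
    between = []
    for _, grp in pheno.groupby("family_id"):
        t = grp["trait"].to_numpy() - overall
        within_cov.append(np.mean([t[i] * t[j] for i in range(len(t))
                                   for j in range(i + 1, len(t))]))
        between.append(grp["trait"].mean())
    icc_proxy = np.mean(within_cov) / pheno["trait"].var()
    assert icc_proxy > 0.2


def test_summary_stats_null_and_linearity():
    base = dict(seed=37, n_families=50, offspring_range=(0, 0), n_events=1,
                variants_per_window=400, cis_r2=0.3,
                n_causal_variants_per_event=3, trait_kind="continuous")
    null = SimulationConfig(psi_effect_on_trait=0.0, **base)
    ss0 = simulate_summary_stats(null, n_gwas=4000)
    z = ss0["b"] / ss0["se"]
    assert np.mean(np.abs(z) > 3) < 0.01
    # with shared seed, b is exactly affine in the causal effect size
    ss1 = simulate_summary_stats(SimulationConfig(psi_effect_on_trait=1.0, **base), n_gwas=4000)
    ss2 = simulate_summary_stats(SimulationConfig(psi_effect_on_trait=2.0, **base), n_gwas=4000)
    resid = ss2["b"] - 2 * ss1["b"] + ss0["b"]
    assert np.max(np.abs(resid)) < 1e-10
    assert np.abs(ss1["b"] - ss0["b"]).max() > 0.005  # effect actually propagates


def test_summary_stats_se_scales_with_cohort_size():
    cfg = SimulationConfig(seed=41, n_families=50, offspring_range=(0, 0), n_events=1,
                           variants_per_window=50, cis_r2=0.3,
                           n_causal_variants_per_event=3, trait_kind="continuous")
    se_small = simulate_summary_stats(cfg, n_gwas=2000)["se"]
    se_large = simulate_summary_stats(cfg, n_gwas=8000)["se"]
    ratio = (se_large / se_small).mean()
    assert ratio == pytest.approx(0.5, abs=0.03)


def test_covariate_effect_shifts_trait():
    cfg = SimulationConfig(seed=43, n_families=2000, offspring_range=(0, 0),
                           n_events=1, variants_per_window=5,
                           cis_r2=0.0, n_causal_variants_per_event=0,
                           trait_kind="binary", family_effect_sd=0.0,
                           covariates=(CovariateSpec("sex", "binary", p=0.5, effect=1.0),))
    panel, ped = simulate_genotypes(cfg)
    _c, truth = simulate_splicing(panel, cfg, pedigree=ped)
    pheno = simulate_phenotypes(truth, cfg)
    p1 = pheno.loc[pheno["sex"] == 1, "trait"].mean()
    p0 = pheno.loc[pheno["sex"] == 0, "trait"].mean()
    assert p1 > p0 + 0.1
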