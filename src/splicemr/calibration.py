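"""Desk-scale simulation studies of each pipeline stage.

Every routine here builds its inputs with the synthetic-cohort generator,
runs the corresponding analysis stage end to end, and returns the summary
statistic(s) of interest (type-I error rates, recovery rates, agreement
with brute-force references).  The study sizes are chosen so each routine
runs in minutes on one core; the methods note records them.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import expression, gee, gsmr, models
from .psi import PsiMatrix, compute_psi_table, support_mask
from .simulate import (SimulationConfig, simulate_genotypes,
                       simulate_phenotypes, simulate_splicing, simulate_summary_stats)


def _seed_for(seed: int, label: str) -> int:
    """Stable per-study sub-seed below 2**31."""
    import zlib

    tag = zlib.crc32(label.encode()) % (2 ** 31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2 ** 31))


def _reference_panel_psi(config: SimulationConfig):
    """Simulate an unrelated reference panel and quantify PSI from counts."""
    panel, ped = simulate_genotypes(config)
    counts, truth = simulate_splicing(panel, config, pedigree=ped)
    psi = compute_psi_table(counts, truth.events)
    support = support_mask(counts, genotyped=panel.samples)
    return panel, PsiMatrix(psi=psi, support=support), truth


def loo_calibration(seed: int, n_events: int = 200, n_families: int = 200,
                    cis_r2: float = 0.0, n_causal: int = 0) -> dict:
    """LOO-test behavior of the cis-splicing models on simulated events.

    With ``cis_r2=0`` this measures the type-I rate of the one-sided LOO
    test at 0.05; with cis_r2 > 0 it measures power and R^2 recovery.
    Reference panels are unrelated (founders-only), n = 2 * n_families.
    """
    config = SimulationConfig(seed=seed, n_families=n_families, offspring_range=(0, 0),
                              n_events=n_events, variants_per_window=50,
                              cis_r2=cis_r2, n_causal_variants_per_event=n_causal)
    panel, psi, truth = _reference_panel_psi(config)
    pvals, r2s = [], []
    for ev in truth.events:
        sup = psi.support_samples(ev.event_id)
        cand = models.candidate_variants(panel, ev, sup)
        y = psi.psi.loc[ev.event_id, sup]
        ev_result = models.loo_cross_validate(cand, y)
        if ev_result.valid:
            pvals.append(ev_result.loo_p)
            r2s.append(ev_result.r_squared)
    pvals = np.asarray(pvals)
    return {
        "n_simulated": n_events,
        "n_events": int(pvals.size),  # events with an informative evaluation
        "rejection_rate_05": float(np.mean(pvals < 0.05)),
        "median_r2": float(np.median(r2s)),
        "pvalues": pvals,
    }


def gee_null_calibration(seed: int, n_events: int = 500, n_families: int = 1127) -> dict:
    """Type-I behavior of the family-clustered GEE association.

    One large family cohort (1127 families of about seven members,
    roughly 8000 subjects — the scale of family-based genetic studies of
    substance-use phenotypes), a binary trait with zero splicing effect
    but a real shared-family effect, and one association test per
    simulated event (each event's genetic PSI component as the exposure).
    Returns
    the empirical rejection rate at 0.05 and the KS uniformity p of the
    per-event p-values.
    """
    config = SimulationConfig(seed=seed, n_families=n_families, offspring_range=(3, 7),
                              n_events=n_events, variants_per_window=12,
                              cis_r2=0.4, n_causal_variants_per_event=3,
                              psi_effect_on_trait=0.0, trait_kind="binary",
                              family_effect_sd=0.5)
    panel, ped = simulate_genotypes(config)
    _counts, truth = simulate_splicing(panel, config, pedigree=ped)
    pheno = simulate_phenotypes(truth, config)
    pvals = []
    for event_id in truth.genetic_psi.columns:
        psihat = truth.genetic_psi[event_id]
        psihat.index = truth.genetic_psi.index
        try:
            res = gee.gee_associate(psihat, pheno, family="binomial-logit",
                                    covariates=["sex"], event_id=event_id)
            pvals.append(res.p)
        except gee.AssociationError:
            continue
    pvals = np.asarray(pvals)
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    return {"n_events": int(pvals.size),
            "type1_rate_05": float(np.mean(pvals < 0.05)),
            "ks_uniform_p": ks_p,
            "pvalues": pvals}


def gee_glm_singleton_agreement(seed: int, n_samples: int = 400) -> float:
    """Max |difference| between GEE and plain GLM logistic coefficients when
    every subject is their own family (GEE must reduce to the GLM)."""
    import statsmodels.api as sm

    config = SimulationConfig(seed=seed, n_families=n_samples // 2, offspring_range=(0, 0),
                              n_events=1, variants_per_window=20, cis_r2=0.4,
                              n_causal_variants_per_event=2, psi_effect_on_trait=2.0,
                              trait_kind="binary", family_effect_sd=0.0)
    panel, ped = simulate_genotypes(config)
    _counts, truth = simulate_splicing(panel, config, pedigree=ped)
    # singleton pedigree: each sample is its own family
    truth.families = pd.Series(truth.families.index, index=truth.families.index)
    pheno = simulate_phenotypes(truth, config)
    psihat = truth.genetic_psi.iloc[:, 0]
    res = gee.gee_associate(psihat, pheno, family="binomial-logit", covariates=["sex"])
    df = pheno.set_index("sample_id")
    exog = sm.add_constant(pd.DataFrame({"psihat": psihat.reindex(df.index),
                                         "sex": df["sex"]}).astype(float))
    glm = sm.GLM(df["trait"].astype(float), exog, family=sm.families.Binomial()).fit(tol=1e-12)
    return float(abs(res.beta - glm.params["psihat"]))


def gsmr_recovery(seed: int, n_reps: int = 50, beta_psi_y: float = 0.3,
                  n_families_train: int = 500, n_gwas: int = 200_000) -> dict:
    """Parameter recovery and null calibration of the summary-MR slope.

    Each replicate simulates an unrelated training panel (PSI measured
    from junction reads, per-variant splicing effects by covariate-free
    OLS) and an independent GWAS cohort sharing the generative parameters;
    instruments are kept independent (no LD) to match the estimator's
    working assumption.  Reports the fraction of replicates recovering the
    causal slope within +/-20% and the null fraction with p > 0.05.
    """
    within = []
    null_above = []
    for rep in range(n_reps):
        for effect, bucket in ((beta_psi_y, within), (0.0, null_above)):
            config = SimulationConfig(seed=_seed_for(seed, f"gsmr{rep}{effect}"),
                                      n_families=n_families_train, offspring_range=(0, 0),
                                      n_events=1, variants_per_window=20, ld_decay=0.0,
                                      cis_r2=0.4, n_causal_variants_per_event=3,
                                      psi_effect_on_trait=effect, trait_kind="continuous")
            panel, ped = simulate_genotypes(config)
            counts, truth = simulate_splicing(panel, config, pedigree=ped)
            psi = compute_psi_table(counts, truth.events).loc[truth.events[0].event_id]
            effects = gsmr.estimate_beta_x_psi(panel, psi)
            gwas = simulate_summary_stats(config, n_gwas=n_gwas)
            inst = gsmr.harmonize(effects, gwas)
            est = gsmr.gsmr_fit(inst)
            if effect == 0.0:
                bucket.append(est.p > 0.05)
            else:
                bucket.append(abs(est.beta_psi_y - beta_psi_y) <= 0.2 * abs(beta_psi_y))
    return {"n_reps": n_reps,
            "recovery_rate": float(np.mean(within)),
            "null_p_above_05_rate": float(np.mean(null_above))}


def simulate_de_counts(seed: int, n_genes: int = 2000, frac_de: float = 0.2,
                       fold: float = 2.0, dispersion: float = 0.1,
                       n_per_group: int = 100, direction: str = "balanced"):
    """NB count matrix with a known set of two-fold differential genes.

    Baseline means are log-uniform in [20, 500]; library depths vary
    2-fold across samples.  ``direction='balanced'`` splits the DE genes
    evenly between up and down in the high group (the standard design for
    FDR-control benchmarks, keeping library composition comparable);
    ``'up'`` makes them all up-regulated.  Returns (counts, groups,
    up_index, down_index).
    """
    rng = np.random.default_rng(seed)
    means = np.exp(rng.uniform(np.log(20), np.log(500), size=n_genes))
    n_de = int(n_genes * frac_de)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    if direction == "balanced":
        up_idx, down_idx = de_idx[:n_de // 2], de_idx[n_de // 2:]
    elif direction == "up":
        up_idx, down_idx = de_idx, np.array([], dtype=int)
    else:
        raise ValueError("direction must be 'balanced' or 'up'")
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    low = [f"L{i + 1:03d}" for i in range(n_per_group)]
    high = [f"H{i + 1:03d}" for i in range(n_per_group)]
    depth = rng.uniform(0.5, 2.0, size=2 * n_per_group)
    mu = np.tile(means[:, None], (1, 2 * n_per_group))
    mu[up_idx, n_per_group:] *= fold
    mu[down_idx, n_per_group:] /= fold
    mu *= depth[None, :]
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=low + high)
    groups = expression.StratifiedGroups(event_id="SIM", low=low, high=high, unused=[],
                                         low_cut=np.nan, high_cut=np.nan,
                                         min_group=min(50, n_per_group))
    return (counts, groups, pd.Index([genes[i] for i in up_idx]),
            pd.Index([genes[i] for i in down_idx]))


def de_power_study(seed: int, n_genes: int = 2000, n_per_group: int = 100,
                   direction: str = "balanced") -> dict:
    """Sensitivity, sign accuracy and realized false-discovery proportion
    of the DE stage on NB counts with 20% true two-fold genes."""
    counts, groups, up, down = simulate_de_counts(seed, n_genes=n_genes,
                                                  n_per_group=n_per_group,
                                                  direction=direction)
    true_de = up.union(down)
    kept = expression.filter_low_expression(counts, groups)
    res = expression.nb_differential_expression(counts.loc[kept], groups)
    hits = res.index[res["fdr"] < 0.05]
    true_in_kept = true_de.intersection(kept)
    tp = len(hits.intersection(true_de))
    sens = tp / len(true_in_kept) if len(true_in_kept) else float("nan")
    fdp = (len(hits) - tp) / len(hits) if len(hits) else 0.0
    sign_hits = hits.intersection(true_de)
    n_sign_ok = int((res.loc[sign_hits.intersection(up), "log2fc"] > 0).sum()
                    + (res.loc[sign_hits.intersection(down), "log2fc"] < 0).sum())
    sign_ok = n_sign_ok / len(sign_hits) if len(sign_hits) else float("nan")
    return {"n_genes_tested": int(len(kept)), "sensitivity": float(sens),
            "fdp": float(fdp), "sign_correct_rate": float(sign_ok)}


def bh_bruteforce_max_diff(seed: int, n_vectors: int = 1000, max_len: int = 50) -> float:
    """Max |difference| between bh_fdr and a literal step-up implementation
    over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.random(m)
        ours = gee.bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        adj = p[order] * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):  # enforce monotone non-decreasing
            adj[i] = min(adj[i], adj[i + 1])
        brute = np.empty(m)
        brute[order] = np.minimum(adj, 1.0)
        worst = max(worst, float(np.max(np.abs(ours - brute))))
    return worst


GSEA_EXAMPLE_METRIC = pd.Series(
    [5.0, 4.0, 3.0, 2.0, 1.0, 0.5, 0.4, 0.3, 0.2, 0.1],
    index=[f"g{i}" for i in range(1, 11)])
GSEA_EXAMPLE_SET = {"g2", "g5", "g8"}


def gsea_worked_example(n_perm: int = 200, seed: int = 0) -> dict:
    """ES of a ten-gene example set plus a fixed-seed reproducibility check."""
    res1 = expression.gsea(GSEA_EXAMPLE_METRIC, {"demo": GSEA_EXAMPLE_SET},
                           n_perm=n_perm, seed=seed)
    res2 = expression.gsea(GSEA_EXAMPLE_METRIC, {"demo": GSEA_EXAMPLE_SET},
                           n_perm=n_perm, seed=seed)
    return {"es": float(res1.loc["demo", "es"]),
            "p_reproducible": bool(res1.loc["demo", "p"] == res2.loc["demo", "p"])}
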