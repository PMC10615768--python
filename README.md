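# splicemr

Tools for asking whether the *cis*-genetically determined inclusion
level of a skipped exon causally influences a complex trait — the
TWAS/PrediXcan idea transplanted from gene expression to RNA splicing,
with family-cohort association and summary-statistics Mendelian
randomization (MR) on top.

The analysis chain, end to end:

1. **Quantify splicing.**  Percent spliced in per sample and event from
   junction reads, `Ψ = (I/L_I) / (I/L_I + S/L_S)`, with effective-length
   correction, support masks (genotyped, ≥10 junction reads) and event
   eligibility filters (≥2 cis SNVs, ≥100 support samples, IQR(Ψ) > 10%).
2. **Model the genetic component.**  Per event, an elastic net over the
   top-20 correlated SNVs in the transcribed region yields
   `Ψ̂ = α + Σ β_k X_k` (N ≤ 20); leave-one-out cross-validation gives
   Pearson r, a one-sided p for r > 0 and R², gated by Bonferroni over
   all evaluated events.
3. **Impute Ψ̂ into a cohort.**  Variant matching with allele
   harmonization (swapped alleles flipped, ambiguous palindromic SNVs
   dropped) and a ≥90% coverage gate.
4. **Test association under family structure.**  Generalized estimating
   equations with exchangeable within-family correlation and sandwich
   standard errors: binomial-logit for diagnoses, Poisson-log for symptom
   counts, Gaussian-log for continuous outcomes; BH FDR per phenotype and
   discovery → replication logic.
5. **Characterize downstream effects.**  Ψ̂ stratification, TMM
   normalization, negative-binomial differential expression,
   hypergeometric over-representation and permutation GSEA against
   user-supplied GMT gene sets.
6. **Summary-statistics MR.**  The causal effect β̂_Ψy as the
   (inverse-variance-weighted) least-squares slope of per-variant GWAS
   effects β_xy on per-variant splicing effects β_xΨ, through the origin.

A synthetic-cohort generator (`splicemr.simulate`) produces
family-structured genotypes with cis-LD, binomially sampled junction
counts with a controlled cis-genetic variance fraction, liability-scale
phenotypes and GWAS summary statistics — with full ground truth — so
every stage above is testable at desk scale.

## Worked example

Train splicing models on a simulated unrelated reference panel, impute
Ψ̂ into an independent family cohort drawn from the same splicing
architecture, and test the association with a binary trait:

```python
import dataclasses
from splicemr import (SimulationConfig, simulate_genotypes, simulate_splicing,
                      simulate_phenotypes, psi_matrix, filter_events,
                      train_events, impute_cohort, associate_events)

config = SimulationConfig(seed=42, n_families=150, offspring_range=(0, 0),
                          n_events=3, cis_r2=0.4, n_causal_variants_per_event=3)
panel, pedigree = simulate_genotypes(config)
counts, truth = simulate_splicing(panel, config, pedigree=pedigree)

psi = psi_matrix(counts, truth.events, genotyped=panel.samples)
eligible = filter_events(psi, truth.events, panel)
models, evals = train_events(panel, psi,
                             [e for e in truth.events if e.event_id in eligible])
for event_id, ev in evals.items():
    print(f"{event_id}: LOO r = {ev.loo_r:.3f}, one-sided p = {ev.loo_p:.2e}, "
          f"R^2 = {ev.r_squared:.3f}")

# an independent cohort (same architecture, different individuals) whose
# binary trait is driven by the genetic PSI component of the first event
cohort_cfg = dataclasses.replace(config, cohort_id=1, n_families=400,
                                 offspring_range=(1, 3),
                                 psi_effect_on_trait=6.0, trait_kind="binary")
cohort, cohort_ped = simulate_genotypes(cohort_cfg)
_, cohort_truth = simulate_splicing(cohort, cohort_cfg, pedigree=cohort_ped)
phenotypes = simulate_phenotypes(cohort_truth, cohort_cfg)

psihat, report = impute_cohort(models, cohort)
assoc = associate_events(psihat, phenotypes, family="binomial-logit",
                         covariates=["sex"])
print(assoc[["beta", "se", "p", "fdr"]].round(4))
```

Output:

```
EV0001: LOO r = 0.551, one-sided p = 1.43e-25, R^2 = 0.297
EV0002: LOO r = 0.667, one-sided p = 2.40e-40, R^2 = 0.431
EV0003: LOO r = 0.508, one-sided p = 2.05e-21, R^2 = 0.236
            beta      se       p     fdr
event_id
EV0001    5.4331  0.6327  0.0000  0.0000
EV0002    0.4655  0.4820  0.3341  0.5011
EV0003    0.2712  0.6028  0.6528  0.6528
```

All three events are strongly cis-regulated (LOO p ≪ the Bonferroni
cutoff; R² near the generative cis fraction of 0.4).  Only the first
event drives the simulated trait, and only it associates after
imputation: the GEE effect estimate 5.43 ± 0.63 on the liability scale
(true value 6; Ψ̂ is a noisy proxy for the genetic component, so some
attenuation is expected), while the two non-causal events are null.

The same pipeline is available from the shell:

```bash
splicemr simulate --config cfg.yaml --out cohort/
splicemr psi --counts cohort/junction_counts.tsv --events cohort/events.tsv --out psi.tsv
splicemr train --genotypes cohort/dosages.tsv --counts cohort/junction_counts.tsv \
               --events cohort/events.tsv --out models.json
splicemr impute --models models.json --genotypes cohort/dosages.tsv --out psihat.tsv
splicemr associate --psihat psihat.tsv --pheno cohort/phenotypes.tsv \
                   --ped cohort/pedigree.tsv --family binomial-logit \
                   --covars sex --out assoc.tsv
splicemr gsmr --genotypes cohort/dosages.tsv --psi psi.tsv --event EV0001 \
              --gwas cohort/gwas_summary.ma --out gsmr.tsv
```

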