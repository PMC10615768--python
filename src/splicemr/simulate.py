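"""Synthetic family cohorts with cis-regulated exon skipping.

The generator produces every input the analysis stages consume, with known
ground truth:

* diploid genotypes for nuclear families (two founders plus offspring by
  Mendelian transmission of whole parental haplotype windows), with
  first-order autoregressive LD among founder haplotypes within each
  event window;
* per-event splicing levels on the logit scale, ``logit(psi) = mu +
  sum_j gamma_j * dosage_j + noise`` with the genetic variance fraction
  pinned to ``cis_r2``, read out as binomial junction counts;
* phenotypes (binary liability / Poisson count / positive continuous)
  driven by the *genetic* component of PSI plus covariates and a shared
  family effect;
* per-variant GWAS summary statistics from an independent large cohort.

All randomness flows from ``SimulationConfig.seed`` through named child
streams, so each stage is reproducible in isolation.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .panel import GenotypePanel, make_variant_key
from .psi import SpliceEvent, DEFAULT_INCLUSION_LENGTH, DEFAULT_SKIP_LENGTH

logger = logging.getLogger(__name__)

_STREAMS = ("panel_params", "genotypes", "splicing_params", "splicing_noise",
            "reads", "phenotypes", "gwas_genotypes", "gwas_trait")


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate and its effect on the trait's linear predictor."""

    name: str
    kind: str = "binary"  # "binary" or "normal"
    p: float = 0.5
    mean: float = 0.0
    sd: float = 1.0
    effect: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``offspring_range`` gives the inclusive bounds on offspring per nuclear
    family; ``(0, 0)`` yields an unrelated (founders-only) panel, the shape
    of a transcriptomic reference cohort.  ``cis_r2`` is the fraction of
    logit-PSI variance explained by the causal cis variants;
    ``logit_psi_sd`` the total logit-scale standard deviation.
    ``psi_effect_on_trait`` acts on the centered genetic PSI component
    of the ``causal_event_index``-th event, on the liability (binary),
    log-rate (count) or log-mean (continuous) scale.

    Configs sharing ``seed`` but differing in ``cohort_id`` draw
    independent individuals under the same splicing architecture (same
    MAFs, causal variants and effect sizes) — use this to pair a training
    panel with an application cohort.
    """

    seed: int = 0
    cohort_id: int = 0
    n_families: int = 250
    offspring_range: tuple[int, int] = (1, 3)
    n_events: int = 20
    variants_per_window: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.7
    n_causal_variants_per_event: int = 3
    cis_r2: float = 0.4
    logit_psi_sd: float = 0.8
    read_depth_law: tuple[str, float] = ("poisson", 100.0)
    psi_effect_on_trait: float = 0.0
    trait_kind: str = "binary"
    trait_intercept: float | None = None
    family_effect_sd: float = 0.5
    continuous_noise_sd: float = 0.5
    causal_event_index: int = 0
    covariates: tuple[CovariateSpec, ...] = (CovariateSpec("sex", "binary", p=0.5, effect=0.2),)

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.cis_r2 < 1.0):
            raise ValueError("cis_r2 must be in [0, 1)")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        if self.offspring_range[0] < 0 or self.offspring_range[0] > self.offspring_range[1]:
            raise ValueError("offspring_range must be nonnegative and ordered")
        if self.trait_kind not in ("binary", "count", "continuous"):
            raise ValueError("trait_kind must be binary, count or continuous")
        if (self.cis_r2 == 0.0) != (self.n_causal_variants_per_event == 0):
            raise ValueError("cis_r2 == 0 requires n_causal_variants_per_event == 0 and vice versa")

    @property
    def intercept(self) -> float:
        if self.trait_intercept is not None:
            return self.trait_intercept
        return {"binary": 0.0, "count": float(np.log(2.0)), "continuous": 1.0}[self.trait_kind]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for downstream checks."""

    events: list[SpliceEvent]
    causal_variants: dict[str, list[str]]
    gamma: dict[str, dict[str, float]]          # event -> variant key -> logit-scale effect
    mu: dict[str, float]
    genetic_logit: pd.DataFrame                  # samples x events, centered genetic component
    genetic_psi: pd.DataFrame                    # samples x events, expit(mu + genetic)
    psi_true: pd.DataFrame                       # samples x events, with noise
    families: pd.Series                          # sample -> family
    realized_trait_effect: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "causal_variants": self.causal_variants,
            "gamma": self.gamma,
            "mu": self.mu,
            "families": self.families.to_dict(),
            "realized_trait_effect": self.realized_trait_effect,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


_SHARED_STREAMS = ("panel_params", "splicing_params")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Named RNG streams.

    The generative parameters (MAFs, causal variants, effect sizes) depend
    only on ``seed``; individual-level draws also key on ``cohort_id``, so
    two configs differing only in cohort_id describe independent cohorts
    with the same splicing architecture — the training-panel / GWAS-cohort
    relationship the imputation stage assumes.
    """
    streams = {}
    for idx, name in enumerate(_STREAMS):
        if name in _SHARED_STREAMS:
            ss = np.random.SeedSequence([config.seed, idx])
        else:
            ss = np.random.SeedSequence([config.seed, config.cohort_id + 101, idx])
        streams[name] = np.random.default_rng(ss)
    return streams


# ---------------------------------------------------------------------------
# genome layout

_WINDOW_SPACING = 1_000_000
_VARIANT_SPACING = 1_000


def event_annotations(config: SimulationConfig) -> list[SpliceEvent]:
    """Deterministic event/window layout implied by the config."""
    events = []
    v = config.variants_per_window
    for i in range(config.n_events):
        chrom = f"chr{(i % 22) + 1}"
        base = _WINDOW_SPACING * (1 + i // 22)
        start = base - 500
        end = base + (v - 1) * _VARIANT_SPACING + 500
        mid = base + (v // 2) * _VARIANT_SPACING
        events.append(SpliceEvent(
            event_id=f"EV{i + 1:04d}", host_gene=f"GENE{i + 1:04d}", chrom=chrom,
            strand="+", exon_start=mid + 100, exon_end=mid + 250,
            region_start=start, region_end=end,
            inclusion_length=DEFAULT_INCLUSION_LENGTH, skip_length=DEFAULT_SKIP_LENGTH,
        ))
    return events


def _window_variant_keys(config: SimulationConfig, event_index: int) -> list[str]:
    v = config.variants_per_window
    chrom = f"chr{(event_index % 22) + 1}"
    base = _WINDOW_SPACING * (1 + event_index // 22)
    # alternating non-palindromic allele pairs
    pairs = [("A", "G"), ("C", "T")]
    return [make_variant_key(chrom, base + j * _VARIANT_SPACING, *pairs[j % 2]) for j in range(v)]


def _draw_mafs(config: SimulationConfig) -> np.ndarray:
    rng = _streams(config)["panel_params"]
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_events * config.variants_per_window)


def _founder_haplotypes(rng: np.random.Generator, n_haps: int, mafs: np.ndarray,
                        ld: float, window_size: int) -> np.ndarray:
    """AR(1)-copula haplotypes; LD resets at window boundaries."""
    n_var = mafs.size
    thr = norm.ppf(mafs)
    haps = np.empty((n_haps, n_var), dtype=np.uint8)
    innov = rng.standard_normal((n_haps, n_var))
    carry = np.sqrt(1.0 - ld * ld)
    z = None
    for j in range(n_var):
        if j % window_size == 0 or ld == 0.0:
            z = innov[:, j]
        else:
            z = ld * z + carry * innov[:, j]
        col = (z < thr[j]).astype(np.uint8)
        # monomorphic draw: resample the column independently (LD broken, logged)
        tries = 0
        while col.min() == col.max() and tries < 20:
            col = (rng.standard_normal(n_haps) < thr[j]).astype(np.uint8)
            tries += 1
        if tries:
            logger.warning("variant column %d resampled %d time(s) after monomorphic draw", j, tries)
        haps[:, j] = col
    return haps


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    """Family-structured dosage panel plus pedigree table.

    Founder haplotypes are drawn per variant MAF with AR(1) LD inside each
    event window; each offspring receives one whole parental haplotype per
    window from each parent (no recombination within windows).
    """
    rng = _streams(config)["genotypes"]
    mafs = _draw_mafs(config)
    v = config.variants_per_window
    n_var = config.n_events * v
    n_founder_haps = 4 * config.n_families  # two diploid founders per family

    haps = _founder_haplotypes(rng, n_founder_haps, mafs, config.ld_decay, v)

    keys: list[str] = []
    for i in range(config.n_events):
        keys.extend(_window_variant_keys(config, i))

    lo_k, hi_k = config.offspring_range
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    ped_rows: list[dict] = []
    n_windows = config.n_events
    for f in range(config.n_families):
        fam = f"FAM{f + 1:04d}"
        fh = haps[4 * f:4 * f + 2]        # father's two haplotypes
        mh = haps[4 * f + 2:4 * f + 4]    # mother's two haplotypes
        father = f"{fam}_P1"
        mother = f"{fam}_P2"
        for sid, h in ((father, fh), (mother, mh)):
            sample_ids.append(sid)
            rows.append(h.sum(axis=0).astype(np.float64))
            ped_rows.append({"sample_id": sid, "family_id": fam, "role": "founder",
                             "father_id": "", "mother_id": ""})
        k = int(rng.integers(lo_k, hi_k + 1)) if hi_k > 0 else 0
        for c in range(k):
            sid = f"{fam}_O{c + 1}"
            pick_f = rng.integers(0, 2, size=n_windows)
            pick_m = rng.integers(0, 2, size=n_windows)
            hap_f = np.concatenate([fh[pick_f[w], w * v:(w + 1) * v] for w in range(n_windows)])
            hap_m = np.concatenate([mh[pick_m[w], w * v:(w + 1) * v] for w in range(n_windows)])
            sample_ids.append(sid)
            rows.append((hap_f + hap_m).astype(np.float64))
            ped_rows.append({"sample_id": sid, "family_id": fam, "role": "offspring",
                             "father_id": father, "mother_id": mother})

    dosages = pd.DataFrame(np.vstack(rows), index=pd.Index(sample_ids, name="sample_id"),
                           columns=keys)
    pedigree = pd.DataFrame(ped_rows)
    return GenotypePanel(dosages), pedigree


# ---------------------------------------------------------------------------
# splicing

def _event_params(config: SimulationConfig) -> list[dict]:
    """Per-event generative parameters, drawn once from a dedicated stream."""
    rng = _streams(config)["splicing_params"]
    params = []
    for i in range(config.n_events):
        mu = rng.uniform(-1.0, 1.0)
        n_causal = config.n_causal_variants_per_event
        idx = np.sort(rng.choice(config.variants_per_window, size=n_causal, replace=False)) \
            if n_causal > 0 else np.array([], dtype=int)
        gamma = rng.standard_normal(n_causal)
        params.append({"mu": mu, "causal_idx": idx, "gamma_raw": gamma})
    return params


def _read_depth(rng: np.random.Generator, law: tuple[str, float], shape) -> np.ndarray:
    kind, value = law
    if kind == "fixed":
        return np.full(shape, int(value), dtype=np.int64)
    if kind == "poisson":
        return rng.poisson(value, size=shape)
    raise ValueError(f"unknown read depth law {kind!r}")


def simulate_splicing(panel: GenotypePanel, config: SimulationConfig,
                      pedigree: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Junction counts and ground truth for every event in the layout.

    Returns a long table (event_id, sample_id, IJC, SJC) plus the
    :class:`SyntheticTruth`.  The genetic component per event is scaled so
    its sample variance is ``cis_r2 * logit_psi_sd**2``.
    """
    if config.cis_r2 == 0.0 and config.n_causal_variants_per_event > 0:
        raise ValueError("cis_r2 == 0 contradicts n_causal_variants_per_event > 0")
    streams = _streams(config)
    noise_rng, reads_rng = streams["splicing_noise"], streams["reads"]
    events = event_annotations(config)
    params = _event_params(config)
    v = config.variants_per_window
    n = panel.n_samples
    total_var = config.logit_psi_sd ** 2

    genetic = np.zeros((n, config.n_events))
    psi_true = np.empty((n, config.n_events))
    causal_variants: dict[str, list[str]] = {}
    gamma_out: dict[str, dict[str, float]] = {}
    mu_out: dict[str, float] = {}
    ijc = np.empty((n, config.n_events), dtype=np.int64)
    sjc = np.empty((n, config.n_events), dtype=np.int64)

    for i, ev in enumerate(events):
        p = params[i]
        keys = _window_variant_keys(config, i)
        mu_out[ev.event_id] = p["mu"]
        g = np.zeros(n)
        if p["causal_idx"].size:
            ck = [keys[j] for j in p["causal_idx"]]
            x = panel.dosages[ck].to_numpy()
            g_raw = (x - x.mean(axis=0)) @ p["gamma_raw"]
            sd_raw = g_raw.std()
            scale = np.sqrt(config.cis_r2 * total_var) / sd_raw if sd_raw > 0 else 0.0
            g = g_raw * scale
            causal_variants[ev.event_id] = ck
            gamma_out[ev.event_id] = {k: float(gr * scale) for k, gr in zip(ck, p["gamma_raw"])}
        else:
            causal_variants[ev.event_id] = []
            gamma_out[ev.event_id] = {}
        noise_sd = np.sqrt((1.0 - config.cis_r2) * total_var)
        e = noise_rng.standard_normal(n) * noise_sd
        lp = p["mu"] + g + e
        psi = expit(lp)
        psi_true[:, i] = psi
        genetic[:, i] = g

        total = _read_depth(reads_rng, config.read_depth_law, n)
        p_incl = psi * ev.inclusion_length / (psi * ev.inclusion_length + (1 - psi) * ev.skip_length)
        inc = reads_rng.binomial(total, p_incl)
        ijc[:, i] = inc
        sjc[:, i] = total - inc

    event_ids = [ev.event_id for ev in events]
    samples = panel.samples
    counts = pd.DataFrame({
        "event_id": np.repeat(event_ids, n),
        "sample_id": np.tile(samples.to_numpy(), config.n_events),
        "IJC": ijc.T.ravel(),
        "SJC": sjc.T.ravel(),
    })
    if pedigree is not None:
        families = pedigree.set_index("sample_id")["family_id"].reindex(samples)
    else:
        families = pd.Series(samples, index=samples, name="family_id")  # singletons
    genetic_df = pd.DataFrame(genetic, index=samples, columns=event_ids)
    mu_vec = np.array([mu_out[e] for e in event_ids])
    truth = SyntheticTruth(
        events=events, causal_variants=causal_variants, gamma=gamma_out, mu=mu_out,
        genetic_logit=genetic_df,
        genetic_psi=pd.DataFrame(expit(genetic + mu_vec[None, :]), index=samples, columns=event_ids),
        psi_true=pd.DataFrame(psi_true, index=samples, columns=event_ids),
        families=families,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(truth: SyntheticTruth, config: SimulationConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Phenotype/covariate table driven by the genetic PSI component.

    The exposure is the centered noise-free genetic PSI of the causal
    event; families share a Gaussian random effect on the linear predictor.
    ``seed`` overrides the config's phenotype stream, for replicate draws
    on a fixed cohort.
    """
    rng = _streams(config)["phenotypes"] if seed is None else np.random.default_rng(seed)
    samples = truth.genetic_psi.index
    n = len(samples)
    event_id = truth.events[config.causal_event_index].event_id
    exposure = truth.genetic_psi[event_id].to_numpy()
    exposure = exposure - exposure.mean()

    eta = np.full(n, config.intercept)
    eta += config.psi_effect_on_trait * exposure
    cov_cols: dict[str, np.ndarray] = {}
    for spec in config.covariates:
        if spec.kind == "binary":
            col = rng.binomial(1, spec.p, size=n).astype(float)
        elif spec.kind == "normal":
            col = rng.normal(spec.mean, spec.sd, size=n)
        else:
            raise ValueError(f"unknown covariate kind {spec.kind!r}")
        cov_cols[spec.name] = col
        eta += spec.effect * col
    fam_ids = truth.families.to_numpy()
    uniq = pd.unique(fam_ids)
    fam_eff = dict(zip(uniq, rng.normal(0.0, config.family_effect_sd, size=len(uniq))))
    eta += np.array([fam_eff[f] for f in fam_ids])

    if config.trait_kind == "binary":
        trait = rng.binomial(1, expit(eta)).astype(float)
    elif config.trait_kind == "count":
        trait = rng.poisson(np.exp(eta)).astype(float)
    else:
        trait = np.exp(eta) + rng.normal(0.0, config.continuous_noise_sd, size=n)
    truth.realized_trait_effect = config.psi_effect_on_trait
    out = pd.DataFrame({"sample_id": samples, "family_id": fam_ids, "trait": trait})
    for name, col in cov_cols.items():
        out[name] = col
    return out


# ---------------------------------------------------------------------------
# GWAS summary statistics

def simulate_summary_stats(config: SimulationConfig, n_gwas: int = 20_000) -> pd.DataFrame:
    """Per-variant marginal trait effects from an independent unrelated cohort.

    The cohort shares the causal event's generative parameters (MAFs, LD,
    causal variants, gamma) with the family cohort; the quantitative trait
    is ``psi_effect_on_trait * psi + N(0, 1)`` with psi the full (noisy)
    splicing level.  Output uses the COJO ``.ma`` dialect: SNP A1 A2 freq
    b se p N, with A1 the alternative (effect) allele.
    """
    streams = _streams(config)
    g_rng, t_rng = streams["gwas_genotypes"], streams["gwas_trait"]
    i = config.causal_event_index
    v = config.variants_per_window
    mafs = _draw_mafs(config)[i * v:(i + 1) * v]
    params = _event_params(config)[i]
    keys = _window_variant_keys(config, i)

    haps = _founder_haplotypes(g_rng, 2 * n_gwas, mafs, config.ld_decay, v)
    x = (haps[0::2].astype(np.float64) + haps[1::2].astype(np.float64))

    total_var = config.logit_psi_sd ** 2
    g = np.zeros(n_gwas)
    if params["causal_idx"].size:
        xc = x[:, params["causal_idx"]]
        g_raw = (xc - xc.mean(axis=0)) @ params["gamma_raw"]
        sd_raw = g_raw.std()
        if sd_raw > 0:
            g = g_raw * (np.sqrt(config.cis_r2 * total_var) / sd_raw)
    e = t_rng.standard_normal(n_gwas) * np.sqrt((1.0 - config.cis_r2) * total_var)
    psi = expit(params["mu"] + g + e)
    y = config.psi_effect_on_trait * (psi - psi.mean()) + t_rng.standard_normal(n_gwas)

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxy = xc.T @ yc
    b = sxy / sxx
    rss = (yc ** 2).sum() - b * sxy
    sigma2 = rss / (n_gwas - 2)
    se = np.sqrt(sigma2 / sxx)
    from scipy.stats import t as t_dist
    p = 2 * t_dist.sf(np.abs(b / se), df=n_gwas - 2)

    from .panel import parse_variant_key
    parsed = [parse_variant_key(k) for k in keys]
    return pd.DataFrame({
        "SNP": keys,
        "A1": [alt for _, _, _, alt in parsed],
        "A2": [ref for _, _, ref, _ in parsed],
        "freq": x.mean(axis=0) / 2.0,
        "b": b, "se": se, "p": p,
        "N": n_gwas,
    })


# ---------------------------------------------------------------------------
# writers

def write_cohort(outdir, panel: GenotypePanel, pedigree: pd.DataFrame,
                 counts: pd.DataFrame, truth: SyntheticTruth,
                 phenotypes: pd.DataFrame | None = None,
                 summary: pd.DataFrame | None = None) -> None:
    """Write a simulated cohort as plain-text files under ``outdir``."""
    from pathlib import Path
    from .annotation import write_event_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel.to_dosage_tsv(out / "dosages.tsv")
    panel.to_vcf(out / "genotypes.vcf")
    pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    counts.to_csv(out / "junction_counts.tsv", sep="\t", index=False)
    write_event_table(truth.events, out / "events.tsv")
    truth.to_json(out / "truth.json")
    if phenotypes is not None:
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if summary is not None:
        summary.to_csv(out / "gwas_summary.ma", sep="\t", index=False)
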