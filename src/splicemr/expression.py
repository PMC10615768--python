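"""Downstream expression analysis for a replicated splicing event.

Samples are stratified into low / high groups of the genetically
determined splicing level psi_hat; genes are filtered for low expression
(<= 1 CPM in more than half of the smaller group), normalized by trimmed
mean of M-values (TMM), and tested for differential expression with a
negative-binomial log-linear model (group + covariates, offsets of
log(library size x TMM factor), tagwise dispersion shrunk toward a
mean-dispersion trend, likelihood-ratio p, BH FDR).  Enrichment of the
resulting gene lists against user-supplied gene sets is provided both as
over-representation (hypergeometric) and as a weighted Kolmogorov-Smirnov
running-sum GSEA with a gene-permutation null.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gee import bh_fdr

logger = logging.getLogger(__name__)

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


# ---------------------------------------------------------------------------
# stratification

@dataclass
class StratifiedGroups:
    """Low/high psi_hat sample groups for one event."""

    event_id: str
    low: list[str]
    high: list[str]
    unused: list[str]
    low_cut: float
    high_cut: float
    min_group: int

    @property
    def n1(self) -> int:
        return len(self.low)

    @property
    def n2(self) -> int:
        return len(self.high)

    @property
    def analyzable(self) -> bool:
        return self.n1 >= self.min_group and self.n2 >= self.min_group


def stratify_by_psihat(psihat: pd.Series, low_q: float = 1 / 3, high_q: float = 2 / 3,
                       min_group: int = 50, cutoffs: tuple[float, float] | None = None,
                       event_id: str = "") -> StratifiedGroups:
    """Split samples at psi_hat quantiles (or explicit cutoffs).

    low = {psi_hat < low cut}, high = {psi_hat > high cut}; samples tied at
    a cut fall in the unused middle.  When either group is smaller than
    ``min_group`` the event is unanalyzable — the behavior of heavily
    centered psi_hat distributions, where most samples share near-identical
    predicted values.
    """
    s = psihat.dropna()
    if cutoffs is not None:
        low_cut, high_cut = cutoffs
    else:
        low_cut, high_cut = np.quantile(s.to_numpy(), [low_q, high_q])
    low = list(s.index[s < low_cut])
    high = list(s.index[s > high_cut])
    unused = list(s.index[(s >= low_cut) & (s <= high_cut)])
    groups = StratifiedGroups(event_id=event_id, low=low, high=high, unused=unused,
                              low_cut=float(low_cut), high_cut=float(high_cut),
                              min_group=min_group)
    if not groups.analyzable:
        logger.warning("%s: stratification left groups of %d/%d (< %d); unanalyzable",
                       event_id or "event", groups.n1, groups.n2, min_group)
    return groups


# ---------------------------------------------------------------------------
# expression filtering and TMM normalization

def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return counts / library_sizes * 1e6


def filter_low_expression(counts: pd.DataFrame, groups: StratifiedGroups,
                          cpm_threshold: float = 1.0,
                          gene_chrom: pd.Series | None = None) -> pd.Index:
    """Genes retained for DE analysis.

    A gene is removed iff its CPM is <= ``cpm_threshold`` in *more than*
    N = min(n1, n2) / 2 of the group samples.  When ``gene_chrom`` is
    given, non-autosomal genes are removed first.  Samples with zero
    library size are excluded with a log message.
    """
    samples = [s for s in groups.low + groups.high if s in counts.columns]
    sub = counts[samples]
    lib = sub.sum(axis=0)
    empty = lib.index[lib == 0]
    if len(empty):
        logger.warning("excluding %d sample(s) with zero library size", len(empty))
        sub = sub.drop(columns=empty)
        lib = lib.drop(empty)
    genes = counts.index
    if gene_chrom is not None:
        genes = genes[[str(gene_chrom.get(g)) in AUTOSOMES for g in genes]]
    n_cap = min(groups.n1, groups.n2) / 2.0
    low_cpm = (cpm(sub.loc[genes], lib) <= cpm_threshold).sum(axis=1)
    return genes[low_cpm <= n_cap]


def tmm_normalize(counts: pd.DataFrame, logratio_trim: float = 0.30,
                  sum_trim: float = 0.05, ref_column: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Follows the standard TMM recipe: the reference sample is the one whose
    upper-quartile CPM is closest to the mean upper quartile; per sample,
    M (log2 expression ratio) and A (average log2 abundance) values over
    genes expressed in both are doubly trimmed (30% on M, 5% on A) and the
    factor is the precision-weighted mean of the surviving M values.
    Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    rates = counts.div(lib, axis=1)
    if ref_column is None:
        f75 = rates.quantile(0.75, axis=0)
        ref_column = (f75 - f75.mean()).abs().idxmin()
    ref = counts[ref_column].to_numpy(dtype=float)
    ref_lib = float(lib[ref_column])

    factors = {}
    for col in counts.columns:
        x = counts[col].to_numpy(dtype=float)
        x_lib = float(lib[col])
        ok = (x > 0) & (ref > 0)
        if not ok.any():
            logger.warning("sample %s shares no expressed genes with the reference; factor set to 1", col)
            factors[col] = 1.0
            continue
        xr, rr = x[ok] / x_lib, ref[ok] / ref_lib
        m = np.log2(xr / rr)
        a = 0.5 * np.log2(xr * rr)
        w = (x_lib - x[ok]) / (x_lib * x[ok]) + (ref_lib - ref[ok]) / (ref_lib * ref[ok])
        if np.max(np.abs(m)) < 1e-6:
            factors[col] = 1.0
            continue
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            factors[col] = 1.0
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[col] = float(2.0 ** f) if np.isfinite(f) else 1.0
    out = pd.Series(factors)
    out /= np.exp(np.mean(np.log(out)))
    return out


# ---------------------------------------------------------------------------
# negative-binomial differential expression

def _estimate_dispersions(y: np.ndarray, design: np.ndarray, offset: np.ndarray,
                          prior_df: float = 10.0) -> np.ndarray:
    """Tagwise NB dispersions shrunk toward a mean-dispersion trend.

    Per gene a Poisson GLM supplies fitted means; the moment estimator of
    the dispersion (df-adjusted Pearson-type) is computed, a lowess trend
    of log dispersion on log mean abundance is fit across genes, and each
    tagwise value is shrunk toward the trend with weight
    resid_df / (resid_df + prior_df).
    """
    n_genes, n_samples = y.shape
    p = design.shape[1]
    resid_df = n_samples - p
    disp = np.empty(n_genes)
    means = np.empty(n_genes)
    for g in range(n_genes):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y[g], design, family=sm.families.Poisson(), offset=offset).fit()
        mu = fit.fittedvalues
        means[g] = mu.mean()
        num = np.sum((y[g] - mu) ** 2) * n_samples / resid_df - np.sum(mu)
        disp[g] = max(num / np.sum(mu ** 2), 1e-6)
    log_disp = np.log(disp)
    log_mean = np.log(means + 1e-8)
    trend = sm.nonparametric.lowess(log_disp, log_mean, frac=0.5, return_sorted=False)
    w = resid_df / (resid_df + prior_df)
    return np.exp(w * log_disp + (1.0 - w) * trend)


def nb_differential_expression(counts: pd.DataFrame, groups: StratifiedGroups,
                               covariates: pd.DataFrame | None = None,
                               norm_factors: pd.Series | None = None,
                               prior_df: float = 10.0) -> pd.DataFrame:
    """Gene-level NB log-linear test of high vs low psi_hat groups.

    ``counts`` should already be filtered (see
    :func:`filter_low_expression`).  Returns a frame with log2 fold-change
    (high over low), likelihood-ratio p and BH FDR; genes whose fit fails
    get NaN p and are excluded from the FDR family.
    """
    if not groups.analyzable:
        raise ValueError(f"{groups.event_id or 'event'} is unanalyzable: "
                         f"groups of {groups.n1}/{groups.n2} below {groups.min_group}")
    samples = [s for s in groups.low + groups.high if s in counts.columns]
    sub = counts[samples]
    lib = sub.sum(axis=0).astype(float)
    if norm_factors is None:
        norm_factors = tmm_normalize(sub)
    offset = np.log(lib.to_numpy() * norm_factors.reindex(samples).to_numpy())
    group_ind = np.array([1.0 if s in set(groups.high) else 0.0 for s in samples])
    cols = [np.ones(len(samples)), group_ind]
    if covariates is not None:
        cov = covariates.reindex(samples)
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
    design = np.column_stack(cols)
    reduced = np.delete(design, 1, axis=1)
    y = sub.to_numpy(dtype=float)

    disp = _estimate_dispersions(y, design, offset, prior_df=prior_df)
    rows = []
    for g, gene in enumerate(sub.index):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.NegativeBinomial(alpha=float(disp[g]))
                full = sm.GLM(y[g], design, family=fam, offset=offset).fit()
                null = sm.GLM(y[g], reduced, family=fam, offset=offset).fit()
            lr = 2.0 * (full.llf - null.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            log2fc = float(full.params[1] / np.log(2.0))
        except Exception as exc:
            logger.warning("gene %s: NB fit failed (%s); excluded from FDR", gene, exc)
            p, log2fc = np.nan, np.nan
        rows.append({"gene_id": gene, "log2fc": log2fc, "p": p, "dispersion": float(disp[g])})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora_enrichment(de_genes: set[str], universe: set[str],
                   gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of DE genes in each set.

    p is the upper tail of drawing at least the observed overlap when
    sampling len(de_genes) genes from the universe; sets with no member in
    the universe are skipped.
    """
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    n_universe = len(universe)
    n_de = len(de_genes)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = in_universe & de_genes
        k, big_k = len(overlap), len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_de))
        rows.append({"set": name, "overlap": k, "set_size": big_k,
                     "gene_ratio": k / n_de if n_de else 0.0, "p": p,
                     "genes": ",".join(sorted(overlap))})
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["overlap", "set_size", "gene_ratio", "p", "genes"])
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def _running_es(hit_pos: np.ndarray, hit_weight: np.ndarray, n_genes: int) -> tuple[float, int]:
    """Enrichment score and extremum index from sorted hit positions.

    The running sum increases by weight/sum(weights) at each set member and
    decreases by 1/(N - Nh) per non-member; its extremes occur at member
    positions, so only those are evaluated.
    """
    nh = hit_pos.size
    total_w = hit_weight.sum()
    if total_w == 0:  # all-zero metric inside the set: fall back to equal weights
        hit_weight = np.ones(nh)
        total_w = float(nh)
    miss_step = 1.0 / (n_genes - nh)
    cum_w = np.cumsum(hit_weight) / total_w
    k = np.arange(1, nh + 1)
    top = cum_w - (hit_pos + 1 - k) * miss_step          # just after each hit
    bottom = np.concatenate(([0.0], cum_w[:-1])) - (hit_pos - (k - 1)) * miss_step  # just before
    i_top = int(np.argmax(top))
    i_bot = int(np.argmin(bottom))
    if top[i_top] >= -bottom[i_bot]:
        return float(top[i_top]), i_top
    return float(bottom[i_bot]), i_bot


def gsea(ranked: pd.Series, gene_sets: dict[str, set[str]], n_perm: int = 1000,
         seed: int = 0, weight: float = 1.0, min_size: int = 3,
         max_size: int = 500) -> pd.DataFrame:
    """Weighted KS running-sum GSEA with a gene-permutation null.

    ``ranked`` maps gene -> ranking metric (e.g. log2 fold-change); genes
    are ordered by decreasing metric.  ES is the signed maximal deviation
    of the running sum with member increments |metric|^weight; NES divides
    by the mean |null ES| of the same sign and p is the one-sided
    permutation tail.  Leading edge: members at or before (after, for
    negative ES) the extremum.
    """
    if not np.all(np.isfinite(ranked.to_numpy(dtype=float))):
        raise ValueError("ranking metric must be finite")
    order = ranked.sort_values(ascending=False, kind="mergesort")
    # deterministic tie-break on gene name
    order = order.iloc[np.lexsort((order.index.to_numpy(), -order.to_numpy()))]
    genes = order.index.to_numpy()
    metric = np.abs(order.to_numpy(dtype=float)) ** weight
    n_genes = genes.size
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        hit_pos = np.sort([pos_of[g] for g in members if g in pos_of])
        nh = hit_pos.size
        if nh < min_size or nh > max_size or nh >= n_genes:
            continue
        es, ext_i = _running_es(hit_pos, metric[hit_pos], n_genes)
        # gene-permutation null: same-size random member sets
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.sort(rng.choice(n_genes, size=nh, replace=False))
            null_es[b], _ = _running_es(perm, metric[perm], n_genes)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same:
            p = (1 + int(np.sum(np.abs(null_es[same_sign]) >= abs(es)))) / (1 + n_same)
            mean_same = float(np.mean(np.abs(null_es[same_sign])))
            nes = es / mean_same if mean_same > 0 else np.nan
        else:
            p, nes = 1.0, np.nan
        if es >= 0:
            leading = [genes[i] for i in hit_pos[:ext_i + 1]]
        else:
            leading = [genes[i] for i in hit_pos[ext_i:]]
        rows.append({"set": name, "es": es, "nes": nes, "p": p, "size": nh,
                     "leading_edge": ",".join(leading)})
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["es", "nes", "p", "size", "leading_edge"])
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out
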