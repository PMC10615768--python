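"""Summary-statistics Mendelian randomization for splicing (GSMR-style).

Per-variant effects on the splicing level (beta_x_psi, from individual
level reference data) are co-localized with per-variant GWAS effects on
the trait (beta_xy); under the MR model beta_xy = beta_psi_y * beta_x_psi,
so the causal effect is estimated as the least-squares slope of beta_xy
on beta_x_psi through the origin, by default inverse-variance weighted by
the GWAS standard errors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, is_palindromic, parse_variant_key

logger = logging.getLogger(__name__)


@dataclass
class GsmrEstimate:
    beta_psi_y: float
    se: float
    p: float
    n_instruments: int
    weighting: str

    def __post_init__(self):
        if self.n_instruments < 2:
            raise ValueError("GSMR needs at least 2 instruments")


class WeakInstrumentError(RuntimeError):
    pass


def estimate_beta_x_psi(panel: GenotypePanel, psi: pd.Series,
                        covariates: pd.DataFrame | None = None,
                        collinear_tol: float = 1e-8) -> pd.DataFrame:
    """Per-variant OLS slope of psi on dosage, covariate adjusted.

    Covariates are projected out of both psi and each dosage
    (Frisch-Waugh), giving the same slope and standard error as the joint
    OLS fit.  Monomorphic variants are skipped; variants whose dosage is
    (numerically) explained by the covariates are flagged collinear.
    """
    common = psi.dropna().index.intersection(panel.samples)
    y = psi.loc[common].to_numpy(dtype=float)
    x = panel.dosages.loc[common].to_numpy(dtype=float)
    n = len(common)
    if covariates is not None:
        c = covariates.reindex(common).to_numpy(dtype=float)
        z = np.column_stack([np.ones(n), c])
    else:
        z = np.ones((n, 1))
    n_cov = z.shape[1]
    # residualize on covariates + intercept
    zz_inv = np.linalg.pinv(z.T @ z)
    proj = z @ (zz_inv @ (z.T @ np.column_stack([y[:, None], x])))
    res = np.column_stack([y[:, None], x]) - proj
    ry, rx = res[:, 0], res[:, 1:]

    sxx = (rx ** 2).sum(axis=0)
    var_raw = x.var(axis=0)
    rows = []
    for j, key in enumerate(panel.variant_keys):
        if var_raw[j] == 0:
            logger.warning("variant %s is monomorphic; skipped", key)
            continue
        collinear = sxx[j] / (var_raw[j] * n) < collinear_tol
        if collinear:
            rows.append({"variant": key, "beta_x_psi": np.nan, "se": np.inf,
                         "n": n, "collinear": True})
            continue
        b = float(rx[:, j] @ ry / sxx[j])
        dof = n - n_cov - 1
        rss = float((ry ** 2).sum() - b * (rx[:, j] @ ry))
        se = float(np.sqrt(max(rss, 0.0) / dof / sxx[j])) if dof > 0 else np.inf
        rows.append({"variant": key, "beta_x_psi": b, "se": se, "n": n,
                     "collinear": False})
    return pd.DataFrame(rows).set_index("variant")


def harmonize(psi_effects: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    """Join splicing and GWAS effects on chrom:pos with allele alignment.

    The splicing effect allele is the variant key's alt allele.  GWAS
    records with (A1, A2) = (alt, ref) are kept as-is; (ref, alt) flips
    the sign of b; palindromic variants whose alleles do not match exactly
    are dropped (strand ambiguity).  Raises when nothing joins.
    """
    gwas_by_pos: dict[tuple[str, int], list[pd.Series]] = {}
    for _, rec in gwas.iterrows():
        chrom, pos, _r, _a = parse_variant_key(str(rec["SNP"]))
        gwas_by_pos.setdefault((chrom, pos), []).append(rec)
    rows = []
    dropped_palindromic = 0
    for key, eff in psi_effects.iterrows():
        chrom, pos, ref, alt = parse_variant_key(str(key))
        for rec in gwas_by_pos.get((chrom, pos), []):
            a1, a2 = str(rec["A1"]).upper(), str(rec["A2"]).upper()
            if (a1, a2) == (alt, ref):
                sign = 1.0
            elif (a1, a2) == (ref, alt):
                if is_palindromic(ref, alt):
                    dropped_palindromic += 1
                    continue
                sign = -1.0
            else:
                continue
            rows.append({"variant": key, "beta_x_psi": eff["beta_x_psi"],
                         "se_x_psi": eff["se"], "beta_xy": sign * float(rec["b"]),
                         "se_xy": float(rec["se"])})
            break
    if not rows:
        raise ValueError("no shared variants between splicing effects and GWAS summary")
    out = pd.DataFrame(rows).set_index("variant")
    out.attrs["dropped_palindromic"] = dropped_palindromic
    return out


def greedy_ld_prune(instruments: pd.DataFrame, panel: GenotypePanel,
                    r2_threshold: float) -> pd.DataFrame:
    """Keep the strongest instruments, dropping any in LD (reference r^2)."""
    order = (instruments["beta_x_psi"].abs() / instruments["se_x_psi"]).sort_values(ascending=False)
    dosages = panel.dosages
    kept: list[str] = []
    for key in order.index:
        if key not in dosages.columns:
            continue
        x = dosages[key]
        ok = True
        for other in kept:
            r = np.corrcoef(x, dosages[other])[0, 1]
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(key)
    return instruments.loc[kept]


def gsmr_fit(instruments: pd.DataFrame, weighting: str = "inverse-variance",
             ld_prune_r2: float | None = None,
             panel: GenotypePanel | None = None) -> GsmrEstimate:
    """Through-origin LS slope of beta_xy on beta_x_psi.

    ``weighting='inverse-variance'`` weights each instrument by
    1/se(beta_xy)^2 (Wald normal p); ``'none'`` is the unweighted LS fit
    with a residual-based t test.  Optional greedy LD pruning against a
    reference panel runs first.
    """
    inst = instruments.dropna(subset=["beta_x_psi", "beta_xy"])
    if ld_prune_r2 is not None:
        if panel is None:
            raise ValueError("LD pruning needs a reference panel")
        inst = greedy_ld_prune(inst, panel, ld_prune_r2)
    x = inst["beta_x_psi"].to_numpy(dtype=float)
    y = inst["beta_xy"].to_numpy(dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("GSMR needs at least 2 instruments after filtering")
    if np.max(np.abs(x)) < 1e-12 or (inst["beta_x_psi"].abs() < 2 * inst["se_x_psi"]).all():
        raise WeakInstrumentError(
            "all instruments have negligible splicing effects (|beta_x_psi| < 2 SE); "
            "the slope of beta_xy on beta_x_psi is not identified")
    if weighting == "inverse-variance":
        w = 1.0 / inst["se_xy"].to_numpy(dtype=float) ** 2
        sxx = float(np.sum(w * x * x))
        b = float(np.sum(w * x * y) / sxx)
        se = float(np.sqrt(1.0 / sxx))
        p = float(2 * stats.norm.sf(abs(b / se)))
    elif weighting == "none":
        sxx = float(np.sum(x * x))
        b = float(np.sum(x * y) / sxx)
        rss = float(np.sum((y - b * x) ** 2))
        se = float(np.sqrt(rss / (n - 1) / sxx))
        p = float(2 * stats.t.sf(abs(b / se), df=n - 1)) if se > 0 else 0.0
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return GsmrEstimate(beta_psi_y=b, se=se, p=p, n_instruments=n, weighting=weighting)


def read_ma(path) -> pd.DataFrame:
    """COJO '.ma' summary statistics: SNP A1 A2 freq b se p N."""
    df = pd.read_csv(path, sep=r"\s+")
    required = {"SNP", "A1", "A2", "b", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary file missing columns {sorted(missing)}")
    return df
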