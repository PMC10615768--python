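"""Mendelian-randomization association of psi_hat with traits via GEE.

Subjects are clustered by family; the working correlation is exchangeable
within families (a block-diagonal structure with one coefficient shared by
all members of a family, zero across families) and standard errors are
robust sandwich estimates.  Supported marginal models: binomial with logit
link (diagnosis), Poisson with log link (symptom counts), Gaussian with
log link (e.g. regional brain volumes) and Gaussian with identity link.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

FAMILIES = {
    "binomial-logit": lambda: sm.families.Binomial(),
    "poisson-log": lambda: sm.families.Poisson(),
    "gaussian-log": lambda: sm.families.Gaussian(sm.families.links.Log()),
    "gaussian-identity": lambda: sm.families.Gaussian(),
}


@dataclass
class AssociationResult:
    event_id: str
    trait: str
    beta: float
    se: float
    p: float
    n: int
    converged: bool
    fdr: float | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


class AssociationError(RuntimeError):
    pass


def _design(psihat: pd.Series, phenotypes: pd.DataFrame, covariates: list[str]):
    df = phenotypes.set_index("sample_id") if "sample_id" in phenotypes.columns else phenotypes.copy()
    df = df.copy()
    df["psihat"] = psihat.reindex(df.index)
    cols = ["trait", "family_id", "psihat"] + list(covariates)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table is missing columns {missing}")
    before = len(df)
    df = df.dropna(subset=cols)
    dropped = before - len(df)
    exog = sm.add_constant(df[["psihat"] + list(covariates)].astype(float), has_constant="add")
    return df, exog, dropped


def gee_associate(psihat: pd.Series, phenotypes: pd.DataFrame,
                  family: str = "binomial-logit",
                  covariates: list[str] | None = None,
                  event_id: str = "", trait_name: str = "trait") -> AssociationResult:
    """GEE fit of the trait on psi_hat with covariate adjustment.

    ``phenotypes`` must carry sample_id, family_id, trait and the named
    covariate columns; rows with missing values are dropped.  Returns the
    Wald test of the psi_hat coefficient with sandwich standard errors.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    covariates = list(covariates or [])
    df, exog, _ = _design(psihat, phenotypes, covariates)
    if df["family_id"].nunique() < 2:
        raise AssociationError("need at least two families")
    if df["psihat"].nunique() <= 1:
        raise AssociationError("psi_hat is constant; association is undefined")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GEE(df["trait"].astype(float), exog, groups=df["family_id"],
                           family=FAMILIES[family](), cov_struct=sm.cov_struct.Exchangeable())
            fit = model.fit(maxiter=100)
        except Exception as exc:  # separation / non-convergence
            raise AssociationError(f"GEE failed: {exc}") from exc
    params = fit.params
    beta = float(params["psihat"])
    se = float(fit.bse["psihat"])
    p = float(fit.pvalues["psihat"])
    if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        raise AssociationError("GEE produced non-finite estimates")
    return AssociationResult(event_id=event_id, trait=trait_name, beta=beta, se=se,
                             p=p, n=len(df), converged=converged)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone enforced).

    NaNs are passed through and excluded from the correction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def associate_events(psihat: pd.DataFrame, phenotypes: pd.DataFrame,
                     family: str = "binomial-logit",
                     covariates: list[str] | None = None,
                     trait_name: str = "trait") -> pd.DataFrame:
    """Per-event GEE association with BH FDR across the tested events.

    Events whose fit fails (separation, constant psi_hat, non-convergence)
    are reported with NaN statistics and excluded from the FDR family.
    """
    rows = []
    for event_id in psihat.columns:
        try:
            res = gee_associate(psihat[event_id], phenotypes, family=family,
                                covariates=covariates, event_id=event_id,
                                trait_name=trait_name)
            rows.append({"event_id": event_id, "trait": trait_name, "beta": res.beta,
                         "se": res.se, "p": res.p, "n": res.n, "note": ""})
        except AssociationError as exc:
            rows.append({"event_id": event_id, "trait": trait_name, "beta": np.nan,
                         "se": np.nan, "p": np.nan, "n": 0, "note": str(exc)})
    out = pd.DataFrame(rows).set_index("event_id")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def replicate(discovery: pd.DataFrame, replication: pd.DataFrame,
              fdr_cut: float = 0.05) -> pd.DataFrame:
    """Discovery -> replication logic over association tables.

    Events significant in discovery (fdr < cut) are carried forward; the
    replication FDR is recomputed by BH *within that carried-forward
    subset*.  ``replicated`` requires both FDRs below the cut; sign
    consistency of the effect estimates is reported separately, not
    required for the replicated label.  Events untestable in replication
    are recorded as not replicated with a reason.
    """
    disc_sig = discovery[discovery["fdr"] < fdr_cut]
    rows = []
    rep_p = replication["p"] if "p" in replication.columns else pd.Series(dtype=float)
    carried = disc_sig.index
    rep_sub = rep_p.reindex(carried)
    rep_fdr = pd.Series(bh_fdr(rep_sub.to_numpy()), index=carried)
    for event_id in carried:
        testable = event_id in replication.index and np.isfinite(rep_p.get(event_id, np.nan))
        if not testable:
            rows.append({"event_id": event_id, "replication_fdr": np.nan,
                         "replicated": False, "consistent": False,
                         "reason": "untestable in replication"})
            continue
        replicated = bool(rep_fdr[event_id] < fdr_cut)
        consistent = bool(np.sign(discovery.loc[event_id, "beta"])
                          == np.sign(replication.loc[event_id, "beta"]))
        rows.append({"event_id": event_id, "replication_fdr": float(rep_fdr[event_id]),
                     "replicated": replicated, "consistent": consistent, "reason": ""})
    return pd.DataFrame(rows).set_index("event_id") if rows else pd.DataFrame(
        columns=["replication_fdr", "replicated", "consistent", "reason"])
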