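"""Apply trained splicing models to a new cohort's genotypes.

Model variants are matched into the cohort on chrom:pos.  Exact ref/alt
matches are used as-is; records with swapped ref/alt contribute the
complementary dosage 2 - X; strand-ambiguous palindromic SNVs (A/T, C/G)
whose alleles do not match exactly are dropped rather than guessed.  An
event proceeds only when the matched fraction of its model variants
reaches the coverage gate (default 0.9, boundary inclusive); unmatched
variants contribute nothing to psi_hat.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import SpliceModel
from .panel import GenotypePanel, is_palindromic, parse_variant_key


@dataclass
class ImputationReport:
    event_id: str
    n_model_variants: int
    n_matched: int
    flipped_count: int
    dropped_ambiguous: int
    proceed: bool
    reason: str = ""

    @property
    def coverage_fraction(self) -> float:
        if self.n_model_variants == 0:
            return 0.0
        return self.n_matched / self.n_model_variants


class BuildMismatchError(RuntimeError):
    pass


def match_variants(model: SpliceModel, cohort: GenotypePanel,
                   min_coverage: float = 0.9
                   ) -> tuple[ImputationReport, pd.DataFrame]:
    """Harmonize a cohort's dosages to the model's variant definitions.

    Returns the report and a samples x matched-model-variants dosage frame
    (columns named by the model's own variant keys).
    """
    matched: dict[str, pd.Series] = {}
    flipped = 0
    ambiguous = 0
    for key in model.weights:
        chrom, pos, ref, alt = parse_variant_key(key)
        hits = cohort.lookup_position(chrom, pos)
        found = None
        for hit in hits:
            _c, _p, href, halt = parse_variant_key(hit)
            if (href, halt) == (ref, alt):
                found = cohort.dosages[hit]
                break
            if (href, halt) == (alt, ref):
                if is_palindromic(ref, alt):
                    ambiguous += 1
                    found = None
                    break
                found = 2.0 - cohort.dosages[hit]
                flipped += 1
                break
        if found is not None:
            matched[key] = found
    n_model = len(model.weights)
    report = ImputationReport(
        event_id=model.event_id, n_model_variants=n_model, n_matched=len(matched),
        flipped_count=flipped, dropped_ambiguous=ambiguous,
        proceed=n_model > 0 and len(matched) / n_model >= min_coverage,
    )
    if not report.proceed:
        report.reason = (f"coverage {report.coverage_fraction:.2f} below {min_coverage}"
                         if n_model else "model has no variants")
    dosages = pd.DataFrame(matched, index=cohort.samples)
    return report, dosages


def impute_psi(model: SpliceModel, harmonized: pd.DataFrame) -> pd.Series:
    """psi_hat = alpha + sum_k beta_k X_k over the matched variants.

    A subject missing any matched dosage gets NaN (no mean imputation).
    """
    pred = pd.Series(model.intercept, index=harmonized.index, dtype=float)
    for key in harmonized.columns:
        pred = pred + model.weights[key] * harmonized[key]
    return pred


def impute_cohort(models: dict[str, SpliceModel], cohort: GenotypePanel,
                  min_coverage: float = 0.9
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """psi_hat (subjects x events) and the per-event imputation reports.

    Non-informative models and events failing the coverage gate are
    skipped (recorded in the report).  Raises :class:`BuildMismatchError`
    when no model variant matches the cohort at all, which almost always
    means a genome-build mismatch.
    """
    preds: dict[str, pd.Series] = {}
    reports = []
    any_match = False
    any_variants = False
    for event_id, model in models.items():
        if not model.informative:
            reports.append(ImputationReport(event_id, len(model.weights), 0, 0, 0,
                                            False, "non-informative model"))
            continue
        any_variants = True
        report, dosages = match_variants(model, cohort, min_coverage=min_coverage)
        reports.append(report)
        any_match = any_match or report.n_matched > 0
        if report.proceed:
            preds[event_id] = impute_psi(model, dosages)
    if any_variants and not any_match:
        raise BuildMismatchError(
            "no model variant matched the cohort at any position; the cohort "
            "genotypes are probably on a different genome build — lift the "
            "models or the cohort to a common build before imputing")
    psihat = pd.DataFrame(preds, index=cohort.samples)
    psihat.index.name = "sample_id"
    report_df = pd.DataFrame([{
        "event_id": r.event_id, "n_model_variants": r.n_model_variants,
        "n_matched": r.n_matched, "coverage_fraction": r.coverage_fraction,
        "flipped_count": r.flipped_count, "dropped_ambiguous": r.dropped_ambiguous,
        "proceed": r.proceed, "reason": r.reason,
    } for r in reports])
    return psihat, report_df
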