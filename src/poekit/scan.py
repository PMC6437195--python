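"""Per-CpG variance decomposition and the genome-wide imprinting-signature scan.

Two entry points:

- :func:`gkfsc_decompose` fits the five-component model
  CpG ~ G + K + F + S + C (+ residual) per CpG, reporting the proportion of
  methylation variance attributable to common-SNP additive effects, extra
  pedigree-associated additive effects, and the nuclear-family, full-sib and
  couple environmental layers, with one-sided Wald tests per component.

- :func:`poe_scan` runs the model-selection scan for parent-of-origin effects:
  a base model CpG ~ G + K is compared by one-sided LRT against three
  alternatives that each add one covariance signature of imprinting —
  S (complex / bipolar pattern: only sibs more alike), S_M (maternal
  imprinting: sibs and father-offspring more alike) and S_P (paternal
  imprinting: sibs and mother-offspring more alike).  Per CpG the significant
  alternative with the largest log-likelihood gain is selected, and
  Benjamini-Hochberg FDR is applied across CpGs on the selected-model
  p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import reml
from .relmat import RelationshipMatrix

#: deterministic preference when alternatives tie on log-likelihood; the
#: complex (sib-only) pattern nests inside both one-parent patterns.
MODEL_ORDER = ("complex", "maternal", "paternal")
MODEL_MATRIX = {"complex": "S", "maternal": "S_M", "paternal": "S_P"}


def pre_correct(y, covariates=None, matrices=(), **fit_kw) -> np.ndarray:
    """Residualise a phenotype for fixed covariates and fitted random effects.

    Fits covariates as fixed effects and the supplied relationship matrices
    as random effects by REML, then returns
    ``y - X beta_hat - sum_i BLUP_i`` — i.e. the phenotype with both the
    covariate predictions and the best linear unbiased predictions of the
    random effects removed.  With no covariates and no matrices this is
    simple mean-centring.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([np.ones(n), cov])
    fit = reml.reml_fit(y, X, matrices, **fit_kw)
    beta, u = reml.blup(y, X, matrices, fit)
    return y - X @ beta - u


@dataclass
class ComponentTest:
    """Per-component result of a GKFSC decomposition for one CpG."""

    cpg: str
    component: str
    variance: float
    se: float
    proportion: float
    wald_p: float
    genome_wide: bool


def gkfsc_decompose(methylation: pd.DataFrame,
                    matrices: dict[str, RelationshipMatrix],
                    covariates=None, alpha: float = 0.05,
                    components: tuple[str, ...] = ("G", "K", "F", "S", "C"),
                    ) -> tuple[pd.DataFrame, dict[str, reml.VCFit]]:
    """Five-component variance decomposition of every CpG column.

    Returns a long table (one row per CpG x component, columns as in
    :class:`ComponentTest`) and the per-CpG fits.  ``genome_wide`` applies a
    Bonferroni threshold ``alpha / n_CpGs`` to the one-sided Wald p-values;
    non-converged fits are flagged (``wald_p = NaN``) and excluded from
    significance calls.
    """
    _check_alignment(methylation, matrices)
    mats = [matrices[c] for c in components]
    n_cpgs = methylation.shape[1]
    threshold = alpha / n_cpgs
    rows, fits = [], {}
    for cpg in methylation.columns:
        fit = reml.reml_fit(methylation[cpg].to_numpy(), covariates, mats,
                            names=list(components))
        fits[cpg] = fit
        for comp in components:
            est, se = fit.variance(comp), fit.se_of(comp)
            if fit.converged and se > 0:
                p = reml.wald_onesided(est, se)
                gw = p <= threshold
            else:
                p, gw = np.nan, False
            rows.append(ComponentTest(cpg, comp, est, se,
                                      fit.proportion(comp), p, gw))
    return pd.DataFrame(rows), fits


@dataclass
class POEScanRecord:
    """Selected imprinting model and test results for one CpG."""

    cpg: str
    loglik_base: float
    logliks: dict[str, float]
    selected: str               # "none", "complex", "maternal" or "paternal"
    best_model: str | None      # best alternative before the FDR gate
    statistic: float
    p: float
    q: float
    significant: bool
    skipped: tuple[str, ...]    # alternatives dropped for non-convergence
    fit: reml.VCFit | None


def poe_scan(methylation: pd.DataFrame,
             matrices: dict[str, RelationshipMatrix],
             covariates=None, fdr_q: float = 0.05,
             models: tuple[str, ...] = MODEL_ORDER) -> list[POEScanRecord]:
    """Model-selection scan for imprinting signatures across CpGs.

    Per CpG the base model (G + K) and each alternative are fitted by REML
    (alternatives warm-started from the base estimates); each alternative is
    tested against the base by the one-sided boundary LRT.  The alternative
    with the largest log-likelihood is the per-CpG candidate (ties broken
    complex > maternal > paternal); its p-value enters a single
    Benjamini-Hochberg pass across all CpGs, and CpGs with q <= ``fdr_q``
    are labelled with their selected model, the rest as ``"none"``.

    CpGs whose base model does not converge are dropped entirely;
    non-converged alternatives are skipped for that CpG and noted.
    """
    _check_alignment(methylation, matrices)
    base_mats = [matrices["G"], matrices["K"]]
    records: list[POEScanRecord] = []
    for cpg in methylation.columns:
        y = methylation[cpg].to_numpy()
        base = reml.reml_fit(y, covariates, base_mats, names=["G", "K"])
        if not base.converged:
            continue
        warm = np.concatenate([base.variances[:-1],
                               [0.05 * base.variances.sum()],
                               [max(base.variances[-1], 1e-4 * y.var())]])
        logliks, alt_fits, skipped = {}, {}, []
        for model in models:
            mat = matrices[MODEL_MATRIX[model]]
            alt = reml.reml_fit(y, covariates, base_mats + [mat],
                                names=["G", "K", MODEL_MATRIX[model]],
                                start=warm)
            if not alt.converged:
                skipped.append(model)
                continue
            logliks[model] = alt.loglik
            alt_fits[model] = alt
        if not logliks:
            continue
        best = max(MODEL_ORDER, key=lambda m: (logliks.get(m, -np.inf),
                                               -MODEL_ORDER.index(m)))
        statistic, p = reml.lrt_onesided(base.loglik, logliks[best])
        records.append(POEScanRecord(cpg, base.loglik, logliks, "none", best,
                                     statistic, p, np.nan, False,
                                     tuple(skipped), alt_fits[best]))
    if records:
        qvals, flags = bh_fdr([r.p for r in records], fdr_q)
        for r, q, sig in zip(records, qvals, flags):
            r.q = float(q)
            r.significant = bool(sig)
            r.selected = r.best_model if sig else "none"
    return records


def scan_records_frame(records: list[POEScanRecord]) -> pd.DataFrame:
    """Flatten scan records to a results table."""
    rows = []
    for r in records:
        row = {"cpg": r.cpg, "selected": r.selected, "best_model": r.best_model,
               "statistic": r.statistic, "p": r.p, "q": r.q,
               "significant": r.significant, "loglik_base": r.loglik_base}
        for m in MODEL_ORDER:
            row[f"loglik_{m}"] = r.logliks.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def _check_alignment(methylation: pd.DataFrame,
                     matrices: dict[str, RelationshipMatrix]) -> None:
    ids = list(methylation.index)
    for kind, mat in matrices.items():
        if mat.ids and list(mat.ids) != ids:
            raise ValueError(
                f"id order of matrix {kind} does not match the methylation table")
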