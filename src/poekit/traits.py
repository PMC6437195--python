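"""Trait-level consequences of parent-of-origin effects.

- EWAS: each pre-corrected quantitative trait regressed on methylation at
  each candidate CpG (two-sided), with Bonferroni tiers built from the
  effective number of independently tested traits.
- PheWAS: each trait tested against candidate SNPs with the joint
  additive / dominance / POE model, phenome-wide Bonferroni threshold
  ``alpha / (n_independent_snps * N_eff)``.
- POE-by-covariate interactions: sex interaction via a product term,
  age-decile profile via the plain POE test within deciles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mqtl import GenotypeCodings, MQTLRecord, poe_regression


def effective_trait_count(traits: pd.DataFrame | np.ndarray | None = None,
                          corr: np.ndarray | None = None) -> int:
    """Effective number of independently tested traits.

    Eigen-decomposes the trait correlation matrix and returns the smallest k
    whose leading eigenvalues explain >= 95% of the variance, after verifying
    (Kaiser's rule) that every eigenvalue beyond k is < 0.5.  When the two
    criteria disagree the more conservative ``max(k, #eigenvalues >= 0.5)``
    is returned with a warning.
    """
    if corr is None:
        if traits is None:
            raise ValueError("provide a trait table or a correlation matrix")
        corr = pd.DataFrame(traits).corr().to_numpy()
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] < 2:
        raise ValueError("need at least two traits")
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ValueError("trait correlation matrix has rank 0")
    cum = np.cumsum(eig) / total
    k = int(np.searchsorted(cum, 0.95 - 1e-12) + 1)
    kaiser = int(np.sum(eig >= 0.5))
    if k < len(eig) and eig[k] >= 0.5:
        n_eff = max(k, kaiser)
        warnings.warn(
            "95%-variance and Kaiser criteria disagree "
            f"(k95={k}, #eig>=0.5={kaiser}); using {n_eff}", stacklevel=2)
        return n_eff
    return k


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class AssociationRecord:
    """One trait-predictor association with its significance tier."""

    trait: str
    predictor: str
    estimate: float
    se: float
    p: float
    n: int
    tier: str  # "multi-trait", "per-trait" or "none"


def ewas(traits: pd.DataFrame, methylation: pd.DataFrame,
         n_eff: int | None = None, alpha: float = 0.05
         ) -> list[AssociationRecord]:
    """Trait ~ CpG simple regressions for every trait-CpG pair.

    Both tables must be pre-corrected and share their index (individuals).
    Tiers: ``multi-trait`` at p <= alpha / (N_eff * n_CpGs), ``per-trait`` at
    p <= alpha / n_CpGs.  Zero-variance predictors are skipped.
    """
    if list(traits.index) != list(methylation.index):
        raise ValueError("trait and methylation tables must share their index")
    if n_eff is None:
        n_eff = effective_trait_count(traits)
    n_cpgs = methylation.shape[1]
    thr_multi = bonferroni_threshold(n_eff * n_cpgs, alpha)
    thr_single = bonferroni_threshold(n_cpgs, alpha)
    out: list[AssociationRecord] = []
    for cpg in methylation.columns:
        x = methylation[cpg].to_numpy(dtype=float)
        sx = x.std(ddof=1)
        if sx == 0 or not np.isfinite(sx):
            continue
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            n = int(keep.sum())
            if n < 3:
                continue
            slope, se, p = _simple_regression(x[keep], y[keep])
            tier = ("multi-trait" if p <= thr_multi
                    else "per-trait" if p <= thr_single else "none")
            out.append(AssociationRecord(trait, cpg, slope, se, p, n, tier))
    return out


def _simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return slope, se, p


def phewas(traits: pd.DataFrame, snp_codings: dict[str, GenotypeCodings],
           n_independent_snps: int | None = None, n_eff: int | None = None,
           alpha: float = 0.05) -> list[MQTLRecord]:
    """Trait ~ SNP_add + SNP_dom + SNP_poe for candidate SNPs.

    Reuses the mQTL regression per trait-SNP pair; the phenome-wide
    (``multi-trait``) tier applies ``alpha / (n_independent_snps * N_eff)``
    to the POE coefficient's p-value, the ``per-trait`` tier
    ``alpha / n_independent_snps``.
    """
    if n_eff is None:
        n_eff = effective_trait_count(traits)
    if n_independent_snps is None:
        n_independent_snps = len(snp_codings)
    thr_multi = bonferroni_threshold(n_independent_snps * n_eff, alpha)
    thr_single = bonferroni_threshold(n_independent_snps, alpha)
    out: list[MQTLRecord] = []
    for snp, codings in snp_codings.items():
        for trait in traits.columns:
            rec = poe_regression(traits[trait].to_numpy(dtype=float), codings,
                                 snp=snp, phenotype_id=trait)
            p_poe = rec.p.get("poe", np.nan)
            rec.tier = ("multi-trait" if p_poe <= thr_multi
                        else "per-trait" if p_poe <= thr_single else "none")
            out.append(rec)
    return out


@dataclass
class InteractionResult:
    estimate: float
    se: float
    p: float
    n: int


def poe_interaction_test(phenotype: np.ndarray, codings: GenotypeCodings,
                         moderator: np.ndarray) -> InteractionResult:
    """Two-sided t-test of a POE-by-moderator interaction.

    Augments the joint additive/dominance/POE regression with the moderator
    main effect and the ``poe x moderator`` product; returns the interaction
    coefficient.  A planted sex-specific imprinting effect shows up here as a
    non-zero interaction while the marginal POE term averages the two groups.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotype, dtype=float)
    mod = np.asarray(moderator, dtype=float)
    keep = codings.valid & np.isfinite(y) & np.isfinite(mod)
    if len(np.unique(mod[keep])) < 2:
        raise ValueError("moderator must have at least two levels")
    X = np.column_stack([
        np.ones(keep.sum()),
        codings.add[keep], codings.dom[keep], codings.poe[keep],
        mod[keep], codings.poe[keep] * mod[keep],
    ])
    res = sm.OLS(y[keep], X).fit()
    return InteractionResult(float(res.params[-1]), float(res.bse[-1]),
                             float(res.pvalues[-1]), int(keep.sum()))


def poe_by_age_decile(phenotype: np.ndarray, codings: GenotypeCodings,
                      age: np.ndarray) -> pd.DataFrame:
    """Plain POE test within each age decile (ties broken to the lower decile)."""
    age = np.asarray(age, dtype=float)
    edges = np.quantile(age, np.linspace(0, 1, 11))
    decile = np.clip(np.searchsorted(edges, age, side="left"), 1, 10)
    rows = []
    for d in range(1, 11):
        sel = decile == d
        if sel.sum() < 10:
            continue
        sub = GenotypeCodings(codings.add[sel], codings.dom[sel],
                              codings.poe[sel], codings.valid[sel])
        rec = poe_regression(np.asarray(phenotype, dtype=float)[sel], sub)
        rows.append({"decile": d, "n": rec.n,
                     "beta_poe": rec.beta.get("poe", np.nan),
                     "se_poe": rec.se.get("poe", np.nan),
                     "p_poe": rec.p.get("poe", np.nan)})
    return pd.DataFrame(rows)
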