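"""Parent-of-origin-aware SNP association mapping against CpG phenotypes.

An origin-assigned genotype at a biallelic SNP has four ordered states
(paternal allele first): AA, Aa, aA, aa.  Three jointly fitted codings
separate the genetic effects:

===========  ====  ====  ====  ====
coding        AA    Aa    aA    aa
===========  ====  ====  ====  ====
additive       0     1     1     2
dominance      0     1     1     0
POE            0    -1    +1     0
===========  ====  ====  ====  ====

The POE coding contrasts the reciprocal heterozygotes: a non-zero POE
coefficient means the allele's effect depends on which parent transmitted it,
the hallmark of imprinting.  Under complex (bipolar) imprinting the additive
coefficient is ~0 while the POE coefficient is not — invisible to a standard
additive GWAS.  Supporting machinery: cis/trans classification of SNP-CpG
pairs, permutation-based FDR thresholds, and greedy clumping of correlated
records (applied both to SNPs on genotype r^2 and to CpGs on methylation
correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .origin import OriginAssignedGenotypes

CODING_TABLE = {  # (paternal, maternal) alt counts -> (add, dom, poe)
    (0, 0): (0, 0, 0),   # AA
    (0, 1): (1, 1, -1),  # Aa (paternal A, maternal a)
    (1, 0): (1, 1, +1),  # aA (paternal a, maternal A)
    (1, 1): (2, 0, 0),   # aa
}


@dataclass
class GenotypeCodings:
    """Additive / dominance / POE codings for one SNP across individuals."""

    add: np.ndarray
    dom: np.ndarray
    poe: np.ndarray
    valid: np.ndarray  # False where origin was ambiguous/inconsistent

    def design(self) -> np.ndarray:
        return np.column_stack([self.add, self.dom, self.poe])


def encode_poe(paternal: np.ndarray, maternal: np.ndarray,
               status: np.ndarray | None = None) -> GenotypeCodings:
    """Map ordered (paternal, maternal) allele pairs to the three codings.

    Individuals with unassigned origin (``status != "assigned"`` or negative
    allele codes) are masked out via ``valid``.
    """
    pat = np.asarray(paternal, dtype=int)
    mat = np.asarray(maternal, dtype=int)
    valid = (pat >= 0) & (mat >= 0)
    if status is not None:
        valid &= np.asarray(status) == "assigned"
    add = np.where(valid, pat + mat, 0)
    dom = np.where(valid, (pat + mat) == 1, 0).astype(int)
    poe = np.where(valid, pat - mat, 0)
    return GenotypeCodings(add, dom, poe, valid)


def codings_from_assignment(assigned: OriginAssignedGenotypes,
                            snp: int) -> tuple[int, int, int, bool]:
    """Single-individual codings for one SNP of an origin assignment."""
    c = encode_poe(assigned.paternal[snp:snp + 1], assigned.maternal[snp:snp + 1],
                   assigned.status[snp:snp + 1])
    return int(c.add[0]), int(c.dom[0]), int(c.poe[0]), bool(c.valid[0])


@dataclass
class MQTLRecord:
    """Joint additive/dominance/POE regression result for one SNP-phenotype pair."""

    snp: str
    phenotype: str
    beta: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    n: int = 0
    dropped: tuple[str, ...] = ()
    flagged: bool = False
    cis_trans: str | None = None
    tier: str | None = None  # used by the phenome-wide association analysis


def poe_regression(phenotype: np.ndarray, codings: GenotypeCodings,
                   snp: str = "snp", phenotype_id: str = "y",
                   min_n: int = 10) -> MQTLRecord:
    """OLS of a pre-corrected phenotype on the three codings jointly.

    Individuals with unassigned origin are excluded.  Columns that are
    collinear with earlier ones (e.g. dominance when no minor homozygotes are
    present) are dropped and flagged; a design left rank-deficient after
    drops flags the whole record.  Coefficient tests are two-sided t-tests.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = codings.valid & np.isfinite(y)
    y = y[keep]
    design = codings.design()[keep]
    rec = MQTLRecord(snp, phenotype_id, n=int(keep.sum()))
    if rec.n < min_n or len(np.unique(design[:, 0])) < 2:
        rec.flagged = True
        return rec
    names = ["add", "dom", "poe"]
    cols, kept_names, dropped = [np.ones(rec.n)], [], []
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [design[:, j]])
        if np.linalg.matrix_rank(trial) > len(cols):
            cols.append(design[:, j])
            kept_names.append(name)
        else:
            dropped.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1] or X.shape[1] < 2:
        rec.flagged = True
        rec.dropped = tuple(dropped)
        return rec
    res = sm.OLS(y, X).fit()
    for i, name in enumerate(kept_names, start=1):
        rec.beta[name] = float(res.params[i])
        rec.se[name] = float(res.bse[i])
        rec.p[name] = float(res.pvalues[i])
    for name in dropped:
        rec.beta[name] = np.nan
        rec.se[name] = np.nan
        rec.p[name] = np.nan
    rec.dropped = tuple(dropped)
    return rec


def classify_cis_trans(snp_chrom: str, snp_pos: int, cpg_chrom: str,
                       cpg_pos: int, cis_window: int = 1_000_000,
                       trans_distance: int = 5_000_000) -> str:
    """cis / trans / excluded classification of a SNP-CpG pair.

    Same chromosome and |distance| < 1 Mb -> ``cis``; same chromosome with
    1 Mb <= |distance| <= 5 Mb -> ``excluded`` (ambiguous zone, not
    analysed); |distance| > 5 Mb or different chromosomes -> ``trans``.
    Positions are 1-based inclusive.
    """
    if snp_chrom != cpg_chrom:
        return "trans"
    d = abs(int(snp_pos) - int(cpg_pos))
    if d < cis_window:
        return "cis"
    if d > trans_distance:
        return "trans"
    return "excluded"


def permutation_fdr(observed, permuted_sets, q: float = 0.05) -> float | None:
    """Permutation-based p-value threshold controlling FDR at level ``q``.

    For each candidate threshold t (the sorted observed p-values), the FDR is
    estimated as (mean count of permuted p <= t across replicates) / (count
    of observed p <= t).  Returns the largest observed p whose estimated FDR
    is <= q, or ``None`` when no threshold qualifies.  Permutation sets must
    come from shuffling the phenotype-row identity jointly across phenotypes,
    so the SNP-SNP and CpG-CpG correlation structure is retained.
    """
    obs = np.sort(np.asarray(list(observed), dtype=float))
    if obs.size == 0:
        return None
    perms = [np.sort(np.asarray(list(p), dtype=float)) for p in permuted_sets]
    if not perms:
        raise ValueError("at least one permutation replicate is required")
    n_obs = np.arange(1, obs.size + 1)  # count of observed p <= t at t = obs
    mean_null = np.zeros(obs.size)
    for perm in perms:
        mean_null += np.searchsorted(perm, obs, side="right")
    mean_null /= len(perms)
    ok = mean_null / n_obs <= q
    if not ok.any():
        return None
    return float(obs[np.flatnonzero(ok).max()])


def clump(positions, pvalues, r2, chrom=None, window: int = 250_000,
          r2_cut: float = 0.1, p_cut: float = 1.0) -> np.ndarray:
    """Greedy clumping of correlated records around significance peaks.

    Repeatedly takes the unassigned record with the smallest p-value
    (p <= ``p_cut``) as an index and assigns every unassigned record on the
    same chromosome within ``window`` bp whose squared correlation with the
    index is >= ``r2_cut`` to it.  Returns, per record, the integer position
    of its index record (records never indexed or assigned keep -1: p above
    ``p_cut``).  Used for SNPs (genotype r^2) and CpGs (squared methylation
    correlation) alike.
    """
    pos = np.asarray(positions, dtype=np.int64)
    p = np.asarray(pvalues, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    n = len(pos)
    chrom = np.zeros(n) if chrom is None else np.asarray(chrom)
    assignment = np.full(n, -1, dtype=int)
    free = p <= p_cut
    while free.any():
        idx = int(np.flatnonzero(free)[np.argmin(p[free])])
        members = (free & (chrom == chrom[idx])
                   & (np.abs(pos - pos[idx]) <= window) & (r2[idx] >= r2_cut))
        members[idx] = True
        assignment[members] = idx
        free &= ~members
    return assignment


def genotype_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of SNP dosage columns."""
    return _squared_corr(dosages)


def methylation_r2(methylation: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation of (residualised) methylation columns."""
    return _squared_corr(methylation)


def _squared_corr(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(np.asarray(x, dtype=float), rowvar=False)
    c = np.atleast_2d(c)
    return np.nan_to_num(c ** 2, nan=0.0)
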