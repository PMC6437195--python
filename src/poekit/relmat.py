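"""Relationship matrices for family-based variance-component models.

Seven matrices are used downstream: two genomic ones — G (SNP-based genomic
relationship matrix) and K (its sparse "pedigree" thresholding) — and five
binary family-environment indicators:

- F: same nuclear family (couple, parent-offspring or full sibs),
- S: full siblings (both parents shared),
- C: couples (share at least one common offspring),
- S_M: full sibs OR father-offspring — the covariance signature of maternal
  imprinting (maternal allele silenced, so the expressed allele is the
  paternally inherited one, which fathers share with all their offspring),
- S_P: full sibs OR mother-offspring — the paternal-imprinting counterpart.

All matrices share one individual ordering and unit diagonals for the
indicator kinds.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Pedigree, PhasedGenotypes

INDICATOR_KINDS = ("F", "S", "C", "S_P", "S_M")
KINDS = ("G", "K") + INDICATOR_KINDS


@dataclass
class RelationshipMatrix:
    """Symmetric individual-pair similarity matrix tagged by kind."""

    values: np.ndarray
    kind: str
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        if self.ids and len(self.ids) != n:
            raise ValueError("id list does not match matrix dimension")
        if self.kind in INDICATOR_KINDS:
            off = self.values[~np.eye(n, dtype=bool)]
            if not np.isin(off, (0.0, 1.0)).all():
                raise ValueError(f"{self.kind} entries must be 0/1 off-diagonal")
            if not np.allclose(np.diag(self.values), 1.0):
                raise ValueError(f"{self.kind} must have unit diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reorder(self, ids: list[str]) -> "RelationshipMatrix":
        idx = [self.ids.index(i) for i in ids]
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], self.kind, list(ids))


def build_grm(genotypes: PhasedGenotypes | np.ndarray,
              ids: list[str] | None = None) -> RelationshipMatrix:
    """VanRaden-style genomic relationship matrix from 0/1/2 dosages.

    G_ij = (1/m) * sum_s (x_is - 2 p_s)(x_js - 2 p_s) / (2 p_s (1 - p_s)),
    with p_s the sample alternate-allele frequency; monomorphic SNPs are
    excluded (every SNP monomorphic is an error).
    """
    if isinstance(genotypes, PhasedGenotypes):
        x = genotypes.dosages().astype(float)
        ids = list(genotypes.samples)
    else:
        x = np.asarray(genotypes, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(x.shape[0])]
    if not np.isin(x, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; cannot build a GRM")
    x = x[:, poly]
    p = p[poly]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    g = (z @ z.T) / z.shape[1]
    return RelationshipMatrix(g, "G", ids)


def build_kinship_matrix(g: RelationshipMatrix,
                         threshold: float = 0.05) -> RelationshipMatrix:
    """Thresholded GRM capturing close (pedigree) relatedness only.

    Off-diagonal entries below ``threshold`` are zeroed; the diagonal and
    entries at or above the threshold are copied from G.  Fitting K jointly
    with G separates pedigree-associated additive variance from the variance
    tagged by common SNPs in nominally unrelated pairs.
    """
    k = g.values.copy()
    off = ~np.eye(g.n, dtype=bool)
    k[off & (g.values < threshold)] = 0.0
    return RelationshipMatrix(k, "K", list(g.ids))


def build_family_matrices(pedigree: Pedigree) -> dict[str, RelationshipMatrix]:
    """The five indicator matrices {F, S, C, S_P, S_M} from a pedigree.

    Missing parents simply contribute no pairs.  S_M marks full sibs plus
    father-offspring pairs; S_P full sibs plus mother-offspring pairs, so
    S <= S_M and S <= S_P elementwise by construction.
    """
    n = pedigree.n
    mats = {k: np.eye(n) for k in INDICATOR_KINDS}

    def _set(mat: np.ndarray, a: str, b: str) -> None:
        i, j = pedigree.index_of(a), pedigree.index_of(b)
        mat[i, j] = mat[j, i] = 1.0

    for a, b in pedigree.full_sib_pairs():
        for k in INDICATOR_KINDS:
            _set(mats[k], a, b)
    for a, b in pedigree.parent_offspring_pairs("father"):
        _set(mats["F"], a, b)
        _set(mats["S_M"], a, b)
    for a, b in pedigree.parent_offspring_pairs("mother"):
        _set(mats["F"], a, b)
        _set(mats["S_P"], a, b)
    for a, b in pedigree.couple_pairs():
        _set(mats["F"], a, b)
        _set(mats["C"], a, b)
    ids = pedigree.ids
    return {k: RelationshipMatrix(v, k, list(ids)) for k, v in mats.items()}


def build_all_matrices(pedigree: Pedigree, genotypes: PhasedGenotypes,
                       k_threshold: float = 0.05) -> dict[str, RelationshipMatrix]:
    """Convenience constructor for the full {G, K, F, S, C, S_P, S_M} set."""
    g = build_grm(genotypes)
    out = {"G": g, "K": build_kinship_matrix(g, k_threshold)}
    out.update(build_family_matrices(pedigree))
    return out


# ---------------------------------------------------------------------------
# Serialisation (GCTA-GRM-style triplets and dense TSV)
# ---------------------------------------------------------------------------

def write_grm_triplets(mat: RelationshipMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.grm.gz`` (i j n_used value) and ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in mat.ids:
            fh.write(f"{iid}\t{iid}\n")
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(mat.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t1\t{mat.values[i, j]:.10g}\n")


def read_grm_triplets(prefix: str | Path, kind: str = "G") -> RelationshipMatrix:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    vals = np.zeros((n, n))
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            i, j, _, v = line.split()
            a, b = int(i) - 1, int(j) - 1
            vals[a, b] = vals[b, a] = float(v)
    return RelationshipMatrix(vals, kind, ids)


def write_matrix_tsv(mat: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(mat.values, index=mat.ids, columns=mat.ids).to_csv(
        path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path: str | Path, kind: str) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.to_numpy(), kind, [str(i) for i in df.index])
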