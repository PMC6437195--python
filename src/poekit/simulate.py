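"""Synthetic family data with planted genetic, environmental and imprinting effects.

The generator emulates a family-structured population cohort: nuclear families
(a founder couple plus one or more offspring), common biallelic SNPs transmitted
as whole phased chromosomes, CpG methylation phenotypes built from additive
genetic, shared-environment and parent-of-origin components, and correlated
quantitative traits.  Every stochastic quantity carries its ground truth so the
downstream estimators can be scored against it.

Orientation convention used throughout the package: in every ordered allele
pair the FIRST allele is the paternally inherited one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_PARENT = "0"

#: Default planted variance fractions for a methylation phenotype.  These are
#: realistic genome-wide averages for blood methylation in a family cohort:
#: ~9.5% common-SNP additive, ~7% extra pedigree-associated additive, and a
#: few percent for each shared-environment layer.
DEFAULT_VARIANCE_FRACTIONS = {
    "sigma2_g": 0.095,
    "sigma2_k": 0.072,
    "sigma2_f": 0.012,
    "sigma2_s": 0.014,
    "sigma2_c": 0.021,
}


class ConfigurationError(ValueError):
    """Raised when a simulation specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeSpec:
    """Specification of a synthetic two-generation pedigree.

    Parameters
    ----------
    n_families:
        Number of nuclear families (founder couple + offspring).
    offspring_per_family:
        Either a fixed count or a ``{count: probability}`` distribution.
    founder_couples:
        Extra founder couples appended to the pedigree, each with a single
        joint offspring (so that they qualify as couples).
    genotyped_parent_pattern:
        Proportions of families whose parents are observed as
        ``{"trio": ..., "father_duo": ..., "mother_duo": ..., "none": ...}``.
        Masked parents remain in the pedigree but are flagged un-genotyped.
    seed:
        Root seed; identical seeds give bit-identical pedigrees.
    """

    n_families: int = 100
    offspring_per_family: int | dict[int, float] = 2
    founder_couples: int = 0
    genotyped_parent_pattern: dict[str, float] = field(
        default_factory=lambda: {"trio": 1.0, "father_duo": 0.0,
                                 "mother_duo": 0.0, "none": 0.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        props = self.genotyped_parent_pattern
        unknown = set(props) - {"trio", "father_duo", "mother_duo", "none"}
        if unknown:
            raise ConfigurationError(f"unknown parent patterns: {sorted(unknown)}")
        vals = list(props.values())
        if any(v < 0 or v > 1 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(
                "genotyped_parent_pattern proportions must lie in [0,1] and sum to 1")
        if isinstance(self.offspring_per_family, dict):
            pvals = list(self.offspring_per_family.values())
            if any(v < 0 for v in pvals) or abs(sum(pvals) - 1.0) > 1e-9:
                raise ConfigurationError("offspring distribution must sum to 1")


class Pedigree:
    """Two-generation pedigree stored as a FAM-like table.

    The table has columns ``fid, iid, father, mother, sex, genotyped`` with
    ``"0"`` marking a missing parent and sex coded 1 = male, 2 = female.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"fid", "iid", "father", "mother", "sex", "genotyped"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self._index = {iid: i for i, iid in enumerate(self.table["iid"])}
        if len(self._index) != len(self.table):
            raise ValueError("duplicate individual ids in pedigree")
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.table["iid"])

    @property
    def n(self) -> int:
        return len(self.table)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        row = self.table.iloc[self._index[iid]]
        f = None if row["father"] == MISSING_PARENT else row["father"]
        m = None if row["mother"] == MISSING_PARENT else row["mother"]
        return f, m

    def validate(self) -> None:
        ids = set(self.table["iid"])
        sex = dict(zip(self.table["iid"], self.table["sex"]))
        for _, row in self.table.iterrows():
            for col, want in (("father", 1), ("mother", 2)):
                pid = row[col]
                if pid == MISSING_PARENT:
                    continue
                if pid not in ids:
                    raise ValueError(f"{col} {pid!r} of {row['iid']!r} not in pedigree")
                if sex[pid] != want:
                    raise ValueError(f"{col} {pid!r} has inconsistent sex {sex[pid]}")
                if pid == row["iid"]:
                    raise ValueError(f"{row['iid']!r} is its own parent")

    # -- relationship pair enumeration --------------------------------------
    def _sibships(self) -> list[list[str]]:
        off = self.table[(self.table["father"] != MISSING_PARENT)
                         & (self.table["mother"] != MISSING_PARENT)]
        groups: dict[tuple[str, str], list[str]] = {}
        for _, row in off.iterrows():
            groups.setdefault((row["father"], row["mother"]), []).append(row["iid"])
        return list(groups.values())

    def full_sib_pairs(self) -> list[tuple[str, str]]:
        """Unordered pairs of individuals sharing both parents."""
        pairs = []
        for sibs in self._sibships():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.append((sibs[i], sibs[j]))
        return pairs

    def parent_offspring_pairs(self, which: str) -> list[tuple[str, str]]:
        """Pairs (parent, offspring); ``which`` is 'father' or 'mother'."""
        out = []
        for _, row in self.table.iterrows():
            pid = row[which]
            if pid != MISSING_PARENT:
                out.append((pid, row["iid"]))
        return out

    def couple_pairs(self) -> list[tuple[str, str]]:
        """Unordered (father, mother) pairs sharing >= 1 common offspring."""
        seen = set()
        for _, row in self.table.iterrows():
            f, m = row["father"], row["mother"]
            if f != MISSING_PARENT and m != MISSING_PARENT:
                seen.add((f, m))
        return sorted(seen)

    def pair_counts(self, genotyped_only: bool = False) -> dict[str, int]:
        """Counts of full-sib / father-offspring / mother-offspring / couple pairs."""
        keep = set(self.ids)
        if genotyped_only:
            keep = set(self.table.loc[self.table["genotyped"], "iid"])

        def _n(pairs):
            return sum(1 for a, b in pairs if a in keep and b in keep)

        return {
            "full_sib": _n(self.full_sib_pairs()),
            "father_offspring": _n(self.parent_offspring_pairs("father")),
            "mother_offspring": _n(self.parent_offspring_pairs("mother")),
            "couple": _n(self.couple_pairs()),
        }


def simulate_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Generate a two-generation pedigree of nuclear families.

    Deterministic given ``spec.seed``.  Parents masked by the genotyped-parent
    pattern stay in the pedigree (so relationships remain defined) but carry
    ``genotyped = False``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    patterns = list(spec.genotyped_parent_pattern)
    probs = np.array([spec.genotyped_parent_pattern[p] for p in patterns])

    def _n_offspring() -> int:
        if isinstance(spec.offspring_per_family, dict):
            ks = sorted(spec.offspring_per_family)
            ps = np.array([spec.offspring_per_family[k] for k in ks], dtype=float)
            return int(rng.choice(ks, p=ps / ps.sum()))
        return int(spec.offspring_per_family)

    total = spec.n_families + spec.founder_couples
    for fam in range(total):
        fid = f"F{fam:05d}"
        fa, mo = f"{fid}_P1", f"{fid}_P2"
        n_off = 1 if fam >= spec.n_families else _n_offspring()
        pattern = patterns[int(rng.choice(len(patterns), p=probs))]
        fa_gt = pattern in ("trio", "father_duo")
        mo_gt = pattern in ("trio", "mother_duo")
        rows.append((fid, fa, MISSING_PARENT, MISSING_PARENT, 1, fa_gt))
        rows.append((fid, mo, MISSING_PARENT, MISSING_PARENT, 2, mo_gt))
        for k in range(n_off):
            sex = int(rng.integers(1, 3))
            rows.append((fid, f"{fid}_O{k + 1}", fa, mo, sex, True))
    table = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother",
                                        "sex", "genotyped"])
    return Pedigree(table)


def expected_pair_counts(spec: PedigreeSpec) -> dict[str, float]:
    """Expected relationship-pair counts implied by a pedigree spec.

    Useful for checking that a generated pedigree matches its specification;
    ignores genotype masking.
    """
    if isinstance(spec.offspring_per_family, dict):
        e_off = sum(k * v for k, v in spec.offspring_per_family.items())
        e_pairs = sum(k * (k - 1) / 2 * v for k, v in spec.offspring_per_family.items())
    else:
        k = spec.offspring_per_family
        e_off, e_pairs = float(k), k * (k - 1) / 2
    fams, extra = spec.n_families, spec.founder_couples
    return {
        "full_sib": fams * e_pairs,
        "father_offspring": fams * e_off + extra,
        "mother_offspring": fams * e_off + extra,
        "couple": float(fams + extra),
    }


# ---------------------------------------------------------------------------
# Phased genotypes
# ---------------------------------------------------------------------------

@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes; haplotype axis order is (paternal, maternal).

    Attributes
    ----------
    samples:
        Individual ids, aligned with the first axis of ``haplotypes``.
    variants:
        Per-SNP metadata: ``chrom, pos, id, ref, alt, maf`` (1-based positions).
    haplotypes:
        ``(n_samples, n_snps, 2)`` int8 array of alternate-allele indicators;
        ``[..., 0]`` is the paternal haplotype by package convention.
    """

    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.samples), len(self.variants), 2):
            raise ValueError("haplotype array shape does not match samples/variants")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Alternate-allele dosage matrix, shape (n_samples, n_snps), values 0/1/2."""
        return self.haplotypes.sum(axis=2).astype(np.int8)

    def scrambled_phase(self, seed: int) -> tuple["PhasedGenotypes", np.ndarray]:
        """Randomly permute haplotype order per individual per chromosome.

        Emulates statistical phasing, where within-chromosome phase is known
        but which haplotype came from which parent is not.  Returns the new
        object and a boolean array ``flipped[i, c]`` (True where haplotype 0
        of individual ``i`` on chromosome ``c`` is the *maternal* one).
        """
        rng = np.random.default_rng(seed)
        chroms = pd.unique(self.variants["chrom"])
        flipped = rng.integers(0, 2, size=(self.n_samples, len(chroms))).astype(bool)
        haps = self.haplotypes.copy()
        for c, chrom in enumerate(chroms):
            cols = np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())
            rows = np.flatnonzero(flipped[:, c])
            block = haps[np.ix_(rows, cols)]
            haps[np.ix_(rows, cols)] = block[:, :, ::-1]
        return PhasedGenotypes(self.samples, self.variants.copy(), haps), flipped


def simulate_genotypes(pedigree: Pedigree, n_snps: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0, n_chromosomes: int = 5) -> PhasedGenotypes:
    """Drop phased SNPs through a pedigree by whole-chromosome transmission.

    Founder haplotypes are drawn independently per SNP at a per-SNP allele
    frequency uniform on ``maf_range``; each offspring receives one complete
    haplotype from each parent per chromosome (no recombination).  The
    returned haplotype order is truth: axis 2 index 0 is paternal.
    """
    lo, hi = maf_range
    if not (0.01 <= lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie within [0.01, 0.5]")
    rng = np.random.default_rng(seed)
    n = pedigree.n
    mafs = rng.uniform(lo, hi, size=n_snps)
    chrom_of = np.sort(rng.integers(1, n_chromosomes + 1, size=n_snps))
    pos = np.zeros(n_snps, dtype=np.int64)
    for c in range(1, n_chromosomes + 1):
        idx = np.flatnonzero(chrom_of == c)
        draw = np.sort(rng.integers(1, 200_000_000, size=len(idx)))
        pos[idx] = draw + np.arange(len(idx))  # break ties, keep order
    variants = pd.DataFrame({
        "chrom": [f"chr{c}" for c in chrom_of],
        "pos": pos,
        "id": [f"snp{i}" for i in range(n_snps)],
        "ref": "A",
        "alt": "a",
        "maf": mafs,
    })

    haps = np.zeros((n, n_snps, 2), dtype=np.int8)
    order = _founders_first_order(pedigree)
    chrom_ids = [f"chr{c}" for c in range(1, n_chromosomes + 1)]
    cols_by_chrom = {c: np.flatnonzero((variants["chrom"] == c).to_numpy())
                     for c in chrom_ids}
    for iid in order:
        i = pedigree.index_of(iid)
        fa, mo = pedigree.parents_of(iid)
        for h, parent in enumerate((fa, mo)):
            if parent is None:
                haps[i, :, h] = (rng.random(n_snps) < mafs).astype(np.int8)
            else:
                p = pedigree.index_of(parent)
                for c in chrom_ids:
                    cols = cols_by_chrom[c]
                    pick = int(rng.integers(0, 2))
                    haps[i, cols, h] = haps[p, cols, pick]
    return PhasedGenotypes(pedigree.ids, variants, haps)


def _founders_first_order(pedigree: Pedigree) -> list[str]:
    """Topological order: parents before offspring."""
    done: set[str] = set()
    order: list[str] = []
    pending = list(pedigree.ids)
    while pending:
        progress = False
        rest = []
        for iid in pending:
            fa, mo = pedigree.parents_of(iid)
            if all(p is None or p in done for p in (fa, mo)):
                order.append(iid)
                done.add(iid)
                progress = True
            else:
                rest.append(iid)
        if not progress:
            raise ValueError("pedigree contains a parentage cycle")
        pending = rest
    return order


# ---------------------------------------------------------------------------
# Methylation phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectPlan:
    """Planted variance decomposition and imprinting effect for one phenotype.

    Variance fractions are proportions of total phenotypic variance; the
    residual takes the remainder unless ``sigma2_e`` is given explicitly
    (``sigma2_e = 0`` with all fractions zero gives a noise-free phenotype
    equal to the parent-of-origin term).  ``poe_model`` selects the imprinting
    pattern at ``causal_snp``; with paternal dosage ``x_pat`` and maternal
    dosage ``x_mat`` (alternate-allele indicators in {0, 1}) the planted term is

    - ``complex``:  beta * (x_pat - x_mat)   (reciprocal heterozygotes differ,
      homozygotes equal -- no net additive signal);
    - ``maternal_imprinting`` (maternal allele silenced): 2 * beta * x_pat;
    - ``paternal_imprinting`` (paternal allele silenced): 2 * beta * x_mat.
    """

    sigma2_g: float = DEFAULT_VARIANCE_FRACTIONS["sigma2_g"]
    sigma2_k: float = DEFAULT_VARIANCE_FRACTIONS["sigma2_k"]
    sigma2_f: float = DEFAULT_VARIANCE_FRACTIONS["sigma2_f"]
    sigma2_s: float = DEFAULT_VARIANCE_FRACTIONS["sigma2_s"]
    sigma2_c: float = DEFAULT_VARIANCE_FRACTIONS["sigma2_c"]
    sigma2_e: float | None = None
    poe_model: str = "none"
    causal_snp: int = 0
    poe_effect_size: float = 0.0
    seed: int = 0

    _POE_MODELS = ("none", "complex", "paternal_imprinting", "maternal_imprinting")

    def __post_init__(self) -> None:
        fracs = [self.sigma2_g, self.sigma2_k, self.sigma2_f,
                 self.sigma2_s, self.sigma2_c]
        if any(v < 0 for v in fracs):
            raise ConfigurationError("variance fractions must be >= 0")
        if sum(fracs) > 1 + 1e-9:
            raise ConfigurationError("variance fractions must sum to <= 1")
        if self.sigma2_e is not None and self.sigma2_e < 0:
            raise ConfigurationError("sigma2_e must be >= 0")
        if self.poe_model not in self._POE_MODELS:
            raise ConfigurationError(f"unknown poe_model {self.poe_model!r}")

    @property
    def residual(self) -> float:
        if self.sigma2_e is not None:
            return self.sigma2_e
        return 1.0 - (self.sigma2_g + self.sigma2_k + self.sigma2_f
                      + self.sigma2_s + self.sigma2_c)

    def replace(self, **kw) -> "EffectPlan":
        return dataclasses.replace(self, **kw)


def _clipped_factor(matrix: np.ndarray) -> np.ndarray:
    """Square-root factor of a symmetric matrix with eigenvalues clipped at 0."""
    w, v = np.linalg.eigh(matrix)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


class CovarianceFactors:
    """Cached machinery to draw correlated phenotype components for a pedigree.

    Builds (lazily) the eigen factor of the genomic relationship matrix G and
    of the thresholded-kinship matrix K, plus the family / sibship / couple
    group memberships for the environmental layers.
    """

    def __init__(self, pedigree: Pedigree, genotypes: PhasedGenotypes | None,
                 g_matrix: np.ndarray | None = None,
                 k_matrix: np.ndarray | None = None):
        from . import relmat  # local import to avoid a cycle at import time

        self.pedigree = pedigree
        self.n = pedigree.n
        self._relmat = relmat
        self._genotypes = genotypes
        self._g = g_matrix
        self._k = k_matrix
        self._factors: dict[str, np.ndarray] = {}
        self._groups: dict[str, np.ndarray] = {}

    def factor(self, kind: str) -> np.ndarray:
        if kind not in self._factors:
            if kind == "g":
                if self._g is None:
                    if self._genotypes is None:
                        raise ConfigurationError(
                            "sigma2_g > 0 requires genotypes (or a G matrix)")
                    self._g = self._relmat.build_grm(self._genotypes).values
                self._factors["g"] = _clipped_factor(self._g)
            elif kind == "k":
                if self._k is None:
                    self.factor("g")
                    self._k = self._relmat.build_kinship_matrix(
                        self._relmat.RelationshipMatrix(self._g, "G",
                                                        self.pedigree.ids)).values
                self._factors["k"] = _clipped_factor(self._k)
            else:
                raise KeyError(kind)
        return self._factors[kind]

    def groups(self, kind: str) -> np.ndarray:
        """Integer group label per individual; singletons get unique labels."""
        if kind not in self._groups:
            ped = self.pedigree
            labels = np.arange(self.n)
            if kind == "f":
                key = {}
                for _, row in ped.table.iterrows():
                    fam = row["fid"]
                    labels[ped.index_of(row["iid"])] = key.setdefault(fam, len(key))
            elif kind == "s":
                nxt = self.n
                for sibs in ped._sibships():
                    if len(sibs) > 1:
                        for iid in sibs:
                            labels[ped.index_of(iid)] = nxt
                        nxt += 1
            elif kind == "c":
                nxt = self.n
                for fa, mo in ped.couple_pairs():
                    labels[ped.index_of(fa)] = nxt
                    labels[ped.index_of(mo)] = nxt
                    nxt += 1
            else:
                raise KeyError(kind)
            self._groups[kind] = labels
        return self._groups[kind]

    def draw_group(self, kind: str, sd: float, rng: np.random.Generator) -> np.ndarray:
        labels = self.groups(kind)
        uniq, inv = np.unique(labels, return_inverse=True)
        return rng.normal(0.0, sd, size=len(uniq))[inv]

    def draw_factor(self, kind: str, sd: float, rng: np.random.Generator) -> np.ndarray:
        fac = self.factor(kind)
        return fac @ rng.normal(0.0, sd, size=fac.shape[1])


def poe_term(genotypes: PhasedGenotypes, snp: int, model: str,
             beta: float) -> np.ndarray:
    """The planted parent-of-origin term at one SNP for all individuals."""
    x_pat = genotypes.haplotypes[:, snp, 0].astype(float)
    x_mat = genotypes.haplotypes[:, snp, 1].astype(float)
    if model == "complex":
        return beta * (x_pat - x_mat)
    if model == "maternal_imprinting":
        return 2.0 * beta * x_pat
    if model == "paternal_imprinting":
        return 2.0 * beta * x_mat
    raise ConfigurationError(f"unknown poe_model {model!r}")


def simulate_methylation(pedigree: Pedigree, genotypes: PhasedGenotypes | None,
                         plan: EffectPlan,
                         factors: CovarianceFactors | None = None) -> np.ndarray:
    """Simulate one CpG phenotype (length-n vector) under an effect plan.

    The phenotype is the sum of a polygenic term with covariance
    ``sigma2_g * G``, a pedigree term ``sigma2_k * K``, shared nuclear-family /
    full-sib / couple deviations, the planted parent-of-origin term at the
    causal SNP, and iid residual noise.  Pass a pre-built
    :class:`CovarianceFactors` when simulating many CpGs on the same pedigree.
    """
    if plan.residual < -1e-9:
        raise ConfigurationError("variance fractions sum to more than 1")
    if plan.poe_model != "none":
        if genotypes is None or not (0 <= plan.causal_snp < genotypes.n_snps):
            raise ConfigurationError("causal_snp must index an existing SNP")
    if factors is None:
        factors = CovarianceFactors(pedigree, genotypes)
    rng = np.random.default_rng(plan.seed)
    y = np.zeros(pedigree.n)
    if plan.sigma2_g > 0:
        y += factors.draw_factor("g", np.sqrt(plan.sigma2_g), rng)
    if plan.sigma2_k > 0:
        y += factors.draw_factor("k", np.sqrt(plan.sigma2_k), rng)
    for kind, frac in (("f", plan.sigma2_f), ("s", plan.sigma2_s),
                       ("c", plan.sigma2_c)):
        if frac > 0:
            y += factors.draw_group(kind, np.sqrt(frac), rng)
    if plan.poe_model != "none":
        y += poe_term(genotypes, plan.causal_snp, plan.poe_model,
                      plan.poe_effect_size)
    if plan.residual > 0:
        y += rng.normal(0.0, np.sqrt(plan.residual), size=pedigree.n)
    return y


def simulate_methylome(pedigree: Pedigree, genotypes: PhasedGenotypes | None,
                       plans: list[EffectPlan],
                       factors: CovarianceFactors | None = None,
                       positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate a methylation matrix (individuals x CpGs) from per-CpG plans.

    Returns a DataFrame indexed by individual id with columns ``cpg0..``;
    optional ``positions`` (columns ``chrom, pos``) are attached as
    ``DataFrame.attrs['positions']``.
    """
    if factors is None:
        factors = CovarianceFactors(pedigree, genotypes)
    cols = {f"cpg{i}": simulate_methylation(pedigree, genotypes, plan, factors)
            for i, plan in enumerate(plans)}
    out = pd.DataFrame(cols, index=pedigree.ids)
    if positions is not None:
        out.attrs["positions"] = positions
    return out


# ---------------------------------------------------------------------------
# Quantitative traits
# ---------------------------------------------------------------------------

def simulate_traits(pedigree: Pedigree, n_traits: int,
                    correlation: np.ndarray | None = None, seed: int = 0,
                    predictor: np.ndarray | None = None,
                    slopes: np.ndarray | float = 0.0) -> pd.DataFrame:
    """Simulate correlated quantitative traits, optionally driven by a predictor.

    ``correlation`` is the cross-trait correlation matrix (identity by
    default); ``predictor`` (e.g. a CpG vector or a SNP coding) adds
    ``slope * predictor`` to each trait, enabling power tests.
    """
    if correlation is None:
        correlation = np.eye(n_traits)
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (n_traits, n_traits):
        raise ConfigurationError("correlation matrix has wrong shape")
    w = np.linalg.eigvalsh(correlation)
    if w.min() < -1e-8:
        raise ConfigurationError("correlation matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    fac = _clipped_factor(correlation)
    z = rng.normal(size=(pedigree.n, correlation.shape[1]))
    traits = z @ fac.T
    if predictor is not None:
        slopes = np.broadcast_to(np.atleast_1d(np.asarray(slopes, dtype=float)),
                                 (n_traits,))
        traits = traits + np.outer(np.asarray(predictor, dtype=float), slopes)
    return pd.DataFrame(traits, index=pedigree.ids,
                        columns=[f"trait{i}" for i in range(n_traits)])
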