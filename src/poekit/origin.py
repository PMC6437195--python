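"""Parent-of-origin assignment of offspring alleles from trio/duo genotypes.

Phased offspring haplotypes are compared with parental genotypes at
informative loci (offspring heterozygous and the parental genotypes admit
only one haplotype-to-parent mapping).  A whole-chromosome majority vote over
informative loci picks the global mapping — robust to isolated genotype
errors — and per-locus labels are then emitted under the chosen mapping.  In
duos the unmatched haplotype is assigned to the missing parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import Pedigree, PhasedGenotypes

ASSIGNED, AMBIGUOUS, INCONSISTENT = "assigned", "ambiguous", "inconsistent"


@dataclass
class OriginAssignedGenotypes:
    """Per-SNP (paternal, maternal) allele labels for one offspring.

    ``paternal``/``maternal`` are alternate-allele indicators (−1 where the
    label could not be assigned); ``status`` is per locus one of
    ``assigned`` / ``ambiguous`` / ``inconsistent``.  ``mapping`` records, per
    chromosome group, which input haplotype (0/1) was deemed paternal
    (−1 = undecided).
    """

    paternal: np.ndarray
    maternal: np.ndarray
    status: np.ndarray
    mapping: dict[object, int]

    def assigned_mask(self) -> np.ndarray:
        return self.status == ASSIGNED


def _can_supply(parent_dosage: np.ndarray, allele: np.ndarray) -> np.ndarray:
    """Whether a parent with the given dosage can transmit the given allele."""
    return np.where(allele == 1, parent_dosage > 0, parent_dosage < 2)


def assign_origin(offspring_haplotypes: np.ndarray,
                  father_dosage: np.ndarray | None,
                  mother_dosage: np.ndarray | None,
                  chrom: np.ndarray | None = None,
                  min_margin: int = 1) -> OriginAssignedGenotypes:
    """Label offspring alleles as paternal/maternal by haplotype voting.

    Parameters
    ----------
    offspring_haplotypes:
        ``(m, 2)`` array of phased alternate-allele indicators; the column
        order is arbitrary (that is what gets resolved).
    father_dosage, mother_dosage:
        Length-m 0/1/2 dosage vectors; at most one may be ``None`` (duo).
    chrom:
        Optional per-locus chromosome labels; the haplotype-to-parent vote is
        taken independently within each chromosome (phase is only consistent
        within a chromosome).
    min_margin:
        Minimum winning margin of informative-locus votes for a mapping to be
        accepted; below it the chromosome is left ambiguous.
    """
    haps = np.asarray(offspring_haplotypes)
    m = haps.shape[0]
    if haps.shape != (m, 2):
        raise ValueError("offspring haplotypes must have shape (m, 2)")
    if father_dosage is None and mother_dosage is None:
        raise ValueError("at least one parent must be genotyped")
    h0, h1 = haps[:, 0].astype(np.int8), haps[:, 1].astype(np.int8)
    ones = np.ones(m, dtype=bool)

    def _can(parent, allele):
        return ones if parent is None else _can_supply(np.asarray(parent), allele)

    # mapping 0: hap0 -> father;  mapping 1: hap1 -> father
    compat0 = _can(father_dosage, h0) & _can(mother_dosage, h1)
    compat1 = _can(father_dosage, h1) & _can(mother_dosage, h0)
    het = h0 != h1
    informative = het & (compat0 ^ compat1)

    groups = np.zeros(m, dtype=object) if chrom is None else np.asarray(chrom)
    paternal = np.full(m, -1, dtype=np.int8)
    maternal = np.full(m, -1, dtype=np.int8)
    status = np.full(m, AMBIGUOUS, dtype=object)
    mapping: dict[object, int] = {}

    for g in pd.unique(groups):
        sel = groups == g
        votes0 = int(np.sum(sel & informative & compat0))
        votes1 = int(np.sum(sel & informative & compat1))
        if votes0 + votes1 == 0 or abs(votes0 - votes1) < min_margin:
            mapping[g] = -1
            chosen = None
        else:
            chosen = 0 if votes0 > votes1 else 1
            mapping[g] = chosen
        hom = sel & ~het
        # homozygous loci are labelled trivially whatever the mapping
        paternal[hom] = h0[hom]
        maternal[hom] = h0[hom]
        status[hom] = ASSIGNED
        bad = sel & ~compat0 & ~compat1  # Mendelian violation either way
        status[bad] = INCONSISTENT
        paternal[bad] = -1
        maternal[bad] = -1
        if chosen is None:
            continue
        compat_chosen = compat0 if chosen == 0 else compat1
        ok = sel & het & compat_chosen
        pat = h0 if chosen == 0 else h1
        mat = h1 if chosen == 0 else h0
        paternal[ok] = pat[ok]
        maternal[ok] = mat[ok]
        status[ok] = ASSIGNED
        # loci that contradict the voted mapping would violate Mendelian
        # inheritance if labelled under it: flag, do not assign
        lone = sel & het & ~compat_chosen & (compat0 | compat1)
        status[lone] = INCONSISTENT
    return OriginAssignedGenotypes(paternal, maternal, status, mapping)


def origin_accuracy(assigned: OriginAssignedGenotypes,
                    truth_paternal: np.ndarray,
                    truth_maternal: np.ndarray) -> float:
    """Fraction of assigned genotype labels matching simulation truth.

    Ambiguous and inconsistent loci are excluded; with no assigned loci the
    accuracy is undefined and reported as NaN.
    """
    mask = assigned.assigned_mask()
    if not mask.any():
        return float("nan")
    ok = ((assigned.paternal[mask] == np.asarray(truth_paternal)[mask])
          & (assigned.maternal[mask] == np.asarray(truth_maternal)[mask]))
    return float(np.mean(ok))


def assign_origin_dataset(genotypes: PhasedGenotypes, pedigree: Pedigree,
                          min_margin: int = 1
                          ) -> dict[str, OriginAssignedGenotypes]:
    """Assign allele origins for every offspring with >= 1 genotyped parent.

    ``genotypes`` is taken at face value (haplotype order arbitrary, e.g.
    after :meth:`PhasedGenotypes.scrambled_phase`); parental genotypes are
    used as unphased dosages, honouring the pedigree's ``genotyped`` flags.
    """
    dos = genotypes.dosages()
    chrom = genotypes.variants["chrom"].to_numpy()
    genotyped = dict(zip(pedigree.table["iid"], pedigree.table["genotyped"]))
    out: dict[str, OriginAssignedGenotypes] = {}
    for _, row in pedigree.table.iterrows():
        iid = row["iid"]
        fa, mo = pedigree.parents_of(iid)
        fa_d = dos[pedigree.index_of(fa)] if fa and genotyped.get(fa) else None
        mo_d = dos[pedigree.index_of(mo)] if mo and genotyped.get(mo) else None
        if fa_d is None and mo_d is None:
            continue
        haps = genotypes.haplotypes[pedigree.index_of(iid)]
        out[iid] = assign_origin(haps, fa_d, mo_d, chrom=chrom,
                                 min_margin=min_margin)
    return out


def dataset_accuracy(assigned: dict[str, OriginAssignedGenotypes],
                     truth: PhasedGenotypes, pedigree: Pedigree) -> float:
    """Pooled genotype-level accuracy of a dataset assignment vs truth.

    ``truth`` must carry haplotypes in true (paternal, maternal) order, as
    produced by the simulator before phase scrambling.
    """
    n_ok = n_tot = 0
    for iid, a in assigned.items():
        i = pedigree.index_of(iid)
        mask = a.assigned_mask()
        if not mask.any():
            continue
        ok = ((a.paternal[mask] == truth.haplotypes[i, mask, 0])
              & (a.maternal[mask] == truth.haplotypes[i, mask, 1]))
        n_ok += int(ok.sum())
        n_tot += int(mask.size - (~mask).sum())
    return float("nan") if n_tot == 0 else n_ok / n_tot
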