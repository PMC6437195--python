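"""Readers and writers for the plain-text interchange formats.

Pedigrees travel as PLINK-style FAM text, phased genotypes as VCF 4.2 (GT
``pat|mat`` — the left allele is paternal by package convention, recorded in
the header), phenotypes as TSV keyed by individual id, relationship matrices
as GCTA-style triplets (see :mod:`poekit.relmat`), and regions as BED
(0-based half-open on disk, converted to 1-based inclusive internally).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GenomicRegionSet
from .simulate import Pedigree, PhasedGenotypes


class FormatError(ValueError):
    """Malformed input file; the message names the offending record."""


# ---------------------------------------------------------------------------
# FAM
# ---------------------------------------------------------------------------

def write_fam(pedigree: Pedigree, path: str | Path) -> None:
    """FID IID PAT MAT SEX PHENO; phenotype column fixed at -9 (missing)."""
    with open(path, "w") as fh:
        for _, r in pedigree.table.iterrows():
            fh.write(f"{r['fid']} {r['iid']} {r['father']} {r['mother']} "
                     f"{r['sex']} -9\n")


def read_fam(path: str | Path, genotyped: dict[str, bool] | None = None
             ) -> Pedigree:
    rows = []
    for ln, line in enumerate(open(path), start=1):
        parts = line.split()
        if len(parts) < 5:
            raise FormatError(f"{path}:{ln}: expected >= 5 FAM fields")
        fid, iid, fa, mo, sex = parts[:5]
        try:
            sex = int(sex)
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: non-integer sex {parts[4]!r}") from err
        gt = True if genotyped is None else genotyped.get(iid, True)
        rows.append((fid, iid, fa, mo, sex, gt))
    return Pedigree(pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "genotyped"]))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(genotypes: PhasedGenotypes, path: str | Path) -> None:
    """Phased VCF 4.2; left GT allele is the paternal one by convention."""
    v = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##phasing=full\n")
        fh.write("##poekit_convention=left GT allele is paternal\n")
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        haps = genotypes.haplotypes
        for s in range(len(v)):
            row = v.iloc[s]
            gts = "\t".join(f"{haps[i, s, 0]}|{haps[i, s, 1]}"
                            for i in range(genotypes.n_samples))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, require_phased: bool = True) -> PhasedGenotypes:
    """Read a biallelic VCF into a PhasedGenotypes container (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos, ids, ref, alt = [], [], [], [], []
    hap_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"{path}: {rec.CHROM}:{rec.POS} is not biallelic")
        g = np.array(rec.genotypes)  # (n, 3): allele0, allele1, phased flag
        if require_phased and not g[:, 2].all():
            bad = samples[int(np.flatnonzero(~g[:, 2].astype(bool))[0])]
            raise FormatError(
                f"{path}: unphased genotype at {rec.CHROM}:{rec.POS} "
                f"(sample {bad}); phased GT required")
        if (g[:, :2] < 0).any():
            raise FormatError(f"{path}: missing genotype at {rec.CHROM}:{rec.POS}")
        hap_rows.append(g[:, :2].astype(np.int8))
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    haps = (np.stack(hap_rows, axis=1) if hap_rows
            else np.zeros((len(samples), 0, 2), dtype=np.int8))
    dos = haps.sum(axis=2)
    freq = dos.mean(axis=0) / 2 if len(pos) else np.array([])
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "id": ids,
                             "ref": ref, "alt": alt,
                             "maf": np.minimum(freq, 1 - freq)})
    return PhasedGenotypes(samples, variants, haps)


# ---------------------------------------------------------------------------
# Phenotype / trait tables and BED
# ---------------------------------------------------------------------------

def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Individuals x variables TSV with an ``iid`` index column."""
    table.to_csv(path, sep="\t", index_label="iid", float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="iid")
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def read_bed(path: str | Path, source: str = "") -> GenomicRegionSet:
    """BED (0-based half-open) -> 1-based inclusive GenomicRegionSet."""
    rows = []
    for ln, line in enumerate(open(path), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: expected >= 3 BED fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as err:
            raise FormatError(f"{path}:{ln}: non-integer coordinates") from err
        rows.append((parts[0], start + 1, end,
                     parts[3] if len(parts) > 3 else f"region{ln}"))
    return GenomicRegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
        source or str(path))


def write_bed(regions: GenomicRegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in regions.regions.iterrows():
            name = r["name"] if "name" in regions.regions.columns else "."
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{name}\n")


def check_id_alignment(**tables) -> None:
    """Validate that all inputs cover identical individual ids.

    ``tables`` maps a label to a list of ids; raises listing the offending
    ids per table on mismatch.
    """
    sets = {name: set(ids) for name, ids in tables.items()}
    union = set.union(*sets.values())
    inter = set.intersection(*sets.values())
    if union != inter:
        msgs = []
        for name, s in sets.items():
            missing = sorted(union - s)
            if missing:
                msgs.append(f"{name} missing {missing[:5]}"
                            + ("..." if len(missing) > 5 else ""))
        raise ValueError("individual ids do not align: " + "; ".join(msgs))


def write_origin_vcf(genotypes: PhasedGenotypes, path: str | Path,
                     status: dict[str, np.ndarray]) -> None:
    """VCF whose GT order is paternal|maternal with a per-genotype status tag."""
    v = genotypes.variants
    code = {"assigned": "A", "ambiguous": "U", "inconsistent": "X"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##poekit_convention=left GT allele is paternal\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PO,Number=1,Type=String,'
                 'Description="Parent-of-origin status: A/U/X">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        haps = genotypes.haplotypes
        for s in range(len(v)):
            row = v.iloc[s]
            cells = []
            for i, iid in enumerate(genotypes.samples):
                st = code.get(str(status[iid][s]), "U") if iid in status else "U"
                cells.append(f"{haps[i, s, 0]}|{haps[i, s, 1]}:{st}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT:PO\t" + "\t".join(cells) + "\n")
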