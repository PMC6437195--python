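"""End-to-end pipeline driver tying all analysis stages together.

Stages: simulate -> relmat -> scan -> origin -> mqtl -> ewas -> phewas ->
enrich.  Each stage reads only files written by earlier stages, logs its
parameters and row counts, and writes TSV outputs into the run directory;
a manifest records the configuration hash and per-stage row counts so a rerun
with the same config and seed is byte-identical.  All randomness flows from
one root seed, expanded deterministically per stage, so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrich, io, mqtl, origin, relmat, scan, simulate, traits

log = logging.getLogger("poekit")

STAGES = ("simulate", "relmat", "scan", "origin", "mqtl", "ewas", "phewas",
          "enrich")


@dataclass
class PipelineConfig:
    """Plain-text configuration for a full pipeline run."""

    seed: int = 1
    n_families: int = 50
    offspring_per_family: int = 2
    n_snps: int = 200
    n_cpgs: int = 20
    n_traits: int = 6
    maf_min: float = 0.05
    maf_max: float = 0.5
    poe_fraction: float = 0.2        # fraction of CpGs with a planted POE
    poe_effect_size: float = 0.8
    poe_model: str = "maternal_imprinting"
    k_threshold: float = 0.05
    fdr_q: float = 0.05
    alpha: float = 0.05
    clump_window: int = 250_000
    clump_r2: float = 0.1
    cis_window: int = 1_000_000
    trans_distance: int = 5_000_000
    permutations: int = 10
    stages: dict[str, bool] = field(default_factory=lambda: {s: True
                                                             for s in STAGES})

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.fdr_q <= 1, "fdr_q"), (0 < self.alpha <= 1, "alpha"),
            (0 <= self.clump_r2 <= 1, "clump_r2"),
            (0 < self.cis_window <= self.trans_distance, "cis/trans distances"),
            (self.permutations >= 1, "permutations"),
            (0.01 <= self.maf_min <= self.maf_max <= 0.5, "maf range"),
            (0 <= self.poe_fraction <= 1, "poe_fraction"),
        ]
        for ok, name in checks:
            if not ok:
                raise simulate.ConfigurationError(f"invalid value for {name}")

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGES.index(stage) * 101) % (2 ** 31)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
            .encode()).hexdigest()[:16]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}, produced by stage "
            f"'{stage}', which did not run (toggled off or failed)")
    return path


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 resume: bool = False) -> Path:
    """Execute the configured stages into ``outdir``; returns the directory.

    With ``resume=True`` stages whose outputs already exist are skipped, so a
    failed run can be restarted from its checkpoint.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"config_hash": config.digest(), "seed": config.seed,
                "stages": {}}
    enabled = {s: config.stages.get(s, True) for s in STAGES}

    def _done(stage: str, *rowcounts: tuple[str, int]) -> None:
        manifest["stages"][stage] = {"seed": config.stage_seed(stage),
                                     "rows": dict(rowcounts)}
        log.info("stage %s done: %s", stage, dict(rowcounts))

    # -- simulate -----------------------------------------------------------
    if enabled["simulate"] and not (resume and (out / "meth.tsv").exists()):
        seed = config.stage_seed("simulate")
        spec = simulate.PedigreeSpec(
            n_families=config.n_families,
            offspring_per_family=config.offspring_per_family, seed=seed)
        ped = simulate.simulate_pedigree(spec)
        geno = simulate.simulate_genotypes(
            ped, config.n_snps, (config.maf_min, config.maf_max), seed=seed + 1)
        rng = np.random.default_rng(seed + 2)
        n_poe = int(round(config.poe_fraction * config.n_cpgs))
        causal = rng.choice(config.n_snps, size=n_poe, replace=False)
        plans, truth = [], []
        for i in range(config.n_cpgs):
            if i < n_poe:
                plan = simulate.EffectPlan(poe_model=config.poe_model,
                                           causal_snp=int(causal[i]),
                                           poe_effect_size=config.poe_effect_size,
                                           seed=seed + 10 + i)
            else:
                plan = simulate.EffectPlan(seed=seed + 10 + i)
            plans.append(plan)
            truth.append({"cpg": f"cpg{i}", "poe_model": plan.poe_model,
                          "causal_snp": int(plan.causal_snp)})
        factors = simulate.CovarianceFactors(ped, geno)
        meth = simulate.simulate_methylome(ped, geno, plans, factors)
        # CpG coordinates: near their causal SNP for planted sites
        pos_rows = []
        v = geno.variants
        for i in range(config.n_cpgs):
            if i < n_poe:
                s = int(causal[i])
                pos_rows.append((v.iloc[s]["chrom"], int(v.iloc[s]["pos"]) + 5000))
            else:
                s = int(rng.integers(config.n_snps))
                pos_rows.append((v.iloc[s]["chrom"], int(v.iloc[s]["pos"]) + 5000))
        cpg_pos = pd.DataFrame(pos_rows, columns=["chrom", "pos"],
                               index=meth.columns)
        trait_tab = simulate.simulate_traits(ped, config.n_traits,
                                             seed=seed + 3)
        io.write_fam(ped, out / "pedigree.fam")
        ped.table.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        io.write_vcf(geno, out / "genotypes.vcf")
        io.write_phenotypes(meth, out / "meth.tsv")
        cpg_pos.to_csv(out / "cpg_positions.tsv", sep="\t", index_label="cpg")
        io.write_phenotypes(trait_tab, out / "traits.tsv")
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump({"cpgs": truth}, fh, sort_keys=True)
        _done("simulate", ("individuals", ped.n), ("snps", geno.n_snps),
              ("cpgs", config.n_cpgs))

    # -- shared inputs ------------------------------------------------------
    def _load_ped() -> simulate.Pedigree:
        t = pd.read_csv(_require(out / "pedigree.tsv", "simulate", "relmat"),
                        sep="\t", dtype={"fid": str, "iid": str, "father": str,
                                         "mother": str})
        return simulate.Pedigree(t)

    # -- relmat -------------------------------------------------------------
    if enabled["relmat"] and not (resume and (out / "G.grm.gz").exists()):
        ped = _load_ped()
        geno = io.read_vcf(_require(out / "genotypes.vcf", "simulate", "relmat"))
        mats = relmat.build_all_matrices(ped, geno, config.k_threshold)
        for kind in ("G", "K"):
            relmat.write_grm_triplets(mats[kind], out / kind)
        for kind in relmat.INDICATOR_KINDS:
            relmat.write_matrix_tsv(mats[kind], out / f"{kind}.tsv")
        _done("relmat", ("matrices", len(mats)))

    def _load_matrices() -> dict[str, relmat.RelationshipMatrix]:
        mats = {}
        for k in ("G", "K"):
            _require(out / f"{k}.grm.gz", "relmat", "scan")
            mats[k] = relmat.read_grm_triplets(out / k, k)
        for kind in relmat.INDICATOR_KINDS:
            mats[kind] = relmat.read_matrix_tsv(
                _require(out / f"{kind}.tsv", "relmat", "scan"), kind)
        return mats

    # -- scan ---------------------------------------------------------------
    if enabled["scan"] and not (resume and (out / "scan.tsv").exists()):
        meth = io.read_phenotypes(_require(out / "meth.tsv", "simulate", "scan"))
        mats = _load_matrices()
        records = scan.poe_scan(meth, mats, fdr_q=config.fdr_q)
        tab = scan.scan_records_frame(records)
        tab.to_csv(out / "scan.tsv", sep="\t", index=False)
        _done("scan", ("cpgs", len(tab)),
              ("significant", int(tab["significant"].sum())))

    # -- origin -------------------------------------------------------------
    if enabled["origin"] and not (resume and (out / "origin.tsv").exists()):
        ped = _load_ped()
        geno = io.read_vcf(_require(out / "genotypes.vcf", "simulate", "origin"))
        scrambled, _ = geno.scrambled_phase(config.stage_seed("origin"))
        assigned = origin.assign_origin_dataset(scrambled, ped)
        acc = origin.dataset_accuracy(assigned, geno, ped)
        rows = [{"iid": iid,
                 "assigned": int(a.assigned_mask().sum()),
                 "ambiguous": int((a.status == origin.AMBIGUOUS).sum()),
                 "inconsistent": int((a.status == origin.INCONSISTENT).sum())}
                for iid, a in sorted(assigned.items())]
        pd.DataFrame(rows).to_csv(out / "origin.tsv", sep="\t", index=False)
        pat = pd.DataFrame({iid: a.paternal for iid, a in assigned.items()},
                           index=geno.variants["id"])
        mat = pd.DataFrame({iid: a.maternal for iid, a in assigned.items()},
                           index=geno.variants["id"])
        pat.T.to_csv(out / "origin_paternal.tsv", sep="\t", index_label="iid")
        mat.T.to_csv(out / "origin_maternal.tsv", sep="\t", index_label="iid")
        with open(out / "origin_accuracy.json", "w") as fh:
            json.dump({"genotype_accuracy": acc}, fh)
        _done("origin", ("offspring", len(rows)))

    # -- mqtl ---------------------------------------------------------------
    if enabled["mqtl"] and not (resume and (out / "mqtl.tsv").exists()):
        meth = io.read_phenotypes(_require(out / "meth.tsv", "simulate", "mqtl"))
        cpg_pos = pd.read_csv(_require(out / "cpg_positions.tsv", "simulate",
                                       "mqtl"), sep="\t", index_col="cpg")
        geno = io.read_vcf(out / "genotypes.vcf")
        pat = pd.read_csv(out / "origin_paternal.tsv", sep="\t", index_col="iid")
        mat = pd.read_csv(out / "origin_maternal.tsv", sep="\t", index_col="iid")
        scan_tab = pd.read_csv(_require(out / "scan.tsv", "scan", "mqtl"),
                               sep="\t")
        candidates = list(scan_tab.loc[scan_tab["significant"], "cpg"])
        if not candidates:
            candidates = list(meth.columns[:5])
        mats = _load_matrices()
        offspring = [i for i in pat.index if i in meth.index]
        pat = pat.loc[offspring]
        mat = mat.loc[offspring]
        sub = meth.loc[offspring]
        order = [meth.index.get_loc(i) for i in offspring]
        g_sub = relmat.RelationshipMatrix(
            mats["G"].values[np.ix_(order, order)], "G", offspring)
        rng = np.random.default_rng(config.stage_seed("mqtl"))
        rows, obs_p, perm_p = [], [], [[] for _ in range(config.permutations)]
        perm_orders = [rng.permutation(len(offspring))
                       for _ in range(config.permutations)]
        snp_ids = list(geno.variants["id"])
        for cpg in candidates:
            y = scan.pre_correct(sub[cpg].to_numpy(), matrices=[g_sub])
            cchrom = cpg_pos.loc[cpg, "chrom"]
            cpos = int(cpg_pos.loc[cpg, "pos"])
            for s, snp in enumerate(snp_ids):
                codings = mqtl.encode_poe(pat[snp].to_numpy(),
                                          mat[snp].to_numpy())
                rec = mqtl.poe_regression(y, codings, snp=snp, phenotype_id=cpg)
                if rec.flagged:
                    continue
                rec.cis_trans = mqtl.classify_cis_trans(
                    geno.variants.iloc[s]["chrom"], geno.variants.iloc[s]["pos"],
                    cchrom, cpos, config.cis_window, config.trans_distance)
                rows.append(rec)
                obs_p.append(rec.p["poe"])
                for r, order_ in enumerate(perm_orders):
                    prec = mqtl.poe_regression(y[order_], codings)
                    if not prec.flagged:
                        perm_p[r].append(prec.p["poe"])
        threshold = mqtl.permutation_fdr(obs_p, perm_p, q=config.fdr_q) \
            if obs_p else None
        tab = pd.DataFrame([
            {"snp": r.snp, "cpg": r.phenotype, "class": r.cis_trans, "n": r.n,
             "beta_add": r.beta.get("add", np.nan),
             "beta_dom": r.beta.get("dom", np.nan),
             "beta_poe": r.beta.get("poe", np.nan),
             "p_add": r.p.get("add", np.nan), "p_dom": r.p.get("dom", np.nan),
             "p_poe": r.p.get("poe", np.nan),
             "significant": (threshold is not None
                             and r.p.get("poe", 1.0) <= threshold)}
            for r in rows])
        tab.to_csv(out / "mqtl.tsv", sep="\t", index=False)
        sig = tab[tab["significant"]] if len(tab) else tab
        if len(sig):
            dos = geno.dosages()
            sidx = [snp_ids.index(s) for s in sig["snp"]]
            r2 = mqtl.genotype_r2(dos[:, sidx])
            vpos = geno.variants.iloc[sidx]
            assignment = mqtl.clump(vpos["pos"].to_numpy(),
                                    sig["p_poe"].to_numpy(), r2,
                                    chrom=vpos["chrom"].to_numpy(),
                                    window=config.clump_window,
                                    r2_cut=config.clump_r2)
            clumps = pd.DataFrame({"snp": sig["snp"].to_numpy(),
                                   "cpg": sig["cpg"].to_numpy(),
                                   "index_snp": [sig["snp"].to_numpy()[a]
                                                 for a in assignment]})
        else:
            clumps = pd.DataFrame(columns=["snp", "cpg", "index_snp"])
        clumps.to_csv(out / "clumps.tsv", sep="\t", index=False)
        with open(out / "mqtl_threshold.json", "w") as fh:
            json.dump({"poe_p_threshold": threshold}, fh)
        _done("mqtl", ("tests", len(tab)),
              ("significant", int(tab["significant"].sum()) if len(tab) else 0))

    # -- ewas ---------------------------------------------------------------
    if enabled["ewas"] and not (resume and (out / "ewas.tsv").exists()):
        trait_tab = io.read_phenotypes(_require(out / "traits.tsv", "simulate",
                                                "ewas"))
        meth = io.read_phenotypes(out / "meth.tsv")
        recs = traits.ewas(trait_tab, meth, alpha=config.alpha)
        pd.DataFrame([dataclasses.asdict(r) for r in recs]).to_csv(
            out / "ewas.tsv", sep="\t", index=False)
        _done("ewas", ("tests", len(recs)))

    # -- phewas -------------------------------------------------------------
    if enabled["phewas"] and not (resume and (out / "phewas.tsv").exists()):
        trait_tab = io.read_phenotypes(out / "traits.tsv")
        pat = pd.read_csv(_require(out / "origin_paternal.tsv", "origin",
                                   "phewas"), sep="\t", index_col="iid")
        mat = pd.read_csv(out / "origin_maternal.tsv", sep="\t", index_col="iid")
        mq = pd.read_csv(_require(out / "mqtl.tsv", "mqtl", "phewas"), sep="\t")
        snps = list(pd.unique(mq.loc[mq["significant"], "snp"]))[:20] \
            if len(mq) else []
        offspring = [i for i in pat.index if i in trait_tab.index]
        codings = {s: mqtl.encode_poe(pat.loc[offspring, s].to_numpy(),
                                      mat.loc[offspring, s].to_numpy())
                   for s in snps}
        recs = traits.phewas(trait_tab.loc[offspring], codings,
                             alpha=config.alpha) if codings else []
        pd.DataFrame([{"snp": r.snp, "trait": r.phenotype,
                       "beta_poe": r.beta.get("poe", np.nan),
                       "p_poe": r.p.get("poe", np.nan), "tier": r.tier}
                      for r in recs]).to_csv(out / "phewas.tsv", sep="\t",
                                             index=False)
        _done("phewas", ("tests", len(recs)))

    # -- enrich -------------------------------------------------------------
    if enabled["enrich"] and not (resume and (out / "enrich.tsv").exists()):
        with open(_require(out / "truth.yaml", "simulate", "enrich")) as fh:
            truth = yaml.safe_load(fh)["cpgs"]
        geno = io.read_vcf(out / "genotypes.vcf")
        cpg_pos = pd.read_csv(out / "cpg_positions.tsv", sep="\t",
                              index_col="cpg")
        scan_tab = pd.read_csv(_require(out / "scan.tsv", "scan", "enrich"),
                               sep="\t")
        regions = enrich.GenomicRegionSet(pd.DataFrame(
            [{"chrom": geno.variants.iloc[t["causal_snp"]]["chrom"],
              "start": max(1, int(geno.variants.iloc[t["causal_snp"]]["pos"])
                           - 10_000),
              "end": int(geno.variants.iloc[t["causal_snp"]]["pos"]) + 10_000}
             for t in truth if t["poe_model"] != "none"]), "planted")
        io.write_bed(enrich.GenomicRegionSet(
            regions.regions.assign(name="planted"), "planted"),
            out / "regions.bed")
        classes = enrich.classify_sites(cpg_pos, regions)
        target = scan_tab.set_index("cpg")["significant"].reindex(
            cpg_pos.index).fillna(False).to_numpy(dtype=bool)
        anno = (classes == enrich.REPLICATION).to_numpy()
        result = enrich.fisher_enrichment(target, anno, "planted_regions")
        pd.DataFrame({"cpg": cpg_pos.index, "distance_class": classes.to_numpy(),
                      "scan_significant": target}).to_csv(
            out / "enrich.tsv", sep="\t", index=False)
        with open(out / "enrichment.json", "w") as fh:
            json.dump({"odds_ratio": result.odds_ratio, "p": result.p,
                       "table": result.table.tolist()}, fh)
        _done("enrich", ("sites", len(cpg_pos)))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
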