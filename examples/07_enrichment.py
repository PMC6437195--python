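"""Distance classes against known regions and Fisher-exact enrichment.

Classifies candidate CpGs by distance to a reference set of imprinted-like
regions (replication < 2 kb, overlap 2 kb - 2 Mb, not identified > 2 Mb) and
tests whether hits are enriched near those regions.
"""

import numpy as np
import pandas as pd

from poekit import enrich

rng = np.random.default_rng(80)
regions = enrich.GenomicRegionSet(pd.DataFrame({
    "chrom": ["chr1", "chr1", "chr2"],
    "start": [1_000_000, 40_000_000, 8_000_000],
    "end": [1_050_000, 40_020_000, 8_100_000]}), source="reference")

# 200 background CpGs; "hits" concentrated near the regions
chroms = rng.choice(["chr1", "chr2"], size=200)
pos = rng.integers(1, 60_000_000, size=200)
is_hit = np.zeros(200, dtype=bool)
is_hit[:30] = True
pos[:20] = 1_000_000 + rng.integers(0, 50_000, size=20)  # inside region 1
sites = pd.DataFrame({"chrom": chroms, "pos": pos})
sites.loc[:19, "chrom"] = "chr1"

classes = enrich.classify_sites(sites, regions)
print("distance classes:", classes.value_counts().to_dict())

near = (classes == enrich.REPLICATION).to_numpy()
res = enrich.fisher_enrichment(is_hit, near, label="known_regions",
                               n_annotations=3)
print(f"2x2 table [[hit&near, hit&far], [bg&near, bg&far]]: "
      f"{res.table.tolist()}")
print(f"odds ratio (conditional MLE) = {res.odds_ratio:.1f} "
      f"(95% CI {res.ci_low:.1f}-{res.ci_high:.1f}), "
      f"Fisher p = {res.p:.2e}, Bonferroni-significant: "
      f"{res.bonferroni_significant}")
# Hits planted inside the reference regions give an odds ratio far above 1:
# the candidate set is enriched in previously identified territory.
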