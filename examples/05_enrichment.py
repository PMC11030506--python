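"""Fisher-exact enrichment: sex-specific OCRs inside sex-specific CRDs,
gene-set enrichment from a GMT, and XCI-escape-list overlap.
"""

import pandas as pd

from sexregulome.enrich import (fisher_enrichment, gene_set_enrichment,
                                ocr_in_crd_enrichment, xci_overlap)

# --- are sex-specific OCRs concentrated inside sex-specific CRDs?
ids = [f"ocr_{i}" for i in range(200)]
membership = pd.Series({ids[i]: ("crd_a" if i < 40 else "crd_b")
                        for i in range(100)})      # half the OCRs live in CRDs
sex_specific = pd.Series([i < 30 or i % 40 == 0 for i in range(200)], index=ids)
res = ocr_in_crd_enrichment(sex_specific, membership, {"crd_a"})
t = res.table
print(f"2x2 table a={t.a} b={t.b} c={t.c} d={t.d}")
print(f"odds ratio {res.odds_ratio:.2f}, Fisher p {res.p:.2e}")
# OR > 1: sex-specific OCRs are more likely inside the sex-specific CRD.

# --- gene-set enrichment over a toy GMT
planted = {f"HOX{i}" for i in range(15)}
universe = planted | {f"BG{i}" for i in range(200)}
gmt = {"planted_pathway": planted,
       "decoy_pathway": {f"BG{i}" for i in range(15)}}
for r in gene_set_enrichment(planted, universe, gmt, size_bounds=(10, 1000)):
    print(f"{r.term_id}: OR {r.odds_ratio:.1f}, p {r.p:.2e}, FDR {r.fdr:.2e}")

# --- overlap with an X-inactivation escape gene list
out = xci_overlap(
    {"neuronal": {"XIST", "JPX", "FIRRE", "KDM6A", "SYN1"},
     "non-neuronal": {"XIST", "FIRRE", "DDX3X", "GFAP"}},
    ["XIST", "JPX", "FIRRE", "KDM6A", "DDX3X", "EIF1AX"])
print(f"escape genes regulated: {out['overlap_counts']}, "
      f"shared across cell types: {out['n_shared']} {sorted(out['shared_genes'])}")
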