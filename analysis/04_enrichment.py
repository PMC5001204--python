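"""Pathway enrichment of the maximal module, focus terms and key genes.

Hypergeometric enrichment of the module genes against the scenario's gene
sets, keyword/top-KEGG focus-term selection, the key-gene union, the
one-level extension network with its degree >= 4 hubs, and the relative
abundance comparison between module genes and all SDGs.
"""

from pathlib import Path

import pandas as pd

from pinmod import diffexpr, enrichment, module_detection as md
from pinmod import network, synthetic

SEED = 17
OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sc = synthetic.generate_scenario(SEED)
    stats = diffexpr.de_test(sc.control, sc.treated)
    sdgs = diffexpr.select_sdgs(stats)
    rrpin = network.induce_subnetwork(sc.network, sdgs)
    module = md.fdr_scan(rrpin, stats,
                         truth=set(sc.truth.module_genes)).module

    rows = enrichment.hypergeometric_enrich(module.genes, sc.pathways)
    rows.to_csv(OUT / "04_enrichment.tsv", sep="\t", index=False,
                float_format="%.4g")
    planted = set(sc.truth.enriched_pathway_ids)
    top = rows.head(len(planted))
    print(f"pathways tested: {len(rows)}; planted enriched sets recovered in "
          f"top {len(planted)}: {len(set(top['name']) & planted)}/{len(planted)}")

    focal = enrichment.select_focus_terms(rows)
    print(f"focal terms ({len(focal)}): {focal}")
    term_genes = {t: sorted(set(module.genes) & sc.pathways.genes_of(t))
                  for t in focal}
    key = enrichment.extract_key_genes(focal, term_genes)
    (OUT / "04_key_genes.txt").write_text("".join(f"{g}\n" for g in sorted(key)))
    print(f"key genes: {len(key)}")

    ext = network.extension_network(rrpin, key, levels=1)
    hubs = network.find_hubs(ext, min_degree=4)
    print(f"extension network: {ext.number_of_nodes()} nodes / "
          f"{ext.number_of_edges()} edges; hubs (degree >= 4): {sorted(hubs)}")

    ra = pd.concat([
        enrichment.relative_abundance(module.genes, sc.pathways, focal)
        .assign(query="module"),
        enrichment.relative_abundance(sdgs, sc.pathways, focal)
        .assign(query="sdgs"),
    ])
    ra.to_csv(OUT / "04_relative_abundance.tsv", sep="\t", index=False,
              float_format="%.4g")
    wide = ra.pivot(index="pathway", columns="query", values="e_value")
    frac = (wide["module"] >= wide["sdgs"]).mean()
    print(f"relative abundance: module >= SDG concentration on "
          f"{frac:.0%} of focal terms")


if __name__ == "__main__":
    main()
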