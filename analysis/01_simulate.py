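"""Generate the default synthetic drug-response scenario and write its inputs.

A scale-free 2000-gene interaction network with a planted 30-gene connected
response module, two-condition log2 expression with 7 replicates per arm, a
334-miRNA panel (~6% significant, repressing module genes), and 50 pathway
gene sets of which 5 oversample the module. Everything downstream of this
script analyses exactly these files.
"""

import json
from pathlib import Path

from pinmod import enrichment, network, synthetic

SEED = 17
OUT = Path("results/analysis/01_inputs")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sc = synthetic.generate_scenario(SEED)

    network.write_network(sc.network, OUT / "network_edges.tsv")
    sc.control.rename_axis("gene").to_csv(OUT / "control.tsv", sep="\t",
                                          float_format="%.6g")
    sc.treated.rename_axis("gene").to_csv(OUT / "treated.tsv", sep="\t",
                                          float_format="%.6g")
    sc.mirna_stats.to_csv(OUT / "mirna_stats.tsv", sep="\t", index=False,
                          float_format="%.6g")
    pairs = sc.target_pairs.assign(
        sources=sc.target_pairs["sources"].apply(lambda s: ",".join(sorted(s)))
    )
    pairs.to_csv(OUT / "target_pairs.tsv", sep="\t", index=False)
    enrichment.write_gmt(sc.pathways, OUT / "pathways.gmt")
    (OUT / "truth.json").write_text(json.dumps({
        "module_genes": sorted(sc.truth.module_genes),
        "enriched_pathways": sc.truth.enriched_pathway_ids,
        "seed": SEED,
    }, indent=1))

    print(f"network: {sc.network.number_of_nodes()} genes, "
          f"{sc.network.number_of_edges()} interactions")
    print(f"planted module: {len(sc.truth.module_genes)} genes "
          f"({sum(1 for s in sc.truth.module_signs.values() if s > 0)} up)")
    print(f"miRNA panel: {len(sc.mirna_stats)} miRNAs, "
          f"{len(sc.truth.mirna_targets)} with planted module targets")
    print(f"pathways: {len(sc.pathways.sets)} sets, "
          f"{len(sc.truth.enriched_pathway_ids)} enriched for the module")
    print(f"inputs written to {OUT}")


if __name__ == "__main__":
    main()
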