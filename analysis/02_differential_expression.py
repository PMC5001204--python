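"""Differential expression and significant-gene selection.

Welch t-tests per gene between the treated and control arms of the
simulated scenario, then the loose uncorrected p < 0.01 filter that feeds
the network stage. Reports the funnel and how many planted module genes
survive.
"""

from pathlib import Path

from pinmod import diffexpr, synthetic

SEED = 17
OUT = Path("results/analysis")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sc = synthetic.generate_scenario(SEED)
    stats = diffexpr.de_test(sc.control, sc.treated)
    diffexpr.write_gene_stats(stats, OUT / "02_gene_stats.tsv")

    sdgs = diffexpr.select_sdgs(stats, alpha=0.01)
    (OUT / "02_sdgs.txt").write_text("".join(f"{g}\n" for g in sorted(sdgs)))

    truth = set(sc.truth.module_genes)
    print(f"genes tested: {len(stats)}")
    print(f"SDGs at p < 0.01 (uncorrected): {len(sdgs)}")
    print(f"planted module genes among SDGs: {len(truth & sdgs)}/{len(truth)}")
    bg = len(sdgs - truth)
    print(f"background false positives: {bg} "
          f"(expected ~{round(0.01 * (len(stats) - len(truth)))})")


if __name__ == "__main__":
    main()
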