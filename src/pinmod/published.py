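"""Loaders for the published rifampin-hepatocyte worked-example tables.

The package bundles the printed summary tables of the rifampin study it
re-implements — the top enriched GO/KEGG terms, the seven module-level
focal terms with their gene lists, the significant-miRNA panel, the
miRNA–gene edge table of the miRNA-regulated network, and the published
miRNA→function assignments. They serve as small worked-example inputs: the
underlying expression data were never deposited, so these tables are the
only recomputable anchors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_top_terms",
    "load_module_terms",
    "module_term_gene_map",
    "load_mirna_stats",
    "load_mirna_gene_edges",
    "load_mirna_functions",
]

# The panel table reports each miRNA's direction but not its magnitude;
# these nominal ratios encode direction only.
_NOMINAL_FC = {"up": 2.0, "down": 0.5}


def _read(name: str) -> pd.DataFrame:
    with resources.files("pinmod.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_top_terms() -> pd.DataFrame:
    """Top 20 GO / top 10 KEGG enrichment rows of the maximal module.

    Columns match the enrichment-row schema (``name``, ``category``,
    ``count``, ``percent``, ``p_value``, ``adjusted_p``).
    """
    df = _read("rifampin_top_terms.tsv")
    return df.rename(columns={"term": "name", "benjamini": "adjusted_p"})


def load_module_terms() -> pd.DataFrame:
    """The seven focal terms with their annotated module genes."""
    df = _read("rifampin_module_terms.tsv")
    df["genes"] = df["genes"].apply(lambda s: [g.strip() for g in s.split(",")])
    return df


def module_term_gene_map() -> dict[str, list[str]]:
    df = load_module_terms()
    return dict(zip(df["term"], df["genes"]))


def load_mirna_stats() -> pd.DataFrame:
    """The 20-row significant-miRNA panel (p-value and direction).

    A nominal fold change (2.0 up / 0.5 down) encodes the printed
    direction so the table satisfies the MirnaStats schema.
    """
    df = _read("rifampin_mirna_stats.tsv")
    df["fold_change"] = df["direction"].map(_NOMINAL_FC)
    return df[["mirna", "p_value", "fold_change", "direction"]]


def load_mirna_gene_edges() -> pd.DataFrame:
    """miRNA–gene edges of the published miRNA-regulated network."""
    return _read("rifampin_mirna_gene_edges.tsv")


def load_mirna_functions() -> dict[str, list[str]]:
    """Published term → miRNA-list assignments."""
    df = _read("rifampin_mirna_functions.tsv")
    return {
        row.term: [m.strip() for m in row.mirnas.split(",")]
        for row in df.itertuples(index=False)
    }
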