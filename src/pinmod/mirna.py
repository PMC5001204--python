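"""miRNA target integration and the miRNA-regulated interaction network.

Target pairs from several prediction/validation databases are merged (union
by default, with a minimum-source or required-source override), filtered to
significant miRNAs whose direction of change opposes their target gene's
log fold change (the anti-correlation rule, reflecting miRNA repression of
its targets), and assembled into a bipartite miRNA→gene network on top of
the gene–gene interactions of a functional module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .module_detection import Module

log = logging.getLogger(__name__)

__all__ = [
    "combine_target_sources",
    "is_anti_correlated",
    "MirnaPin",
    "build_mirna_pin",
    "assign_mirna_functions",
    "read_target_pairs",
    "write_mirna_pin_sif",
]


def read_target_pairs(path) -> pd.DataFrame:
    """Read a TSV of (mirna, gene, source) rows into a TargetPair table.

    Rows for the same (mirna, gene) pair are merged with a source-set
    union; gene symbols are upper-cased.
    """
    df = pd.read_csv(path, sep="\t")
    df["gene"] = df["gene"].str.strip().str.upper()
    df["sources"] = df["source"].apply(lambda s: frozenset({s.strip()}))
    return _dedupe(df[["mirna", "gene", "sources"]])


def _dedupe(pairs: pd.DataFrame) -> pd.DataFrame:
    grouped = (
        pairs.groupby(["mirna", "gene"], sort=True)["sources"]
        .apply(lambda col: frozenset().union(*col))
        .reset_index()
    )
    return grouped


def combine_target_sources(
    pairs: pd.DataFrame,
    min_sources: int = 1,
    required_sources=None,
) -> pd.DataFrame:
    """Merge duplicate pairs and filter by source support.

    A pair is retained when it is reported by at least ``min_sources``
    databases, or by any of ``required_sources`` (e.g. an experimentally
    validated database trumps the prediction-count requirement).
    """
    merged = _dedupe(pairs)
    required = set(required_sources or ())
    keep = merged["sources"].apply(
        lambda s: len(s) >= min_sources or bool(s & required)
    )
    return merged[keep].reset_index(drop=True)


def is_anti_correlated(gene_log_fc: float, mirna_fold_change: float) -> bool:
    """True when the miRNA's change opposes the gene's: repression pattern.

    An up-regulated miRNA (fold change > 1) paired with a down-regulated
    gene (log fold change < 0), or vice versa. Exactly-null values on
    either side never count as anti-correlated.
    """
    if mirna_fold_change <= 0:
        raise ValueError("miRNA fold change must be positive")
    return (gene_log_fc < 0 and mirna_fold_change > 1) or (
        gene_log_fc > 0 and mirna_fold_change < 1
    )


@dataclass(frozen=True)
class MirnaPin:
    """Bipartite miRNA→gene edges over a module's gene–gene interactions."""

    mirna_nodes: frozenset
    gene_nodes: frozenset
    bipartite_edges: frozenset  # (mirna, gene, direction)
    ppi_edges: frozenset


def build_mirna_pin(
    module: Module,
    ppi,
    sig_mirnas: pd.DataFrame,
    pairs: pd.DataFrame,
    gene_stats: pd.DataFrame,
    enforce_anticorrelation: bool = True,
    mirna_alpha: float = 0.05,
) -> MirnaPin:
    """Assemble the miRNA-regulated interaction network for a module.

    Retains target pairs whose gene belongs to the module, whose miRNA
    appears in ``sig_mirnas``, and (by default) which pass the
    anti-correlation rule. Gene nodes are the genes incident to at least
    one retained edge; the gene–gene edges are induced from ``ppi``.
    Entries of ``sig_mirnas`` with p-values above ``mirna_alpha`` are
    honoured but logged as violations of the significance filter rather
    than silently dropped, so a curated table can be audited.
    """
    sig = sig_mirnas.set_index("mirna")
    lax = sig[sig["p_value"] >= mirna_alpha]
    if len(lax):
        log.warning(
            "build_mirna_pin: %d supplied miRNAs have p >= %g: %s",
            len(lax), mirna_alpha, ", ".join(lax.index),
        )
    fc_map = dict(zip(sig.index, sig["fold_change"]))
    lfc_map = dict(zip(gene_stats["gene"], gene_stats["log_fc"]))

    retained = []
    for row in pairs.itertuples(index=False):
        if row.gene not in module.genes or row.mirna not in fc_map:
            continue
        fc = fc_map[row.mirna]
        lfc = lfc_map.get(row.gene)
        if enforce_anticorrelation:
            if lfc is None or not is_anti_correlated(lfc, fc):
                continue
        retained.append((row.mirna, row.gene, "up" if fc > 1 else "down"))

    genes = frozenset(g for _, g, _ in retained)
    mirnas = frozenset(m for m, _, _ in retained)
    ppi_edges = frozenset(
        tuple(sorted((u, v))) for u, v in ppi.subgraph(genes).edges
    )
    return MirnaPin(
        mirna_nodes=mirnas,
        gene_nodes=genes,
        bipartite_edges=frozenset(retained),
        ppi_edges=ppi_edges,
    )


def assign_mirna_functions(
    pin: MirnaPin, focal_terms, term_genes: dict
) -> dict[str, list[str]]:
    """Assign each miRNA the focal terms its retained targets annotate to.

    miRNA m gets term t iff some retained target gene of m belongs to
    term_genes[t]. miRNAs with no assigned term are omitted; term order
    follows ``focal_terms``; output is independent of edge order.
    """
    targets: dict[str, set] = {}
    for m, g, _ in pin.bipartite_edges:
        targets.setdefault(m, set()).add(g)
    out: dict[str, list[str]] = {}
    for m in sorted(targets):
        terms = [
            t for t in focal_terms
            if targets[m] & {x.strip().upper() for x in term_genes[t]}
        ]
        if terms:
            out[m] = terms
    return out


def write_mirna_pin_sif(pin: MirnaPin, path) -> None:
    """SIF export: ``pp`` gene–gene rows plus ``mt`` miRNA→gene rows."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(pin.ppi_edges):
            fh.write(f"{u}\tpp\t{v}\n")
        for m, g, _ in sorted(pin.bipartite_edges):
            fh.write(f"{m}\tmt\t{g}\n")
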