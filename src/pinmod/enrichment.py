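"""Local gene-set enrichment and key-gene extraction.

A hypergeometric over-representation test against user-supplied GMT gene
sets replaces web-service annotation tools: with a universe of M genes, a
pathway of K members and a query of n genes overlapping the pathway in x,
the enrichment p-value is the upper tail P(X >= x) of
Hypergeometric(M, K, n), Benjamini–Hochberg adjusted across all tested
pathways. Focus-term selection and the pathway relative-abundance statistic
E(i) = S(i)/N(i) — the fraction of a query gene set annotated to pathway i
— mirror the drug-response workflow this package implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrich",
    "select_focus_terms",
    "extract_key_genes",
    "relative_abundance",
]

CATEGORIES = ("GO_BP", "KEGG", "other")


@dataclass
class PathwayCollection:
    """Named gene sets with categories over a background universe."""

    sets: dict  # id -> (name, category, frozenset of genes)
    universe: frozenset

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        clean = {}
        for pid, (name, cat, genes) in self.sets.items():
            if cat not in CATEGORIES:
                cat = "other"
            clean[pid] = (name, cat, frozenset(genes) & self.universe)
        self.sets = clean

    def genes_of(self, pid) -> frozenset:
        return self.sets[pid][2]


def read_gmt(path, universe=None, category: str = "other") -> PathwayCollection:
    """Read a GMT file (one set per line: name, description, genes...).

    The description field may carry a category tag (``GO_BP``/``KEGG``);
    otherwise ``category`` applies to every set. Without an explicit
    universe the union of all sets is used.
    """
    sets = {}
    union = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, desc = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            cat = desc if desc in CATEGORIES else category
            sets[name] = (name, cat, genes)
            union |= genes
    return PathwayCollection(sets=sets, universe=universe or union)


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(pathways.sets):
            name, cat, genes = pathways.sets[pid]
            fh.write("\t".join([name, cat, *sorted(genes)]) + "\n")


def hypergeometric_enrich(query, pathways: PathwayCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in every pathway.

    Query genes outside the universe are dropped (logged). Returns one row
    per pathway — columns ``pathway``, ``name``, ``category``, ``count``,
    ``percent``, ``p_value``, ``adjusted_p`` — sorted by p-value (stable).
    """
    query = set(query)
    inside = query & pathways.universe
    if len(inside) < len(query):
        log.info("hypergeometric_enrich: dropped %d query genes outside universe",
                 len(query) - len(inside))
    if not inside:
        return pd.DataFrame(
            columns=["pathway", "name", "category", "count", "percent",
                     "p_value", "adjusted_p"]
        )
    M, n = len(pathways.universe), len(inside)
    rows = []
    for pid in sorted(pathways.sets):
        name, cat, genes = pathways.sets[pid]
        K = len(genes)
        x = len(inside & genes)
        p = float(stats.hypergeom.sf(x - 1, M, K, n)) if K else 1.0
        rows.append({
            "pathway": pid, "name": name, "category": cat, "count": x,
            "percent": 100.0 * x / n, "p_value": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def select_focus_terms(
    rows: pd.DataFrame,
    keywords=("drug", "metabolism"),
    top_kegg: int = 6,
) -> list[str]:
    """Focal terms: keyword-matching GO terms plus the best KEGG pathways.

    GO_BP rows whose name contains any keyword (case-insensitive) are
    combined with the ``top_kegg`` smallest-p KEGG rows (stable order on
    ties); duplicate names are eliminated, order preserved by p-value.
    """
    go = rows[rows["category"] == "GO_BP"]
    kw = [k.lower() for k in keywords]
    hits = go[go["name"].str.lower().apply(lambda s: any(k in s for k in kw))]
    kegg = (rows[rows["category"] == "KEGG"]
            .sort_values("p_value", kind="stable")
            .head(top_kegg))
    combined = pd.concat([hits, kegg]).sort_values("p_value", kind="stable")
    seen, out = set(), []
    for name in combined["name"]:
        if name not in seen:
            seen.add(name)
            out.append(name)
    return out


def extract_key_genes(focal_terms, term_genes: dict) -> set[str]:
    """Union of the focal terms' annotated gene lists, symbol-normalised."""
    missing = [t for t in focal_terms if t not in term_genes]
    if missing:
        raise KeyError(f"no gene list for focal terms: {missing}")
    out = set()
    for t in focal_terms:
        out.update(g.strip().upper() for g in term_genes[t])
    return out


def relative_abundance(
    query, pathways: PathwayCollection, focal_terms,
    per_pathway_denominator: bool = False,
) -> pd.DataFrame:
    """Pathway relative abundance E(i) = S(i)/N(i) per focal pathway.

    S(i) is the number of query genes annotated to pathway i. By default
    N(i) is the query-set size, so E(i) is the fraction of the query inside
    the pathway; ``per_pathway_denominator=True`` divides by the pathway
    size instead (coverage of the pathway by the query).
    """
    query = set(query)
    if not query:
        raise ValueError("relative abundance of an empty query is undefined")
    unknown = [t for t in focal_terms if t not in pathways.sets]
    if unknown:
        raise KeyError(f"focal terms not in pathway collection: {unknown}")
    rows = []
    for pid in focal_terms:
        genes = pathways.genes_of(pid)
        s = len(query & genes)
        n = len(genes) if per_pathway_denominator else len(query)
        rows.append({"pathway": pid, "s_count": s, "n_total": n,
                     "e_value": s / n if n else np.nan})
    return pd.DataFrame(rows)
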