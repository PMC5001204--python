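"""End-to-end pipeline: inputs (real or synthetic) to report, one seed.

The stage order mirrors the drug-response workflow: differential
statistics → significant-gene selection → response-network induction → BUM
fit and FDR scan → maximal module → multiple active modules → pathway
enrichment, focus terms and key genes → extension network and hubs →
relative abundance → miRNA filtering, target combination, the
miRNA-regulated network and miRNA function assignment. Every intermediate
is written as a TSV/SIF/JSON file and a manifest records the config, seed
and per-file checksums; identical config and seed give byte-identical
outputs.
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

from . import diffexpr, enrichment, mirna, module_detection, network, synthetic

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_report"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All thresholds and inputs of a pipeline run.

    Either ``synthetic=True`` (with optional ``scenario`` overrides) or the
    file inputs must be given. Threshold defaults are the study's: SDG
    p < 0.01 uncorrected, miRNA p < 0.05, module FDR 1e-4, five active
    modules at depth 2 with zero overlap, hubs at degree >= 4, focus
    keywords "drug"/"metabolism" with the top six KEGG pathways.
    """

    synthetic: bool = True
    scenario: dict = field(default_factory=dict)
    network_paths: list = field(default_factory=list)
    control_path: str | None = None
    treated_path: str | None = None
    gene_stats_path: str | None = None
    mirna_stats_path: str | None = None
    target_pairs_path: str | None = None
    gmt_path: str | None = None

    sdg_alpha: float = 0.01
    mirna_alpha: float = 0.05
    fdr: float = 1e-4
    fdr_grid: tuple = (1e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.05)
    size_band: tuple = (10, 300)
    n_modules: int = 5
    max_depth: int = 2
    overlap: float = 0.0
    hub_min_degree: int = 4
    keywords: tuple = ("drug", "metabolism")
    top_kegg: int = 6
    min_sources: int = 1
    required_sources: tuple = ()
    extension_levels: int = 1

    seed: int = 0
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 < self.sdg_alpha < 1 and 0 < self.mirna_alpha < 1):
            raise ValueError("significance thresholds must lie in (0,1)")
        if not all(0 < f < 1 for f in self.fdr_grid):
            raise ValueError("fdr_grid values must lie in (0,1)")
        if not self.synthetic and not (
            self.network_paths
            and (self.gene_stats_path or (self.control_path and self.treated_path))
        ):
            raise ValueError(
                "non-synthetic runs need network_paths and either gene stats "
                "or a pair of expression matrices"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_lines(items, path: Path) -> None:
    path.write_text("".join(f"{x}\n" for x in items), encoding="utf-8")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, type(exc).__name__, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write intermediates, return the result bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    # ----- inputs -----------------------------------------------------
    if config.synthetic:
        sc = _stage("synthetic")(synthetic.generate_scenario)(
            config.seed, **config.scenario
        )
        net = sc.network
        bundle["truth"] = sc.truth
        stats = _stage("de_test")(diffexpr.de_test)(sc.control, sc.treated)
        mirna_stats, raw_pairs, pathways = (
            sc.mirna_stats, sc.target_pairs, sc.pathways
        )
        truth_sidecar = {
            "module_genes": sorted(sc.truth.module_genes),
            "module_signs": {g: int(s) for g, s in sorted(sc.truth.module_signs.items())},
            "signal_params": list(sc.truth.signal_params),
            "enriched_pathways": list(sc.truth.enriched_pathway_ids),
            "mirna_targets": {m: sorted(t) for m, t in sorted(sc.truth.mirna_targets.items())},
            "seed": int(sc.truth.seed),
        }
        (out / "truth.json").write_text(
            json.dumps(truth_sidecar, indent=1, sort_keys=True), encoding="utf-8"
        )
    else:
        nets = [
            _stage("load_network")(network.read_edge_list)(p)
            for p in config.network_paths
        ]
        net = nets[0]
        for other in nets[1:]:
            net = network.merge_networks(net, other)
        if config.gene_stats_path:
            stats = _stage("load_stats")(diffexpr.read_gene_stats)(
                config.gene_stats_path
            )
        else:
            control = diffexpr.read_expression(config.control_path)
            treated = diffexpr.read_expression(config.treated_path)
            stats = _stage("de_test")(diffexpr.de_test)(control, treated)
        mirna_stats = (
            pd.read_csv(config.mirna_stats_path, sep="\t")
            if config.mirna_stats_path else None
        )
        raw_pairs = (
            mirna.read_target_pairs(config.target_pairs_path)
            if config.target_pairs_path else None
        )
        pathways = (
            enrichment.read_gmt(config.gmt_path) if config.gmt_path else None
        )
    bundle["network"] = net
    bundle["gene_stats"] = stats
    _write_tsv(stats.sort_values("gene", kind="stable"), out / "gene_stats.tsv")

    # ----- response network -------------------------------------------
    sdgs = _stage("select_sdgs")(diffexpr.select_sdgs)(stats, config.sdg_alpha)
    bundle["sdgs"] = sdgs
    _write_lines(sorted(sdgs), out / "sdgs.txt")
    rrpin = _stage("induce")(network.induce_subnetwork)(net, sdgs)
    bundle["rrpin"] = rrpin
    network.write_network(rrpin, out / "rrpin_edges.tsv", format="tsv_edges")
    log.info("funnel: %d genes -> %d SDGs -> response network %d nodes / %d edges",
             len(stats), len(sdgs), rrpin.number_of_nodes(), rrpin.number_of_edges())

    # ----- module detection -------------------------------------------
    fit = _stage("fit_bum")(module_detection.fit_bum)(stats["p_value"])
    bundle["bum_fit"] = fit
    (out / "bum_fit.json").write_text(json.dumps({
        "lambda_mix": round(fit.lambda_mix, 10),
        "a_shape": round(fit.a_shape, 10),
        "log_likelihood": round(fit.log_likelihood, 6),
        "n_points": fit.n_points,
    }, indent=1, sort_keys=True), encoding="utf-8")

    truth_genes = (
        set(bundle["truth"].module_genes) if "truth" in bundle else None
    )
    scan = _stage("fdr_scan")(module_detection.fdr_scan)(
        rrpin, stats, fit=fit, fdr_grid=config.fdr_grid,
        truth=truth_genes, size_band=config.size_band,
    )
    bundle["fdr_scan"] = scan
    _write_tsv(scan.rows, out / "fdr_scan.tsv")
    module = scan.module
    bundle["max_module"] = module
    scores = module_detection.score_nodes(rrpin, stats, fit, scan.fdr).scores
    mod_rows = stats[stats["gene"].isin(module.genes)].copy()
    mod_rows["score"] = mod_rows["gene"].map(scores)
    _write_tsv(mod_rows.sort_values("gene", kind="stable"),
               out / "max_module_genes.tsv")
    network.write_network(rrpin.subgraph(module.genes),
                          out / "max_module.sif", format="sif")

    actives = _stage("active_modules")(module_detection.active_modules)(
        rrpin, stats, n_modules=config.n_modules, max_depth=config.max_depth,
        overlap=config.overlap, seed=config.seed,
    )
    bundle["active_modules"] = actives
    _write_tsv(
        pd.DataFrame([
            {"module_id": i + 1, "gene": g,
             "calibrated_score": m.calibrated_score}
            for i, m in enumerate(actives) for g in sorted(m.genes)
        ]),
        out / "active_modules.tsv",
    )

    # ----- enrichment --------------------------------------------------
    focal, key_genes, abundance = [], set(), None
    if pathways is not None and module.size:
        rows = _stage("enrichment")(enrichment.hypergeometric_enrich)(
            module.genes, pathways
        )
        bundle["enrichment"] = rows
        _write_tsv(rows, out / "enrichment.tsv")
        focal = enrichment.select_focus_terms(
            rows, keywords=config.keywords, top_kegg=config.top_kegg
        )
        term_genes = {
            t: sorted(set(module.genes) & pathways.genes_of(t)) for t in focal
        }
        key_genes = enrichment.extract_key_genes(focal, term_genes)
        if key_genes:
            abundance_mod = enrichment.relative_abundance(
                module.genes, pathways, focal
            ).assign(query="module")
            abundance_sdg = enrichment.relative_abundance(
                sdgs, pathways, focal
            ).assign(query="sdgs") if sdgs else None
            abundance = pd.concat(
                [abundance_mod] + ([abundance_sdg] if abundance_sdg is not None else [])
            ).reset_index(drop=True)
            _write_tsv(abundance, out / "relative_abundance.tsv")
    bundle["focal_terms"] = focal
    bundle["key_genes"] = key_genes
    bundle["relative_abundance"] = abundance
    _write_lines(focal, out / "focal_terms.txt")
    _write_lines(sorted(key_genes), out / "key_genes.txt")

    # ----- extension network and hubs ---------------------------------
    ext = _stage("extension")(network.extension_network)(
        rrpin, key_genes or module.genes, levels=config.extension_levels
    )
    hubs = network.find_hubs(ext, min_degree=config.hub_min_degree)
    bundle["extension_network"] = ext
    bundle["hubs"] = hubs
    network.write_network(ext, out / "extension_network.tsv", format="tsv_edges")
    _write_lines(sorted(hubs), out / "hubs.txt")

    # ----- miRNA layer -------------------------------------------------
    mirna_functions: dict = {}
    pin = None
    if mirna_stats is not None and raw_pairs is not None and module.size:
        sig = _stage("select_mirnas")(diffexpr.select_significant_mirnas)(
            mirna_stats, alpha=config.mirna_alpha
        )
        _write_tsv(sig, out / "significant_mirnas.tsv")
        combined = mirna.combine_target_sources(
            raw_pairs, min_sources=config.min_sources,
            required_sources=config.required_sources,
        )
        pin = _stage("mirna_pin")(mirna.build_mirna_pin)(
            module, net, sig, combined, stats,
        )
        mirna.write_mirna_pin_sif(pin, out / "mirna_pin.sif")
        if focal and pathways is not None:
            term_gene_full = {t: sorted(pathways.genes_of(t)) for t in focal}
            mirna_functions = mirna.assign_mirna_functions(
                pin, focal, term_gene_full
            )
        _write_tsv(
            pd.DataFrame([
                {"term": t, "mirnas": ",".join(
                    m for m in sorted(mirna_functions) if t in mirna_functions[m]
                )}
                for t in focal
            ]) if focal else pd.DataFrame(columns=["term", "mirnas"]),
            out / "mirna_functions.tsv",
        )
    bundle["mirna_pin"] = pin
    bundle["mirna_functions"] = mirna_functions

    # ----- report and manifest ----------------------------------------
    report = write_report(bundle, out / "report.txt")
    bundle["report"] = report
    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name not in ("manifest.json",) and p.is_file()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    bundle["manifest"] = manifest
    return bundle


def _fmt_set(items) -> str:
    items = sorted(items)
    return ", ".join(items) if items else "none"


def write_report(bundle: dict, path=None) -> str:
    """Render the run's headline results as a plain-text summary."""
    cfg: PipelineConfig = bundle["config"]
    scan = bundle.get("fdr_scan")
    module = bundle.get("max_module")
    lines = [
        "drug-response module analysis",
        "=============================",
        f"seed: {cfg.seed}",
        "",
        f"genes tested: {len(bundle['gene_stats'])}",
        f"SDGs (p < {cfg.sdg_alpha}): {len(bundle['sdgs'])}",
        (f"response network: {bundle['rrpin'].number_of_nodes()} nodes / "
         f"{bundle['rrpin'].number_of_edges()} edges"),
        "",
        "FDR scan (fdr, module size, tp_rate, precision):",
    ]
    if scan is not None and len(scan.rows):
        for r in scan.rows.itertuples(index=False):
            tp = "-" if pd.isna(r.tp_rate) else f"{r.tp_rate:.3f}"
            pr = "-" if pd.isna(r.precision) else f"{r.precision:.3f}"
            lines.append(f"  {r.fdr:g}\t{r.module_size}\t{tp}\t{pr}")
        lines.append(f"selected FDR: {scan.fdr:g}")
    else:
        lines.append("  none")
    if module is not None:
        lines += [
            (f"maximal module: {module.size} genes / {len(module.edges)} "
             f"interactions, score {module.aggregate_score:.3f}"),
        ]
    actives = bundle.get("active_modules") or []
    lines.append(f"active modules: {len(actives)}")
    for i, m in enumerate(actives, 1):
        lines.append(
            f"  module {i}: {m.size} genes, calibrated score "
            f"{m.calibrated_score:.2f}"
        )
    lines += [
        "",
        f"focal terms: {_fmt_set(bundle.get('focal_terms') or [])}",
        f"key genes ({len(bundle.get('key_genes') or [])}): "
        f"{_fmt_set(bundle.get('key_genes') or [])}",
        f"hubs (degree >= {cfg.hub_min_degree}): {_fmt_set(bundle.get('hubs') or [])}",
        "",
        "miRNA functions:",
    ]
    funcs = bundle.get("mirna_functions") or {}
    if funcs:
        for m in sorted(funcs):
            lines.append(f"  {m}: {', '.join(funcs[m])}")
    else:
        lines.append("  none")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
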