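"""Planted-truth benchmarks: module recovery and null calibration.

These experiments run the full analysis chain on synthetic scenarios where
the answer is known, operationalising the true-positive-rate / precision
evaluation the module-size FDR scan is built around. They are shared by the
test suite, the acceptance script and the analysis drivers.
"""

from __future__ import annotations

import numpy as np

from . import diffexpr, enrichment, module_detection, network, synthetic

__all__ = [
    "planted_module_recovery",
    "null_calibration",
    "DEFAULT_FDR_GRID",
]

DEFAULT_FDR_GRID = (1e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.05)


def planted_module_recovery(
    seed: int,
    sdg_alpha: float = 0.01,
    fdr_grid=DEFAULT_FDR_GRID,
    **scenario_overrides,
) -> dict:
    """Run scenario → DE → SDG network → BUM scan, score vs planted truth.

    Returns the selected module's F1, true-positive rate and precision
    against the planted module, along with the fitted mixture parameters
    and funnel counts (SDGs, response-network size, module size).
    """
    sc = synthetic.generate_scenario(seed, **scenario_overrides)
    stats = diffexpr.de_test(sc.control, sc.treated)
    sdgs = diffexpr.select_sdgs(stats, alpha=sdg_alpha)
    rrpin = network.induce_subnetwork(sc.network, sdgs)
    fit = module_detection.fit_bum(stats["p_value"])
    scan = module_detection.fdr_scan(
        rrpin, stats, fit=fit, fdr_grid=fdr_grid,
        truth=set(sc.truth.module_genes),
    )
    best = scan.rows.loc[scan.rows["fdr"] == scan.fdr].iloc[0]
    return {
        "f1": float(best["f1"]),
        "tp_rate": float(best["tp_rate"]),
        "precision": float(best["precision"]),
        "selected_fdr": float(scan.fdr),
        "module_size": int(scan.module.size),
        "n_sdgs": len(sdgs),
        "rrpin_nodes": rrpin.number_of_nodes(),
        "rrpin_edges": rrpin.number_of_edges(),
        "lambda_mix": fit.lambda_mix,
        "a_shape": fit.a_shape,
        "truth_size": len(sc.truth.module_genes),
    }


def null_calibration(
    seed: int,
    sdg_alpha: float = 0.01,
    **scenario_overrides,
) -> dict:
    """Zero-signal scenario: type-I rates the pipeline should not exceed.

    With no expression effect and no enriched pathway, the DE stage should
    call about ``sdg_alpha`` of genes significant, and no focal term should
    survive BH adjustment at 0.05 in most runs.
    """
    overrides = dict(effect_logfc=0.0, enriched_sets=0)
    overrides.update(scenario_overrides)
    sc = synthetic.generate_scenario(seed, **overrides)
    stats = diffexpr.de_test(sc.control, sc.treated)
    de_rate = float((stats["p_value"] < sdg_alpha).mean())

    sdgs = diffexpr.select_sdgs(stats, alpha=sdg_alpha)
    result = {
        "de_rate": de_rate,
        "n_sdgs": len(sdgs),
        "focal_term_min_adj_p": float("nan"),
        "any_focal_term_enriched": False,
    }
    if sdgs:
        rows = enrichment.hypergeometric_enrich(sdgs, sc.pathways)
        focal = enrichment.select_focus_terms(rows)
        sub = rows[rows["name"].isin(focal)]
        if len(sub):
            min_adj = float(sub["adjusted_p"].min())
            result["focal_term_min_adj_p"] = min_adj
            result["any_focal_term_enriched"] = bool(min_adj < 0.05)
    return result


def bum_recovery(
    seed: int,
    lambda_mix: float = 0.7,
    a_shape: float = 0.2,
    n: int = 10_000,
) -> module_detection.BumFit:
    """Fit the mixture on a sample drawn from known (lambda, a)."""
    rng = np.random.default_rng(int(seed))
    signal = rng.random(n) >= lambda_mix
    p = rng.uniform(0.0, 1.0, size=n)
    p[signal] = rng.beta(a_shape, 1.0, size=int(signal.sum()))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return module_detection.fit_bum(p)
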