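"""End-to-end orchestration: correct -> characterise -> geometry-check ->
fit x scenarios -> diagnose -> aggregate -> report, driven by a YAML config.

The config must name every input table and a seed; refusing to run without a
seed is the reproducibility contract. All outputs land in a run directory:
corrected tables, a tidy statistics CSV, a mixing-polygon report per TEF
scenario, per-consumer posterior summaries, convergence JSONs, and a manifest
recording the config, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corrections import SuessConfig, apply_corrections, corrections_frame, read_offsets
from .data_io import GROUPS, read_samples
from .diagnostics import report_to_dict, run_until_converged
from .geometry import tef_plausibility
from .group_stats import pairwise_wilcoxon, kruskal_wallis, knnr_test, summarize_groups
from .simm import (MARINE_TERRESTRIAL, MCMCConfig, NAMED_SCENARIOS,
                   aggregate, fit_consumer, identifiability_check,
                   sources_from_summaries)

log = logging.getLogger("coastmix")


class ConfigError(ValueError):
    pass


def _require(config: dict, key: str):
    if key not in config:
        raise ConfigError(f"config is missing required key {key!r}")
    return config[key]


def _ladder_from_config(config: dict, seed: int) -> list[MCMCConfig]:
    rungs = config.get("mcmc_ladder") or [
        {"chain_length": 10_000, "burn_in": 5_000, "thin": 5, "n_chains": 3},
        {"chain_length": 50_000, "burn_in": 25_000, "thin": 25, "n_chains": 3},
        {"chain_length": 100_000, "burn_in": 50_000, "thin": 50, "n_chains": 3},
    ]
    return [MCMCConfig(seed=seed, **r) for r in rungs]


def run_pipeline(config_path, out_dir=None) -> Path:
    """Run the full workflow described by a YAML config; returns the run dir.

    Raises ConfigError on a malformed config and RuntimeError if any model
    ends non-converged and ``allow_nonconverged`` is not set.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    seed = int(_require(config, "seed"))
    out = Path(out_dir or config.get("out_dir") or config_path.parent / "coastmix_run")
    out.mkdir(parents=True, exist_ok=True)

    sources, src_errors = read_samples(_require(config, "sources"), "sources")
    consumers, con_errors = read_samples(_require(config, "consumers"), "consumers")
    if src_errors or con_errors:
        (out / "row_errors.json").write_text(json.dumps(
            [dataclasses.asdict(e) for e in src_errors + con_errors], indent=2))

    # --- corrections -------------------------------------------------------
    if config.get("atmosphere"):
        series = read_samples(config["atmosphere"], "atmosphere")
        offsets = read_offsets(config["offsets"]) if config.get("offsets") else ()
        corrected, audit = apply_corrections(sources, series, offsets, SuessConfig())
        corrections_frame(sources, corrected).to_csv(out / "sources_corrected.csv",
                                                     index=False)
        pd.DataFrame([dataclasses.asdict(a) for a in audit]).to_csv(
            out / "corrections_audit.csv", index=False)
        sources = corrected

    # --- group characterisation -------------------------------------------
    summaries = summarize_groups(sources)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()]).to_csv(
        out / "group_summaries.csv", index=False)
    stats_rows = []
    pts = np.array([(s.d13C, s.d15N) for s in sources])
    labels = np.array([s.group for s in sources])
    knnr = knnr_test(pts, labels, k=config.get("knnr_k", 1),
                     n_perm=config.get("knnr_permutations", 999), seed=seed)
    stats_rows.append({"test": "KNNr", "variable": "d13C+d15N",
                       "statistic": knnr.statistic, "p": knnr.p_value})
    for var, col in (("d13C", 0), ("d15N", 1)):
        groups = [pts[labels == g, col] for g in GROUPS if (labels == g).any()]
        kw = kruskal_wallis(*groups)
        stats_rows.append({"test": "Kruskal-Wallis", "variable": var,
                           "statistic": kw.statistic, "df": kw.df, "p": kw.p_value})
        by_group = {g: pts[labels == g, col] for g in GROUPS if (labels == g).any()}
        pw = pairwise_wilcoxon(by_group)
        for _, row in pw.iterrows():
            stats_rows.append({"test": "Wilcoxon", "variable": var,
                               "groups": f"{row.group_a} vs {row.group_b}",
                               "statistic": row.W, "p": row.p, "p_holm": row.p_holm})
    pd.DataFrame(stats_rows).to_csv(out / "statistics.csv", index=False)

    # --- scenarios ---------------------------------------------------------
    scenario_names = config.get("scenarios") or list(NAMED_SCENARIOS)
    scenarios = [NAMED_SCENARIOS[n] for n in scenario_names]

    # --- mixing-polygon plausibility ---------------------------------------
    means = np.array([[summaries[g].mean_d13C, summaries[g].mean_d15N]
                      for g in GROUPS if g in summaries])
    mcp_rows = []
    for sc in scenarios:
        n_raw, n_mean, flags = tef_plausibility(consumers, pts, means, sc)
        mcp_rows.append({"scenario": sc.name, "n_consumers": len(consumers),
                         "inside_raw_mcp": n_raw, "inside_mean_mcp": n_mean})
        pd.DataFrame(flags).to_csv(out / f"mcp_flags_{sc.name}.csv", index=False)
    pd.DataFrame(mcp_rows).to_csv(out / "mcp_report.csv", index=False)

    # --- per-consumer fits -------------------------------------------------
    dists = sources_from_summaries(summaries,
                                   pct_N_proxies=config.get("pct_N_proxies"))
    ladder = _ladder_from_config(config, seed)
    summary_rows = []
    any_nonconverged = False
    for sc in scenarios:
        for i, consumer in enumerate(consumers):
            fit_seed = (seed * 1_000_003 + i * len(scenarios)
                        + scenario_names.index(sc.name)) % (2**31 - 1)
            rung = [MCMCConfig(c.chain_length, c.burn_in, c.thin, c.n_chains,
                               seed=fit_seed) for c in ladder]
            result, report = run_until_converged(
                lambda cfg: fit_consumer(consumer, dists, sc, mcmc=cfg), rung)
            (out / f"convergence_{sc.name}_{consumer.consumer_id}.json").write_text(
                json.dumps(report_to_dict(report), indent=2))
            if not report.converged:
                any_nonconverged = True
            agg = aggregate(result)
            flagged = identifiability_check(result)
            row = {"consumer_id": consumer.consumer_id,
                   "rank_by_d13C": consumer.rank_by_d13C,
                   "scenario": sc.name, "converged": report.converged,
                   "indistinguishable_pairs": ";".join(
                       f"{a}|{b}" for a, b, _ in flagged)}
            for name, (lo, hi) in result.ci95.items():
                row[f"{name}_ci95_lo"], row[f"{name}_ci95_hi"] = lo, hi
            for sup, d in agg.items():
                row[f"{sup}_mean"] = d["mean"]
                row[f"{sup}_ci50_lo"], row[f"{sup}_ci50_hi"] = d["ci50"]
                row[f"{sup}_ci95_lo"], row[f"{sup}_ci95_hi"] = d["ci95"]
            summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(out / "posterior_summaries.csv", index=False)

    manifest = {"version": __version__, "seed": seed, "config": config,
                "scenarios": scenario_names, "n_sources": len(sources),
                "n_consumers": len(consumers),
                "all_converged": not any_nonconverged}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if any_nonconverged and not config.get("allow_nonconverged", False):
        raise RuntimeError("one or more models did not converge "
                           "(set allow_nonconverged to override)")
    return out
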