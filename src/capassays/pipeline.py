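"""End-to-end pipeline driver: run configured stages and write a summary.

Each stage either analyses an input file or, in simulation mode, generates
its own data through the synthetic module with a per-stage seed fanned out
deterministically from the global one, so reruns with the same config are
byte-identical.  Outputs land under the config's ``outdir``; the summary
JSON carries the config digest and the seed for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, densitometry, expression, proteomics, quantitation, synthetic
from .io import RunConfig, read_table, write_table

log = logging.getLogger("capassays")

__all__ = ["run_pipeline", "fit_binding_replicates"]


def fit_binding_replicates(
    kd_nM: float,
    *,
    n_replicates: int = 3,
    seeds=None,
    noise_scale: float = 0.02,
    protocol_kwargs: dict | None = None,
    true_params: binding.BindingModelParams | None = None,
    n_points: int = 45,
) -> tuple[binding.PooledBinding, list[binding.BindingFitResult]]:
    """Simulate, fit and pool replicate titrations for one ground-truth K_D.

    This is the full closed loop used for recovery checks: design an
    escalating-stock protocol around the expected K_D, forward-simulate raw
    readings under the study protocol (0.1 uM protein, 1.4 ml start, 1 ul
    aliquots) with relative Gaussian noise, rebuild corrected curves, fit each
    replicate and pool by inverse variance.
    """
    if seeds is None:
        seeds = list(range(1, n_replicates + 1))
    pk = dict(protocol_kwargs or {})
    aliquots, stocks = synthetic.escalating_stocks(
        kd_nM, n_points=n_points,
        start_volume=pk.get("start_volume", 1400.0),
        protein_conc=pk.get("protein_conc0", 0.1),
    )
    protocol = binding.TitrationProtocol(
        aliquot_volumes=aliquots, stock_concs=stocks, **pk)
    if true_params is None:
        true_params = binding.BindingModelParams(
            k_as=1000.0 / kd_nM, p_act=protocol.protein_conc0,
            f0=1000.0, delta_phi=9000.0, phi_free=10.0)
    fits = []
    for seed in seeds:
        sim = synthetic.SimulationConfig(seed=seed, noise_scale=noise_scale)
        raw, _truth = synthetic.gen_titration(true_params, protocol, sim)
        curve = binding.build_curve(raw, protocol)
        # the free-ligand fluorescence efficiency is treated as measured (a
        # ligand-only control titration determines it directly); weighting by
        # 1/F matches the multiplicative photometric noise model
        fits.append(binding.fit_titration(
            curve, fix={"phi_free": true_params.phi_free}, weights="relative"))
    return binding.pool_replicates(fits), fits


def _stage_binding(cfg: dict, seed: int, outdir: Path) -> dict:
    rows = []
    for compound in cfg.get("compounds", [{"name": "reference", "kd_nM": 42.1}]):
        n_rep = int(cfg.get("n_replicates", 3))
        pooled, fits = fit_binding_replicates(
            float(compound["kd_nM"]),
            n_replicates=n_rep,
            seeds=[seed + i for i in range(n_rep)],
            noise_scale=float(cfg.get("noise_scale", 0.02)),
        )
        rows.append({
            "compound": compound["name"], "k_as": pooled.k_as,
            "k_as_se": pooled.k_as_se, "kd_nM": pooled.kd_nM,
            "kd_se_nM": pooled.kd_se_nM, "n_replicates": pooled.n_replicates,
        })
    out = pd.DataFrame(rows)
    write_table(out, outdir / "binding_results.csv")
    return {"binding": out.to_dict(orient="records")}


def _stage_quantitation(cfg: dict, seed: int, outdir: Path) -> dict:
    if "input" in cfg:
        table = read_table(cfg["input"], cfg.get("dialect", "generic_csv"))
    else:
        table = pd.DataFrame(cfg["measurements"])
    out = quantitation.quantitate_table(table)
    write_table(out, outdir / "quantitation_results.csv")
    return {"quantitation": out.to_dict(orient="records")}


def _stage_densitometry(cfg: dict, seed: int, outdir: Path) -> dict:
    summary = {}
    if "capping" in cfg:
        c = cfg["capping"]
        if "input" in c:
            df = read_table(c["input"], c.get("dialect", "generic_csv"))
            profile = densitometry.LaneProfile(
                df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
        else:
            sim = synthetic.SimulationConfig(
                seed=seed, noise_scale=float(c.get("noise_scale", 0.01)))
            x, y, _ = synthetic.gen_lane_profile(
                bands=[(30.0, float(c.get("capped_area", 9.0)), 2.0),
                       (60.0, float(c.get("uncapped_area", 1.0)), 2.0)],
                baseline=(0.05, 0.001), sim=sim)
            profile = densitometry.LaneProfile(x, y)
        bands = densitometry.integrate_bands(profile)
        if len(bands) < 2:
            raise RuntimeError("densitometry stage found fewer than two bands")
        ce = densitometry.capping_efficiency(bands[0], bands[1])
        summary["capping_efficiency"] = ce
    if "decapping" in cfg:
        d = cfg["decapping"]
        if "input" in d:
            df = read_table(d["input"], d.get("dialect", "generic_csv"))
        else:
            sim = synthetic.SimulationConfig(
                seed=seed + 1, noise_scale=float(d.get("noise_scale", 0.0)))
            df, _ = synthetic.gen_decapping_series(
                float(d.get("initial_capped_fraction", 0.9)),
                float(d.get("rate_per_min", 0.05)), sim=sim)
        series = {row.time_min: (row.capped, row.uncapped)
                  for row in df.itertuples()}
        course = densitometry.decapping_course(
            series, query_time_min=float(d.get("query_time_min", 30.0)))
        summary["decapped_at_query"] = course.decapped_at_query
    if not summary:
        raise ValueError("densitometry block enables neither capping nor decapping")
    return {"densitometry": summary}


def _stage_expression(cfg: dict, seed: int, outdir: Path) -> dict:
    reference = cfg.get("reference", "m7GpppAmpG")
    if "input" in cfg:
        table = read_table(cfg["input"], cfg.get("dialect", "generic_csv"))
    else:
        sim = synthetic.SimulationConfig(
            seed=seed, noise_model="lognormal",
            noise_scale=float(cfg.get("noise_scale", 0.05)))
        table, _ = synthetic.gen_expression_plate(
            cfg.get("levels", {reference: 1.0}), sim=sim,
            reference_sample=reference)
    totals = expression.cumulative_expression(table)
    norm = expression.normalize_to_reference(totals, reference)
    write_table(norm, outdir / "expression_results.csv")
    return {"expression": norm.to_dict(orient="records")}


def _stage_proteomics(cfg: dict, seed: int, outdir: Path) -> dict:
    if "input" in cfg:
        table = read_table(cfg["input"], cfg.get("dialect", "maxquant_proteingroups"))
    else:
        sim = synthetic.SimulationConfig(seed=seed)
        spikes = [(s["group"], float(s["log2fc"]))
                  for s in cfg.get("spikes", [])]
        table, _ = synthetic.gen_proteingroups(
            n_background=int(cfg.get("n_background", 1000)),
            spikes=spikes, sim=sim,
            missing_rate=float(cfg.get("missing_rate", 0.0)))
    cleaned = proteomics.clean_table(table)
    normed = proteomics.log2_median_normalize(cleaned)
    filtered = proteomics.completeness_filter(normed)
    comparisons = cfg.get(
        "comparisons", ["AR-3 vs AR-1", "AR-2 vs AR-1", "AR-3 vs AR-2"])
    results = {}
    for comp in comparisons:
        res = proteomics.s0_test(
            filtered, comp, s0=float(cfg.get("s0", 1.0)),
            fdr=float(cfg.get("fdr", 0.02)), seed=seed)
        results[res.comparison] = res
        write_table(res.table,
                    outdir / f"proteomics_{res.comparison.replace(' ', '_')}.csv")
    binders = proteomics.preferential_binders(results)
    if "fc_fc" in binders:
        write_table(binders["fc_fc"], outdir / "proteomics_fc_fc.csv")
    return {"proteomics": {
        "n_filtered": len(filtered),
        "binder_counts": {k: len(v) for k, v in binders["binders"].items()},
        "n_both_tetraphosphate": len(binders.get("both_tetraphosphate", [])),
    }}


_STAGES = {
    "binding": _stage_binding,
    "quantitation": _stage_quantitation,
    "densitometry": _stage_densitometry,
    "expression": _stage_expression,
    "proteomics": _stage_proteomics,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in declared order and write a summary.

    Every output carries the config digest and global seed for provenance.
    A stage failure raises with the stage name attached; outputs already
    written by earlier stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_digest": config.digest(), "seed": config.seed}
    for stage, block in config.stages.items():
        log.info("running stage %s", stage)
        try:
            summary.update(_STAGES[stage](block, config.stage_seed(stage), outdir))
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return summary
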