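"""End-to-end orchestration: simulate -> screen -> stability -> ddpcr -> evaluate.

Each stage reads only the CSV outputs of earlier stages (never mutating
them), writes its own tables into the run directory, and the run ends
with a ``manifest.json`` recording the package version, the seed and the
row counts per output file. All randomness flows from one seeded
generator, so two runs with the same seed produce byte-identical numeric
outputs.
"""

from __future__ import annotations

import json
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import genorm, io, normalize, screen, simulate
from .config import PipelineConfig, resolve_seed
from .ddpcr import quantify_wells
from .errors import RefnormError

__all__ = ["run_full"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except RefnormError as exc:
                raise RefnormError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(config: PipelineConfig, outdir: Path, rng) -> dict:
    sim = config.simulation
    expr, design, truth = simulate.simulate_expression_timecourse(sim, rng)
    panel = simulate.make_panel_truth(sim, rng)
    cq = simulate.cq_from_abundance(panel, sim, rng)
    wells = simulate.simulate_ddpcr_panel(panel, sim, rng)
    io.write_expression(expr, outdir / "expression.csv")
    io.write_design(design, outdir / "design.csv")
    io.write_truth(truth, outdir / "truth.csv")
    io.write_cq(cq, outdir / "cq.csv")
    io.write_droplets(wells, outdir / "droplets.csv")
    return {"expression.csv": len(expr), "design.csv": len(design),
            "truth.csv": len(truth.classes), "cq.csv": len(cq),
            "droplets.csv": len(wells)}


@_stage("screen")
def _run_screen(config: PipelineConfig, outdir: Path) -> dict:
    values = io.read_expression(outdir / "expression.csv")
    design = io.read_design(outdir / "design.csv")
    sc = config.screen
    est = screen.StableGeneScreen(
        fc_threshold=sc.fc_threshold, p_threshold=sc.p_threshold,
        change_threshold=sc.change_threshold, cv_threshold=sc.cv_threshold,
        window=sc.window, window_percentiles=sc.window_percentiles,
    )
    est.fit(values.T, design["day"].to_numpy())
    de = est.log2_fold_changes_.add_prefix("log2fc_d")
    de["pvalue"] = est.pvalues_
    de = de.join(est.de_table_[["adj_pvalue", "is_de", "is_de_progressive"]])
    io._write(de.rename_axis("gene"), outdir / "de_table.csv", "de_table",
              index=True)
    io._write(est.stable_table_.rename_axis("gene"),
              outdir / "candidates.csv", "candidates", index=True)
    return {"de_table.csv": len(de), "candidates.csv": len(est.stable_table_)}


@_stage("stability")
def _run_stability(config: PipelineConfig, outdir: Path) -> dict:
    cq = io.read_cq(outdir / "cq.csv")
    refs = sorted(set(config.evaluate.references)
                  | {t for t in config.evaluate.targets if t.startswith("ref_")})
    cq = cq[cq["gene"].isin(refs)] if refs else cq
    eff = config.efficiency or config.simulation.efficiency
    q = genorm.relative_quantity_from_cq(cq, eff)
    m, _ = genorm.stability_measure(q)
    ranking, ranks = genorm.rank_by_stepwise_exclusion(q)
    v = genorm.pairwise_v_series(q, ranking)
    io.write_stability(m, ranks, outdir / "stability.csv")
    io.write_vseries(v, outdir / "vseries.csv")
    return {"stability.csv": len(m), "vseries.csv": len(v)}


@_stage("ddpcr")
def _run_ddpcr(config: PipelineConfig, outdir: Path) -> dict:
    wells = io.read_droplets(outdir / "droplets.csv")
    quant = quantify_wells(
        wells, droplet_volume=config.simulation.droplet_volume,
        background_correction=config.background_correction,
    )
    io.write_quant(quant, outdir / "quant.csv")
    return {"quant.csv": len(quant)}


@_stage("evaluate")
def _run_evaluate(config: PipelineConfig, outdir: Path) -> dict:
    quant = io.read_quant(outdir / "quant.csv")
    meas = quant.rename(columns={"target": "gene", "conc_bg": "value"})
    meas = meas[["gene", "day", "replicate", "value"]]
    ev = config.evaluate
    report = normalize.build_report(
        meas, targets=ev.targets, references=ev.references,
        combos=ev.combos, scale_mode=ev.scale_mode,
    )
    io.write_cv_report(report.cv_table, outdir / "cv_report.csv")
    io.write_profiles(report.profiles, outdir / "profiles.csv")
    return {"cv_report.csv": len(report.cv_table),
            "profiles.csv": len(report.profiles)}


def run_full(config: PipelineConfig, outdir: str | Path,
             seed: int | None = None,
             skip_screen: bool = False) -> dict:
    """Run every stage into ``outdir`` and return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = resolve_seed(config)
    rng = np.random.default_rng(seed)

    counts: dict[str, int] = {}
    counts.update(_run_simulate(config, outdir, rng))
    if not skip_screen:
        counts.update(_run_screen(config, outdir))
    counts.update(_run_stability(config, outdir))
    counts.update(_run_ddpcr(config, outdir))
    counts.update(_run_evaluate(config, outdir))

    try:
        pkg_version = _pkg_version("refnorm")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "package": "refnorm",
        "version": pkg_version,
        "seed": int(seed),
        "rows": counts,
        "pandas": pd.__version__,
        "numpy": np.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
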