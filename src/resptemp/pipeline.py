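"""End-to-end orchestration of the synthetic study.

Stages run in a fixed order — simulate, fit-ea, optimize, ensemble,
rescale-evaluate, report — with every intermediate artifact persisted under
one run directory and a manifest recording, per stage, the artifacts (with
SHA-256 checksums for data files), parameters, seed and duration. A rerun
with the same configuration and seed reproduces every data artifact
bit-for-bit; figures are listed without checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adjustment import optimize_adjustment
from .arrhenius import fit_arrhenius
from .ensemble import EnsembleFit, odr_fit, prediction_interval, z_compare
from .exceptions import ConfigurationError, RespTempError
from .grids import save_fields
from .rescale import evaluate_rescaled, rescale_model_specific, rescale_to_optimum
from .synthetic import (
    SyntheticTruth,
    WorldConfig,
    generate_biased_ensemble,
    generate_world,
)
from .transport import evaluate_model, sw_benchmark, biospheric_signal

logger = logging.getLogger("resptemp")

STAGES = ("simulate", "fit-ea", "optimize", "ensemble", "rescale-evaluate", "report")

#: files each stage needs from its predecessors
STAGE_INPUTS = {
    "simulate": (),
    "fit-ea": ("world.nc", "obs.csv"),
    "optimize": ("world.nc", "obs.csv", "footprints.csv", "footprints.json", "models.csv"),
    "ensemble": ("fits.csv", "adjustments.csv", "obs.csv"),
    "rescale-evaluate": ("fits.csv", "adjustments.csv", "ensemble.json"),
    "report": ("fits.csv", "adjustments.csv", "ensemble.json", "rescale_report.csv"),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 1234
    eps: float = 0.01             # near-zero respiration filter, umol m-2 s-1
    n_models: int = 12
    bias_ea_low: float = -0.3     # eV, pseudo-model Ea bias range
    bias_ea_high: float = 0.3
    alpha_low: float = 0.8        # pseudo-model baseline-scale range
    alpha_high: float = 1.25
    sw_gate: float | None = None  # None: computed from the SW field
    null_ea: float = 0.65         # eV, reference plot-scale sensitivity
    pi_level: float = 0.95
    world: dict = field(default_factory=dict)   # WorldConfig overrides

    def world_config(self) -> WorldConfig:
        return WorldConfig(**{"seed": self.seed, **self.world})

    def to_yaml(self, path) -> None:
        d = asdict(self)   # recursively converts nested BiomeSpec to dicts
        if d["world"].get("biomes"):
            d["world"]["biomes"] = [
                [b["name"], b["ea_ev"], b["re_ref"], list(b["box"])]
                for b in d["world"]["biomes"]
            ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "world" in d and d["world"] and "biomes" in d["world"]:
            from .synthetic import BiomeSpec
            d["world"]["biomes"] = tuple(
                BiomeSpec(b[0], b[1], b[2], tuple(b[3])) for b in d["world"]["biomes"]
            )
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _artifact(path: Path, checksum: bool = True) -> dict:
    rec = {"path": path.name}
    if checksum:
        rec["sha256"] = _sha256(path)
    return rec


def validate_inputs(outdir: Path, stage: str) -> None:
    """Fail before running a stage if a required predecessor artifact is absent."""
    missing = [f for f in STAGE_INPUTS[stage] if not (outdir / f).exists()]
    if missing:
        raise ConfigurationError(f"stage {stage!r} requires missing file(s): {missing}")


# -- stages ------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> SyntheticTruth:
    truth = generate_world(cfg.world_config())
    save_fields(outdir / "world.nc",
                {"temperature": truth.temperature, "sw": truth.sw, "gpp": truth.gpp,
                 "re": truth.re, "nee": truth.nee, "re_ref": truth.re_ref_field,
                 "biome": truth.biome_map},
                attrs={"seed": cfg.seed})
    truth.towers.to_csv(outdir / "towers.csv", index=False)
    truth.footprints.save(outdir / "footprints.csv", outdir / "footprints.json")
    truth.obs.to_csv(outdir / "obs.csv", index=False)
    truth.obs_clean.to_csv(outdir / "obs_clean.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(
        {"seed": cfg.seed, "biome_labels": truth.biome_labels,
         "biome_truth": truth.biome_truth}, indent=2, sort_keys=True))
    return truth


def _ensemble_models(cfg: RunConfig, truth: SyntheticTruth):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    biases = list(zip(rng.uniform(cfg.bias_ea_low, cfg.bias_ea_high, cfg.n_models),
                      rng.uniform(cfg.alpha_low, cfg.alpha_high, cfg.n_models)))
    return generate_biased_ensemble(truth, biases)


def stage_fit(cfg: RunConfig, outdir: Path, truth: SyntheticTruth):
    models = _ensemble_models(cfg, truth)
    pd.DataFrame([{"model_id": m.model_id, "dea_true": m.dea_true,
                   "alpha_true": m.alpha_true} for m in models]
                 ).to_csv(outdir / "models.csv", index=False)
    rows = []
    for m in models:
        for domain in truth.domains:
            fit = fit_arrhenius(m.re, truth.temperature,
                                domain_mask=truth.domain_mask(domain), eps=cfg.eps)
            rows.append({"model_id": m.model_id, "domain": domain, **fit.to_dict()})
    for domain in truth.domains:   # truth reference fits
        fit = fit_arrhenius(truth.re, truth.temperature,
                            domain_mask=truth.domain_mask(domain), eps=cfg.eps)
        rows.append({"model_id": "truth", "domain": domain, **fit.to_dict()})
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "fits.csv", index=False)
    return models, fits


def stage_optimize(cfg: RunConfig, outdir: Path, truth: SyntheticTruth, models):
    rows = []
    for m in models:
        for domain in truth.domains:
            adj = optimize_adjustment(
                m.re, truth.temperature, m.gpp, truth.footprints, truth.obs,
                domain_mask=truth.domain_mask(domain),
                model_id=m.model_id, domain=domain)
            rows.append(adj.to_dict())
    adj = pd.DataFrame(rows)
    adj.to_csv(outdir / "adjustments.csv", index=False)
    return adj


def stage_ensemble(cfg: RunConfig, outdir: Path, truth: SyntheticTruth, models,
                   fits: pd.DataFrame, adjustments: pd.DataFrame):
    y = biospheric_signal(truth.obs)
    gate = cfg.sw_gate if cfg.sw_gate is not None else \
        sw_benchmark(truth.footprints, truth.sw, y)
    evals = pd.DataFrame([
        evaluate_model(m.model_id, m.gpp, m.nee, truth.footprints, truth.obs,
                       sw_gate=gate).to_dict()
        for m in models
    ])
    evals.to_csv(outdir / "eval.csv", index=False)
    gated_out = tuple(evals.loc[~evals["pass_sw_gate_gpp"], "model_id"])

    result: dict[str, dict] = {"sw_gate": float(gate), "excluded": list(gated_out),
                               "domains": {}}
    for domain in truth.domains:
        f = fits[(fits["domain"] == domain) & (fits["model_id"] != "truth")
                 & ~fits["model_id"].isin(gated_out)].set_index("model_id")
        a = adjustments[(adjustments["domain"] == domain)
                        & ~adjustments["model_id"].isin(gated_out)].set_index("model_id")
        ids = f.index.intersection(a.index)
        fit = odr_fit(f.loc[ids, "ea"].to_numpy(), a.loc[ids, "dea"].to_numpy(),
                      excluded_ids=gated_out)
        z = z_compare(fit.ea_opt, fit.sigma_opt, cfg.null_ea, tail="one") \
            if fit.sigma_opt > 0 else None
        result["domains"][domain] = {
            **fit.to_dict(),
            "z_vs_null": None if z is None else {"z": z.z, "p": z.p, "null": z.null},
        }
    (outdir / "ensemble.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    return evals, result


def stage_rescale(cfg: RunConfig, outdir: Path, truth: SyntheticTruth, models,
                  fits: pd.DataFrame, adjustments: pd.DataFrame, ens: dict):
    gated_out = set(ens["excluded"])
    ea_opt_na = ens["domains"]["north-america"]["ea_opt"]
    masks = {d: truth.domain_mask(d) for d in truth.domains if d != "north-america"}
    rows = []
    from .adjustment import AdjustmentResult
    for m in models:
        if m.model_id in gated_out:
            continue
        adj_m = adjustments[adjustments["model_id"] == m.model_id].set_index("domain")
        per_domain = {
            d: AdjustmentResult(model_id=m.model_id, domain=d,
                                dea=float(adj_m.loc[d, "dea"]),
                                alpha=float(adj_m.loc[d, "alpha"]),
                                objective=float(adj_m.loc[d, "objective"]),
                                n_obs=int(adj_m.loc[d, "n_obs"]),
                                converged=bool(adj_m.loc[d, "converged"]),
                                dea_se=float(adj_m.loc[d, "dea_se"]),
                                alpha_se=float(adj_m.loc[d, "alpha_se"]))
            for d in masks
        }
        re_spec = rescale_model_specific(m.re, truth.temperature, per_domain, masks)
        rows.append(evaluate_rescaled(
            m.model_id, "model-specific", m.gpp, m.re, re_spec,
            truth.footprints, truth.obs).to_dict())

        ea_model = float(fits[(fits["model_id"] == m.model_id)
                              & (fits["domain"] == "north-america")]["ea"].iloc[0])
        res = rescale_to_optimum(m.re, truth.temperature, ea_model, ea_opt_na)
        rows.append(evaluate_rescaled(
            m.model_id, "ensemble-optimum", m.gpp, m.re, res.field,
            truth.footprints, truth.obs, cap_fraction=res.cap_fraction).to_dict())
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "rescale_report.csv", index=False)
    return report


def stage_report(cfg: RunConfig, outdir: Path, truth: SyntheticTruth,
                 fits: pd.DataFrame, adjustments: pd.DataFrame, ens: dict,
                 rescale_report: pd.DataFrame) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not ens["domains"]:
        raise RespTempError("empty ensemble: nothing to report")
    figures = []

    # activation-energy histograms before/after optimization (continental)
    na_fits = fits[(fits["domain"] == "north-america") & (fits["model_id"] != "truth")]
    na_adj = adjustments[adjustments["domain"] == "north-america"].set_index("model_id")
    ea_before = na_fits.set_index("model_id")["ea"]
    ea_after = ea_before + na_adj.loc[ea_before.index, "dea"]
    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharex=True, sharey=True)
    for ax, data, title in zip(axes, (ea_before, ea_after), ("original", "optimized")):
        ax.hist(data, bins=10, color="#7296c4", edgecolor="k")
        ax.axvline(cfg.null_ea, ls="--", color="green")
        ax.set_xlabel("activation energy (eV)")
        ax.set_title(title)
    fig.tight_layout()
    p = outdir / "fig_ea_hist.png"
    fig.savefig(p)
    plt.close(fig)
    figures.append(p)

    # adjustment-vs-Ea scatter with ODR line and optimum, per domain
    fig, axes = plt.subplots(1, len(ens["domains"]), figsize=(4 * len(ens["domains"]), 3.2),
                             squeeze=False)
    for ax, (domain, d) in zip(axes[0], sorted(ens["domains"].items())):
        f = fits[(fits["domain"] == domain) & (fits["model_id"] != "truth")
                 & ~fits["model_id"].isin(ens["excluded"])].set_index("model_id")
        a = adjustments[(adjustments["domain"] == domain)
                        & ~adjustments["model_id"].isin(ens["excluded"])].set_index("model_id")
        ids = f.index.intersection(a.index)
        x, yv = f.loc[ids, "ea"].to_numpy(), a.loc[ids, "dea"].to_numpy()
        ax.scatter(x, yv, s=18, color="#b65a52")
        grid = np.linspace(x.min() - 0.05, x.max() + 0.05, 100)
        efit = EnsembleFit(slope=d["slope"], intercept=d["intercept"],
                           cov=np.array(d["cov"]), ea_opt=d["ea_opt"],
                           sigma_opt=d["sigma_opt"], n_models=d["n_models"],
                           resid_var=d["resid_var"], x_mean=float(x.mean()),
                           excluded_ids=tuple(d["excluded_ids"]))
        lo, hi = prediction_interval(efit, grid, cfg.pi_level)
        ax.fill_between(grid, lo, hi, color="0.85")
        ax.plot(grid, efit.line(grid), "k--")
        ax.axhline(0.0, color="0.4", lw=0.7)
        ax.axvline(d["ea_opt"], color="green", ls="--")
        ax.set_title(f"{domain}: Ea_opt = {d['ea_opt']:.2f} eV")
        ax.set_xlabel("original Ea (eV)")
        ax.set_ylabel("dEa (eV)")
    fig.tight_layout()
    p = outdir / "fig_odr.png"
    fig.savefig(p)
    plt.close(fig)
    figures.append(p)

    # before/after explanatory-power chart
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    for ax, mode in zip(axes, ("model-specific", "ensemble-optimum")):
        sub = rescale_report[rescale_report["mode"] == mode]
        ax.scatter(sub["delta_r2_before"], sub["delta_r2_after"], s=18)
        lim = max(sub[["delta_r2_before", "delta_r2_after"]].abs().max().max(), 0.05)
        ax.plot([-lim, lim], [-lim, lim], "k:", lw=0.7)
        ax.axvline(0, color="0.6", lw=0.7)
        ax.axhline(0, color="0.6", lw=0.7)
        ax.set_xlabel("dR2 before")
        ax.set_title(mode)
    axes[0].set_ylabel("dR2 after")
    fig.tight_layout()
    p = outdir / "fig_delta_r2.png"
    fig.savefig(p)
    plt.close(fig)
    figures.append(p)

    # summary table straight from stored stage outputs (no recomputation)
    rows = []
    for domain, d in sorted(ens["domains"].items()):
        rows.append({
            "domain": domain,
            "ea_opt": d["ea_opt"],
            "sigma_opt": d["sigma_opt"],
            "n_models": d["n_models"],
            "p_vs_null": None if d["z_vs_null"] is None else d["z_vs_null"]["p"],
        })
    improving = rescale_report[rescale_report["delta_r2_before"] < 0]
    summary = pd.DataFrame(rows)
    for mode in ("model-specific", "ensemble-optimum"):
        sub = improving[improving["mode"] == mode]
        summary[f"mean_r2_nee_gain_{mode}"] = (
            (sub["r2_nee_after"] - sub["r2_nee_before"]).mean() if len(sub) else np.nan
        )
    summary.to_csv(outdir / "summary.csv", index=False)
    return figures


# -- orchestration -----------------------------------------------------------

def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest = {"seed": cfg.seed, "config": "config.yaml", "stages": []}

    def record(name, t0, artifacts, checksum=True, figures=()):
        manifest["stages"].append({
            "name": name,
            "duration_s": round(time.perf_counter() - t0, 3),
            "artifacts": [_artifact(outdir / a) for a in artifacts]
                         + [_artifact(f, checksum=False) for f in figures],
            "seed": cfg.seed,
        })
        logger.info("stage %s done in %.2fs", name, manifest["stages"][-1]["duration_s"])

    try:
        t0 = time.perf_counter()
        truth = stage_simulate(cfg, outdir)
        record("simulate", t0, ["world.nc", "towers.csv", "footprints.csv",
                                "footprints.json", "obs.csv", "obs_clean.csv", "truth.json"])

        t0 = time.perf_counter()
        models, fits = stage_fit(cfg, outdir, truth)
        record("fit-ea", t0, ["models.csv", "fits.csv"])

        t0 = time.perf_counter()
        adjustments = stage_optimize(cfg, outdir, truth, models)
        record("optimize", t0, ["adjustments.csv"])

        t0 = time.perf_counter()
        evals, ens = stage_ensemble(cfg, outdir, truth, models, fits, adjustments)
        record("ensemble", t0, ["eval.csv", "ensemble.json"])

        t0 = time.perf_counter()
        report_df = stage_rescale(cfg, outdir, truth, models, fits, adjustments, ens)
        record("rescale-evaluate", t0, ["rescale_report.csv"])

        t0 = time.perf_counter()
        figures = stage_report(cfg, outdir, truth, fits, adjustments, ens, report_df)
        record("report", t0, ["summary.csv"], figures=figures)
    except Exception:
        manifest["completed"] = False
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest["completed"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report_from_manifest(outdir) -> list[Path]:
    """Regenerate report products for an existing run directory."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    done = {s["name"] for s in manifest["stages"]}
    needed = {"simulate", "fit-ea", "optimize", "ensemble", "rescale-evaluate"}
    if not needed <= done:
        warnings.warn(f"manifest incomplete (missing {sorted(needed - done)}); "
                      "report covers completed stages only")
    validate_inputs(outdir, "report")
    cfg = RunConfig.from_yaml(outdir / "config.yaml")
    truth = generate_world(cfg.world_config())
    fits = pd.read_csv(outdir / "fits.csv")
    adjustments = pd.read_csv(outdir / "adjustments.csv")
    ens = json.loads((outdir / "ensemble.json").read_text())
    rescale_report = pd.read_csv(outdir / "rescale_report.csv")
    return stage_report(cfg, outdir, truth, fits, adjustments, ens, rescale_report)
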