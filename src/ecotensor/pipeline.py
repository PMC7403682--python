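"""End-to-end orchestration: simulate -> divergence -> field models ->
tensor -> adaptation -> report.

One master seed spawns an independent, stable stream per stage, so stages
are individually rerunnable yet jointly reproducible: the same
PipelineConfig (including seed) yields byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adaptation import adaptation_strength, linecross_table, variance_adaptation_regression
from .diagnostics import hpd_interval
from .fitmodels import (CharStateSpec, MCMCSettings, MeanModelSpec,
                        cell_probability_draws, fit_charstate_model,
                        fit_mean_model, predicted_means_table)
from .phenodiv import (TraitMatrix, compute_d_matrix, divergence_scores,
                       effective_family_size, manova_sscp, pairwise_manovas,
                       standardize_traits, wilks_test)
from .synthdata import SimConfig, write_outputs
from .tensor import MatrixSet, cov_to_corr, project_axis, summarize_coordinates, tensor_analysis
from .validate import validate_dataset

log = logging.getLogger(__name__)

STAGES = ("simulate", "divergence", "fitfield", "tensor", "adaptation", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "ecotensor_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    mcmc: dict = field(default_factory=dict)         # MCMCSettings overrides
    matrices: str = "correlation"                    # tensor input scale
    stages: tuple = STAGES
    hpd_prob: float = 0.95

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(**({"rng_seed": seed} | dict(self.sim)))

    def mcmc_settings(self, seed: int) -> MCMCSettings:
        return MCMCSettings(**({"seed": seed} | dict(self.mcmc)))

    def config_hash(self) -> str:
        blob = json.dumps({k: v if not isinstance(v, tuple) else list(v)
                           for k, v in asdict(self).items()},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def demo_config(out_dir: str, seed: int = 0) -> PipelineConfig:
    """Reduced-size configuration for smoke tests and desk-scale runs."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed,
        sim={"n_parents_per_ecotype": 16, "f1_families_per_cross": (4, 5),
             "f2_families_per_cross": (3, 4), "n_f3_families": 130,
             "n_f4_families": 80, "trait_reps_per_family": 2,
             "p_field_families_per_ecotype": 16, "f1_field_families_per_cross": 10,
             "seeds_per_family_habitat": {"P": 8, "F1": 8, "F4": 12}},
        mcmc={"iterations": 1700, "burn_in": 200, "thin": 1})


def _stage_seed(master: int, stage: str) -> int:
    # stable small integer per stage derived from the master seed
    return int(np.random.SeedSequence([master, STAGES.index(stage)])
               .generate_state(1)[0] % (2 ** 31))


def _dump(obj, path: Path, meta: dict) -> None:
    def conv(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump({"_meta": meta} | obj, fh, indent=1, default=conv)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the enabled stages; returns the report dictionary.

    With ``resume=True``, stages whose outputs already exist are skipped.
    On stage failure, completed outputs remain on disk and the exception
    propagates after being logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "config_hash": config.config_hash(),
            "seed": config.seed}
    report: dict = {"meta": meta, "stages": {}, "log": []}

    def stage_enabled(name):
        return name in config.stages

    def note(stage, **info):
        entry = {"stage": stage, **info}
        report["log"].append(entry)
        log.info("stage %s: %s", stage, info)

    t0 = time.time()
    try:
        if stage_enabled("simulate") and not (resume and (out / "field.csv").exists()):
            sim = config.sim_config(_stage_seed(config.seed, "simulate"))
            paths = write_outputs(out, sim)
            for name in ("traits", "field"):
                rep = validate_dataset(paths[name], name if name == "field" else "traits")
                if not rep.ok:
                    raise RuntimeError(f"generated {name}.csv violates contract: "
                                       f"{rep.violations[:3]}")
            note("simulate", rows_field=sum(1 for _ in open(paths["field"])) - 1)

        if stage_enabled("divergence"):
            report["stages"]["divergence"] = _divergence_stage(out, note)

        charstate = {}
        mean_post = None
        if stage_enabled("fitfield"):
            mean_post, charstate = _fitfield_stage(out, config, note)

        if stage_enabled("tensor"):
            report["stages"]["tensor"] = _tensor_stage(out, config, charstate, note)

        if stage_enabled("adaptation"):
            report["stages"]["adaptation"] = _adaptation_stage(
                out, config, mean_post, charstate, note)

        if stage_enabled("report"):
            report["elapsed_s"] = round(time.time() - t0, 2)
            _dump({k: v for k, v in report.items() if k != "meta"},
                  out / "report.json", meta)
            (out / "report.md").write_text(_render_markdown(report))
    except Exception:
        log.exception("pipeline failed; partial outputs kept in %s", out)
        raise
    return report


def _divergence_stage(out: Path, note) -> dict:
    df = pd.read_csv(out / "traits.csv")
    trait_cols = [c for c in df.columns
                  if c not in ("plant", "generation", "group", "family")]
    tm = standardize_traits(TraitMatrix.from_frame(df, trait_cols))
    ecotypes = sorted(df.loc[df.generation == "P", "group"].unique())
    pw = pairwise_manovas(tm, "F4", ecotypes)
    parental = tm.subset(ecotypes)
    dec = manova_sscp(parental)
    overall = wilks_test(dec)
    nf = effective_family_size(dec.group_sizes.values())
    dm = compute_d_matrix(dec, nf, trait_cols)
    scores = divergence_scores(dm, tm)
    scores.to_csv(out / "d_scores.csv", index=False)
    manova_json = {
        "pairwise_F4": {k: asdict(v) for k, v in pw.items()},
        "parental": asdict(overall),
    }
    _dump(manova_json, out / "manova.json", {})
    pos = dm.proportions[~np.isnan(dm.proportions)]
    _dump({"d": dm.d, "ms_h": dm.ms_h, "ms_e": dm.ms_e, "nf": dm.nf,
           "eigenvalues": dm.eigenvalues, "eigenvectors": dm.eigenvectors,
           "proportions": dm.proportions, "trait_names": trait_cols},
          out / "d_matrix.json", {})
    note("divergence", n_rows=len(df), wilks_lambda=overall.wilks_lambda)
    return {"parental_wilks_lambda": overall.wilks_lambda,
            "parental_p": overall.p_value,
            "pairwise_lambda": {k: v.wilks_lambda for k, v in pw.items()},
            "dmax_proportion": float(pos[0]) if pos.size else np.nan,
            "d2_proportion": float(pos[1]) if pos.size > 1 else np.nan}


def _fitfield_stage(out: Path, config: PipelineConfig, note):
    field_df = pd.read_csv(out / "field.csv")
    settings = config.mcmc_settings(_stage_seed(config.seed, "fitfield"))
    mean_post = fit_mean_model(field_df, MeanModelSpec(), settings)
    predicted_means_table(mean_post, config.hpd_prob).to_csv(
        out / "means.csv", index=False)
    _dump({"habitats": mean_post.habitats, "categories": mean_post.categories,
           "cells": [list(c) for c in mean_post.cells],
           "cell_draws": mean_post.cell_draws,
           "variance_draws": {k: v for k, v in mean_post.variance_draws.items()},
           "settings": asdict(mean_post.settings), "outcome": mean_post.outcome},
          out / "mean_model_posterior.json", {})
    charstate = {}
    for k, gen in enumerate(("P", "F1", "F4")):
        gs = config.mcmc_settings(_stage_seed(config.seed, "fitfield") + k + 1)
        post = fit_charstate_model(field_df, CharStateSpec.for_generation(gen), gs)
        charstate[gen] = post
        _dump({"generation": gen, "habitats": post.habitats,
               "draws": post.draws, "fixed_draws": post.fixed_draws,
               "variance_draws": {k2: v for k2, v in post.variance_draws.items()},
               "diagnostics": {k2: asdict(v) for k2, v in post.diagnostics.items()},
               "settings": asdict(post.settings), "flagged": post.flagged},
              out / f"posterior_{gen}.json", {})
        note("fitfield", generation=gen, draws=post.draws.shape[0],
             diagnostics_ok=not post.flagged)
    return mean_post, charstate


def load_charstate_posteriors(out_dir) -> dict:
    """Rehydrate posterior_<gen>.json files written by the fitfield stage."""
    from .fitmodels import GenerationCovPosterior
    out = Path(out_dir)
    posts = {}
    for p in sorted(out.glob("posterior_*.json")):
        with open(p) as fh:
            d = json.load(fh)
        posts[d["generation"]] = GenerationCovPosterior(
            d["generation"], d["habitats"], np.array(d["draws"]),
            np.array(d["fixed_draws"]),
            {k: np.array(v) for k, v in d["variance_draws"].items()},
            {}, MCMCSettings(**d["settings"]), d["flagged"])
    return posts


def load_mean_posterior(out_dir) -> "MeanModelPosterior":
    """Rehydrate mean_model_posterior.json written by the fitfield stage."""
    from .fitmodels import MeanModelPosterior
    with open(Path(out_dir) / "mean_model_posterior.json") as fh:
        d = json.load(fh)
    return MeanModelPosterior(
        d["habitats"], d["categories"], [tuple(c) for c in d["cells"]],
        np.array(d["cell_draws"]),
        {k: np.array(v) for k, v in d["variance_draws"].items()},
        {}, MCMCSettings(**d["settings"]), d["outcome"])


def _tensor_stage(out: Path, config: PipelineConfig, charstate: dict, note) -> dict:
    if not charstate:
        charstate = load_charstate_posteriors(out)
    labels = [g for g in ("P", "F1", "F4") if g in charstate]
    S = min(charstate[g].draws.shape[0] for g in labels)
    draws = np.stack([charstate[g].draws[:S] for g in labels])
    if config.matrices == "correlation":
        draws = np.stack([[cov_to_corr(m) for m in gen] for gen in draws])
    mats = MatrixSet.from_draws(labels, draws)
    dec = tensor_analysis(mats)
    coords = summarize_coordinates(dec, config.hpd_prob)
    et1 = dec.eigentensors[0]
    proj_rows = []
    for ax in range(et1.axis_vectors.shape[1]):
        vals, dvals = project_axis(et1.axis_vectors[:, ax], mats)
        for t, lab in enumerate(labels):
            row = {"eigentensor": 1, "axis": ax + 1, "matrix": lab,
                   "projection": float(vals[t])}
            if dvals is not None:
                lo, hi = hpd_interval(dvals[t], config.hpd_prob)
                row["hpd_low"], row["hpd_high"] = lo, hi
            proj_rows.append(row)
    alpha_hpd = [list(hpd_interval(dec.alpha_draws[:, k], config.hpd_prob))
                 for k in range(dec.alpha_draws.shape[1])] \
        if dec.alpha_draws is not None else None
    _dump({"labels": labels, "s_matrix": dec.s, "alphas": dec.alphas,
           "alpha_proportions": dec.alpha_proportions, "alpha_hpd": alpha_hpd,
           "eigentensors": [t.e_matrix for t in dec.eigentensors],
           "eigentensor1_axes": {"values": et1.axis_values,
                                 "vectors": et1.axis_vectors,
                                 "proportions": et1.axis_proportions},
           "coordinates": coords, "projections": proj_rows},
          out / "tensor.json", {})
    pd.DataFrame(coords).to_csv(out / "tensor_report.csv", index=False)
    note("tensor", eigentensor1_share=float(dec.alpha_proportions[0]))
    return {"alphas": dec.alphas.tolist(),
            "eigentensor1_share": float(dec.alpha_proportions[0]),
            "coordinates": coords, "projections": proj_rows}


def _adaptation_stage(out: Path, config: PipelineConfig, mean_post, charstate,
                      note) -> dict:
    if not charstate:
        charstate = load_charstate_posteriors(out)
    if mean_post is None:
        mean_post = load_mean_posterior(out)
    cell_draws = cell_probability_draws(mean_post)
    ecotypes = [c for c in mean_post.categories
                if c not in ("F4",) and "x" not in str(c)]
    f1_cats = [c for c in mean_post.categories if "x" in str(c)]
    lc = linecross_table(cell_draws, mean_post.habitats, ecotypes, f1_cats,
                         config.hpd_prob)
    lc.to_csv(out / "linecross.csv", index=False)
    native_map = {h: h for h in mean_post.habitats}  # habitat named for its ecotype
    adapt = adaptation_strength(cell_draws, native_map, ecotypes, config.hpd_prob)
    pd.DataFrame(adapt.summaries).to_csv(out / "adaptation.csv", index=False)
    slopes = {}
    for gen in ("F1", "F4"):
        if gen in charstate:
            sp = variance_adaptation_regression(adapt, charstate[gen],
                                                config.hpd_prob)
            slopes[gen] = {"summary": sp.summary,
                           "fraction_negative": sp.fraction_negative,
                           "smallest_hpd_excluding_zero":
                               sp.smallest_hpd_excluding_zero}
    _dump({"slopes": slopes}, out / "slope_posterior.json", {})
    note("adaptation", **{f"slope_{g}_frac_neg": s["fraction_negative"]
                          for g, s in slopes.items()})
    f4_dev = lc[(lc.quantity == "f4_deviation")]
    f1_dev = lc[(lc.quantity == "f1_deviation")]
    return {"strength": adapt.summaries, "slopes": slopes,
            "f4_deviation_mean": float(f4_dev["mean"].mean()),
            "f1_deviation_mean": float(f1_dev["mean"].mean())}


def _render_markdown(report: dict) -> str:
    lines = ["# ecotensor pipeline report", ""]
    meta = report["meta"]
    lines += [f"version {meta['version']}, config {meta['config_hash']}, "
              f"seed {meta['seed']}", ""]
    st = report["stages"]
    if "divergence" in st:
        d = st["divergence"]
        lines += ["## Phenotypic divergence",
                  f"- parental Wilks' lambda: {d['parental_wilks_lambda']:.4f} "
                  f"(p = {d['parental_p']:.3g})",
                  f"- d_max / d_2 divergence proportions: "
                  f"{d['dmax_proportion']:.2%} / {d['d2_proportion']:.2%}", ""]
    if "tensor" in st:
        t = st["tensor"]
        lines += ["## Covariance tensor",
                  f"- eigentensor 1 share of among-matrix variance: "
                  f"{t['eigentensor1_share']:.2%}", ""]
        for c in t["coordinates"]:
            if c["eigentensor"] == 1:
                hpd = (f" [{c['hpd_low']:.3f}, {c['hpd_high']:.3f}]"
                       if "hpd_low" in c else "")
                lines.append(f"- coordinate({c['matrix']}, ET1): "
                             f"{c['coordinate']:.3f}{hpd}")
        lines.append("")
    if "adaptation" in st:
        a = st["adaptation"]
        lines += ["## Adaptation and variance"]
        for g, s in a["slopes"].items():
            lines.append(f"- {g} variance-on-adaptation slope: "
                         f"{s['summary']['mean']:.3f}, "
                         f"P(slope<0) = {s['fraction_negative']:.2f}")
        lines.append("")
    return "\n".join(lines)
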