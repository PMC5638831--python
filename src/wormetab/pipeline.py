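"""End-to-end orchestration from a single YAML config.

Stages run in the analysis order simulate -> preprocess -> model (per
treated-vs-control comparison) -> stocsy -> univariate -> pathway -> baf,
each logging its parameters and timing; every artifact is hashed into
``manifest_hashes.json`` so a config snapshot plus the code version
reproduces every output hash. A stage failure moves partial outputs under
``failed/`` and raises :class:`~wormetab.errors.PipelineError`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import time

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import bioaccum, chemo, pathway, spectra, stats, stocsy, synthdata
from .errors import ConfigError, PipelineError


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_metabolites: int = 30
    groups: list[tuple[str, int]] = [("CON", 10), ("D1", 10), ("D2", 10)]
    effects: dict[str, dict[str, float]] = {}
    conc_sd_log: float = 0.15
    dilution_sd_log: float = 0.15
    shift_jitter_sd_ppm: float = 0.001
    noise_sd: float = 1.0
    baseline_offset_sd: float = 0.5


class InputsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    manifest: str | None = None
    assignments: str | None = None
    pathway_index: str | None = None
    exposure: str | None = None


class PreprocessBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lo_ppm: float = 0.2
    hi_ppm: float = 8.8
    target_width: float = 0.015
    exclusions: list[tuple[float, float]] = [spectra.WATER_REGION]
    pqn_reference: str = "median-of-all"
    pqn_reference_group: str | None = None


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_osc: int = 1
    pls_components: int | None = None  # None: maximize Q2Y up to 3
    cv_repeats: int = 50
    perm_repeats: int = 7
    n_perm: int = 2000
    refit_osc: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    simulate: SimulateBlock | None = None
    inputs: InputsBlock = InputsBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    model: ModelBlock = ModelBlock()
    comparisons: list[tuple[str, str]] = []
    stocsy_drivers: list[float] = []
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except ValidationError as e:
            raise ConfigError(str(e)) from e


def demo_config(seed: int = 0) -> RunConfig:
    """Small three-group synthetic study with dose-scaled effects; sized for
    a quick smoke run (modest permutation count)."""
    effects = {
        "alanine": {"D1": 1.8, "D2": 2.6},
        "betaine": {"D1": 0.6, "D2": 0.45},
        "fumarate": {"D1": 1.7, "D2": 2.4},
        "ATP": {"D1": 1.6, "D2": 2.2},
        "succinate": {"D1": 0.65, "D2": 0.5},
    }
    return RunConfig(
        seed=seed,
        simulate=SimulateBlock(n_metabolites=43, effects=effects,
                               groups=[("CON", 8), ("D1", 8), ("D2", 8)]),
        model=ModelBlock(n_perm=99, cv_repeats=10, perm_repeats=3),
        comparisons=[("D1", "CON"), ("D2", "CON")],
        stocsy_drivers=[1.33],
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Run every configured stage; returns a dict of key results."""
    os.makedirs(out_dir, exist_ok=True)
    log = logging.getLogger("wormetab.pipeline")
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh)

    results: dict = {}
    stage = "init"
    try:
        # ---- simulate or load -------------------------------------------
        t0 = time.time()
        assignments = None
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            library = synthdata.default_library(sim.n_metabolites)
            design = synthdata.StudyDesign(
                groups=[tuple(g) for g in sim.groups],
                effects=sim.effects,
                conc_sd_log=sim.conc_sd_log,
                dilution_sd_log=sim.dilution_sd_log,
                shift_jitter_sd_ppm=sim.shift_jitter_sd_ppm,
                noise_sd=sim.noise_sd,
                baseline_offset_sd=sim.baseline_offset_sd,
                seed=config.seed,
            )
            sset, truth = synthdata.simulate_study(library, design)
            spec_dir = os.path.join(out_dir, "spectra")
            synthdata_manifest = spectra.write_spectra(sset, spec_dir)
            truth.to_csv(os.path.join(out_dir, "ground_truth.csv"))
            assignments = synthdata.assignments_from_library(library)
            assignments.to_csv(os.path.join(out_dir, "assignments.csv"), index=False)
            log.info("simulate: %d samples, %d metabolites (%.1fs)",
                     sset.n_samples, len(library), time.time() - t0)
        elif config.inputs.manifest:
            stage = "read"
            sset = spectra.read_spectra(config.inputs.manifest)
            log.info("read: %d samples (%.1fs)", sset.n_samples, time.time() - t0)
        else:
            raise ConfigError("config needs either a simulate block or inputs.manifest")
        if config.inputs.assignments:
            assignments = stats.load_assignments(config.inputs.assignments)

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        pp = config.preprocess
        for lo, hi in pp.exclusions:
            sset = spectra.exclude_region(sset, lo, hi)
        bt = spectra.adaptive_bin(sset, pp.lo_ppm, pp.hi_ppm, pp.target_width)
        ref = (("median-of-group", pp.pqn_reference_group)
               if pp.pqn_reference == "median-of-group" else pp.pqn_reference)
        fm = spectra.pqn_normalize(bt, ref)
        fm.to_csv(os.path.join(out_dir, "feature_matrix.csv"))
        log.info("preprocess: %d bins, mean width %.4f ppm (%.1fs)",
                 len(bt.bins), float(np.mean([b.width for b in bt.bins])),
                 time.time() - t0)
        results["n_bins"] = len(bt.bins)

        # ---- multivariate models per comparison --------------------------
        stage = "model"
        labels = fm.group_labels()
        results["validation"] = {}
        for treated, control in config.comparisons:
            t0 = time.time()
            mask = (labels == treated) | (labels == control)
            Xs = fm.X[mask]
            Y, classes = chemo.dummy_code(labels[mask])
            Xc = Xs - Xs.mean(axis=0)
            mb = config.model
            k = mb.pls_components or chemo.choose_n_components(
                Xc, Y, seed=config.seed, n_osc=mb.n_osc)
            val = chemo.permutation_test(
                Xs, Y, k, n_perm=mb.n_perm, seed=config.seed,
                cv_repeats=mb.cv_repeats, perm_repeats=mb.perm_repeats,
                n_osc=mb.n_osc, refit_osc=mb.refit_osc,
            )
            cmp_name = f"{treated}_vs_{control}"
            cdir = os.path.join(out_dir, f"model_{cmp_name}")
            os.makedirs(cdir, exist_ok=True)
            Xf, _ = chemo.osc_filter(Xc, Y, n_osc=mb.n_osc) if mb.n_osc else (Xc, None)
            model = chemo.plsda_fit(Xf, Y, min(k, Xf.shape[0] - 1))
            ids = np.array(fm.sample_ids)[mask]
            pd.DataFrame(model.scores, index=ids).to_csv(
                os.path.join(cdir, "scores.csv"))
            pd.DataFrame(model.x_loadings, index=fm.feature_ppm).to_csv(
                os.path.join(cdir, "loadings.csv"))
            load_df = chemo.correlation_loading_plot(
                model, Xf, fm.feature_ppm, alpha=config.alpha)
            load_df.to_csv(os.path.join(cdir, "loading_pseudospectrum.csv"),
                           index=False)
            with open(os.path.join(cdir, "validation.json"), "w") as fh:
                json.dump(val.to_dict(), fh, indent=1)
            pd.DataFrame({"null_q2y": val.null_stats}).to_csv(
                os.path.join(cdir, "permutation_null.csv"), index=False)
            results["validation"][cmp_name] = val.to_dict()
            log.info("model %s: k=%d r2y=%.3f q2y=%.3f p=%.4g (%.1fs)",
                     cmp_name, k, val.r2y, val.q2y, val.p_perm, time.time() - t0)

        # ---- stocsy ------------------------------------------------------
        if config.stocsy_drivers:
            stage = "stocsy"
            for d in config.stocsy_drivers:
                res = stocsy.stocsy_1d(fm, d)
                stocsy.write_stocsy_csv(
                    fm, res, os.path.join(out_dir, f"stocsy_{d:.2f}.csv"))
            log.info("stocsy: %d driver(s)", len(config.stocsy_drivers))

        # ---- univariate --------------------------------------------------
        if assignments is not None and config.comparisons:
            stage = "univariate"
            integrals = stats.metabolite_integrals(fm, assignments)
            fct = stats.build_fold_change_table(
                integrals, fm.manifest,
                [(t, c) for t, c in config.comparisons])
            fct.to_csv(os.path.join(out_dir, "fold_changes.csv"))
            fct.to_html(os.path.join(out_dir, "fold_changes.html"))
            results["n_significant"] = {
                f"{t}_vs_{c}": len(stats.significant_metabolites(
                    fct, comparison=f"{t}/{c}"))
                for t, c in config.comparisons
            }
            log.info("univariate: %s", results["n_significant"])

            # ---- pathway -------------------------------------------------
            stage = "pathway"
            library_pw = (pathway.load_library(config.inputs.pathway_index)
                          if config.inputs.pathway_index else pathway.toy_library())
            universe = set(assignments.metabolite)
            universe |= set().union(*(pg.nodes for pg in library_pw))
            for t, c in config.comparisons:
                hits = set(stats.significant_metabolites(
                    fct, comparison=f"{t}/{c}"))
                pw = pathway.metpa(hits, library_pw, universe)
                pw.to_csv(os.path.join(out_dir, f"pathway_{t}_vs_{c}.csv"),
                          index=False)
            log.info("pathway: %d pathways", len(library_pw))

        # ---- bioaccumulation --------------------------------------------
        if config.inputs.exposure:
            stage = "baf"
            records = pd.read_csv(config.inputs.exposure)
            bt2 = bioaccum.baf_table(records)
            bt2.to_csv(os.path.join(out_dir, "baf.csv"))
            with open(os.path.join(out_dir, "baf_summary.md"), "w") as fh:
                fh.write(bt2.to_markdown())
            results["baf_summary"] = bt2.summary.to_dict()
            log.info("baf: %d records", len(records))

        # ---- hash manifest ----------------------------------------------
        stage = "finalize"
        hashes = {}
        for root, _, files in os.walk(out_dir):
            for f in sorted(files):
                if f in ("run.log", "manifest_hashes.json"):
                    continue
                p = os.path.join(root, f)
                hashes[os.path.relpath(p, out_dir)] = _sha256(p)
        with open(os.path.join(out_dir, "manifest_hashes.json"), "w") as fh:
            json.dump(hashes, fh, indent=1, sort_keys=True)
        results["hashes"] = hashes
        log.info("done: %d artifacts", len(hashes))
        return results
    except Exception as e:
        log.error("stage %s failed: %s", stage, e)
        failed = os.path.join(out_dir, "failed")
        os.makedirs(failed, exist_ok=True)
        for name in os.listdir(out_dir):
            if name in ("failed", "run.log"):
                continue
            shutil.move(os.path.join(out_dir, name), os.path.join(failed, name))
        raise PipelineError(stage, e) from e
    finally:
        log.removeHandler(handler)
        handler.close()
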