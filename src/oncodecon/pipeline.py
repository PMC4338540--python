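"""End-to-end orchestration: simulate/load -> deconvolute -> structure ->
phenotypes -> survive -> report, with one global seed, per-stage derived
streams, deterministic TSV outputs and a JSON run manifest."""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cio
from . import deconvolution as dc
from . import phenotype as ph
from . import structure as st
from . import survival as sv
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "deconvolute", "structure", "phenotypes", "survive")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global one (stage toggling
    must not shift other stages' randomness)."""
    return int(np.random.SeedSequence(
        entropy=seed, spawn_key=(ALL_STAGES.index(stage) if stage in ALL_STAGES else 99,)
    ).generate_state(1)[0] % (2**31))


def default_run_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "sim": {},            # overrides for SimulationConfig
        "n_pcs": 20,
        "fdr": 0.05,
        "cv_folds": 5,
        "min_recurrence": 5,
        "stages": list(ALL_STAGES),
    }


def run_pipeline(config: dict, out_dir: str | Path,
                 bundle: cio.CohortBundle | None = None) -> Path:
    """Execute the configured stages into ``out_dir``; returns the run dir.

    If ``bundle`` is given the simulate stage is skipped and the provided
    cohort is analysed instead.
    """
    cfg = default_run_config()
    cfg.update(config or {})
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValueError("run config must set a seed")
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    timings: dict[str, float] = {}

    def timed(stage: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = _time.perf_counter()
                logger.info("stage %s: start", stage)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[stage] = round(_time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", stage, exc)
                else:
                    logger.info("stage %s: done in %.1fs", stage, timings[stage])
                return False
        return _T()

    truth = None
    if bundle is None:
        with timed("simulate"):
            sim_cfg = SimulationConfig.from_dict({**cfg.get("sim", {}),
                                                  "seed": stage_seed(seed, "simulate")})
            bundle, truth = simulate_cohort(sim_cfg)
            cio.write_cohort(bundle, out / "cohort")
            cio.write_tsv(truth.effect_matrix, out / "cohort" / "truth_effects.tsv",
                          index_label="lesion")
            cio.write_tsv(truth.risk_components, out / "cohort" / "truth_risk.tsv",
                          index_label="sample")

    # shared preliminaries for analysis stages
    patients = [s for s in bundle.samples if bundle.normal_flag.loc[s] != 1]
    pca = dc.run_pca(bundle.expression.values,
                     k=min(cfg["n_pcs"], bundle.n_samples - 1,
                           len(bundle.expression.genes)))
    model = None

    if "deconvolute" in stages:
        with timed("deconvolute"):
            design = dc.build_design_matrix(bundle, min_recurrence=cfg["min_recurrence"])
            model = dc.GeneLesionDeconvolution(fdr=cfg["fdr"]).fit(
                design, bundle.expression.values)
            cio.write_tsv(model.to_frame(), out / "gene_fits.tsv", index_label="gene")
            cio.write_tsv(pca.scores, out / "pca_scores.tsv", index_label="sample")
            cio.write_tsv(
                pd.DataFrame({"variance_fraction": pca.variance_fractions},
                             index=[f"PC{i+1}" for i in range(len(pca.variance_fractions))]),
                out / "pca_variance.tsv", index_label="component")
            tsets = model.target_sets()
            for lesion, table in tsets.items():
                cio.write_tsv(table, out / "target_sets" / f"{lesion}.tsv",
                              index_label="gene")
            prior = {"d0": model.d0_, "s0_sq": model.s0_sq_,
                     "n_significant_F": int((model.q_f_ < cfg["fdr"]).sum())}
            (out / "moderation.json").write_text(json.dumps(prior, indent=2) + "\n")

    if "structure" in stages:
        with timed("structure"):
            if model is None:
                design = dc.build_design_matrix(bundle, min_recurrence=cfg["min_recurrence"])
                model = dc.GeneLesionDeconvolution(fdr=cfg["fdr"]).fit(
                    design, bundle.expression.values)
            tsets = {l: set(t.index) for l, t in model.target_sets().items()
                     if l in bundle.lesions.lesions}
            summary = st.structure_summary(
                bundle.lesions.values.loc[patients], tsets,
                seed=stage_seed(seed, "structure"),
                universe_size=len(bundle.expression.genes))
            cio.write_tsv(summary["table"].set_index("lesion_a"),
                          out / "pairwise_structure.tsv", index_label="lesion_a")
            (out / "structure_summary.json").write_text(json.dumps(
                {"spearman_rho": summary["spearman_rho"],
                 "p_permutation": summary["p_permutation"]}, indent=2) + "\n")

    if "phenotypes" in stages:
        with timed("phenotypes"):
            res = ph.model_phenotypes(bundle, pca.scores, n_pcs=cfg["n_pcs"],
                                      cv=cfg["cv_folds"],
                                      seed=stage_seed(seed, "phenotypes"))
            cio.write_tsv(res["summary"].set_index("phenotype"),
                          out / "phenotype_models.tsv", index_label="phenotype")
            if len(res["attribution"]):
                cio.write_tsv(res["attribution"].set_index("phenotype"),
                              out / "variance_attribution.tsv", index_label="phenotype")

    if "survive" in stages:
        with timed("survive"):
            sseed = stage_seed(seed, "survive")
            comp = sv.compare_predictor_classes(bundle, pca.scores,
                                                folds=cfg["cv_folds"], seed=sseed,
                                                n_pcs=cfg["n_pcs"])
            cio.write_tsv(comp.set_index("class"), out / "concordance.tsv",
                          index_label="class")
            X, groups = sv.survival_design(bundle, pca.scores, "all",
                                           n_pcs=cfg["n_pcs"])
            keep = X.notna().all(axis=1)
            svv = bundle.survival.values.loc[X.index]
            keep &= svv["time_days"].notna() & svv["status"].notna()
            Xc = X.loc[keep]
            t = svv.loc[keep, "time_days"].to_numpy(float)
            s = svv.loc[keep, "status"].to_numpy(float)
            fit = sv.RidgeCoxPH(tau=1.0).fit(Xc, t, s)
            decomp = sv.decompose_risk_variance(Xc, fit.coef_, groups)
            cio.write_tsv(decomp.set_index("group"), out / "risk_decomposition.tsv",
                          index_label="group")
            km = sv.kaplan_meier_terciles(fit.predict_risk(Xc), t, s)
            cio.write_tsv(km["curves"], out / "km_terciles.tsv", index_label="time_days")

    logger.info("stage timings: %s", json.dumps(timings))
    cio.write_manifest(out, cfg, seed)
    return out


REPORT_SECTIONS = (
    ("Moderated deconvolution", "moderation.json"),
    ("Target sets", "gene_fits.tsv"),
    ("Co-mutation structure", "structure_summary.json"),
    ("Phenotype models", "phenotype_models.tsv"),
    ("Survival concordance", "concordance.tsv"),
    ("Risk decomposition", "risk_decomposition.tsv"),
)


def generate_report(run_dir: str | Path) -> tuple[str, bool]:
    """Summarise a completed run directory as markdown; flags missing stages."""
    run = Path(run_dir)
    lines = ["# Cohort analysis report", ""]
    complete = True
    for title, fname in REPORT_SECTIONS:
        path = run / fname
        lines.append(f"## {title}")
        if not path.exists():
            lines.append("MISSING: stage output not found\n")
            complete = False
            continue
        if fname.endswith(".json"):
            lines.append("```json")
            lines.append(path.read_text().strip())
            lines.append("```")
        else:
            df = pd.read_csv(path, sep="\t")
            if fname == "gene_fits.tsv":
                qcols = [c for c in df.columns if c.startswith("q.") and c != "q.F"]
                counts = {c[2:]: int((df[c] < 0.05).sum()) for c in qcols}
                counts["any (moderated F)"] = int((df["q.F"] < 0.05).sum())
                lines.append("Significant genes (FDR<0.05) per covariate:")
                for k, v in counts.items():
                    lines.append(f"- {k}: {v}")
            else:
                lines.append(df.to_string(index=False, max_rows=30,
                                          float_format=lambda x: f"{x:.4g}"))
        lines.append("")
    text = "\n".join(lines) + "\n"
    report_path = run / "report.md"
    report_path.write_text(text)
    return text, complete
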