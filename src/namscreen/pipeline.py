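"""End-to-end orchestration: measurements in, the full results bundle out.

Chains vehicle normalization, QC, POD derivation, ToxPi scoring, clustering
with Fowlkes-Mallows evaluation, cross-validated class prediction, and
margin-of-exposure screening.  Every stage's output is written as a
delimited table; a JSON manifest records the configuration, seed, and
per-stage row counts so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, conc_response, grouping, risk, toxpi
from .io import RunConfig, load_classing, load_reference_classing, load_screen_table, load_tk_table, write_screen_table
from .synthetic import simulate_screen

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


def pod_feature_matrix(pods: pd.DataFrame) -> pd.DataFrame:
    """Chemicals x phenotypes matrix of -log10 POD bioactivity features.

    Censored PODs enter at their censoring bound, so an inactive chemical is
    a flat, minimally potent row.
    """
    df = pods.copy()
    df["key"] = [f"{ct}:{ph}" for ct, ph in zip(df["cell_type"], df["phenotype"])]
    wide = df.pivot_table(index="chemical", columns="key", values="pod_uM")
    return -np.log10(wide)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the configuration enables; return the results bundle.

    Stages with missing inputs are skipped with a notice (no toxicokinetic
    table -> no risk stage; no classing -> unsupervised clustering only).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(config).items()
            if k != "extra"
        },
        "stages": {},
    }
    results: dict = {}

    def _stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- inputs -----------------------------------------------------------
    if config.measurements_path is not None:
        measurements = load_screen_table(config.measurements_path)
    else:
        screen = simulate_screen(noise_sd=config.noise_sd, seed=config.seed)
        measurements = screen.measurements
        write_screen_table(measurements, out_dir / "measurements.csv")
        screen.truth.to_csv(out_dir / "truth.csv", index=False)
    classing = (
        load_classing(config.classing_path)
        if config.classing_path is not None
        else load_reference_classing()
    )
    # restrict to chemicals present in both, mirroring pairwise exclusion
    tested = set(measurements["chemical"])
    classing = classing[classing["chemical"].isin(tested)]
    have_classing = not classing.empty
    manifest["stages"]["inputs"] = {
        "n_wells": int(len(measurements)),
        "n_classed_chemicals": int(len(classing)),
    }

    # --- concentration-response -------------------------------------------
    @_stage("conc_response")
    def _():
        normalized, vstats = conc_response.normalize_to_vehicle(measurements)
        results["qc_report"] = conc_response.qc_assay(normalized)
        results["pods"] = conc_response.pod_table(normalized, vstats)
        results["category_contrast"] = conc_response.phenotype_category_contrast(
            results["pods"]
        )

    pods = results["pods"]
    pods.to_csv(out_dir / "pods.csv", index=False)
    results["qc_report"].to_csv(out_dir / "qc_report.csv", index=False)
    results["category_contrast"].to_csv(out_dir / "category_contrast.csv", index=False)
    manifest["stages"]["conc_response"] = {
        "n_pods": int(len(pods)),
        "n_censored": int(pods["censored"].sum()),
    }

    # --- ToxPi ------------------------------------------------------------
    @_stage("toxpi")
    def _():
        matrix = toxpi.scale_pod_matrix(pods, scale_mode=config.scale_mode)
        results["toxpi_profiles"] = toxpi.toxpi_profile(matrix)
        if have_classing:
            results["class_ranges"] = toxpi.class_score_ranges(
                results["toxpi_profiles"], classing
            )

    results["toxpi_profiles"].to_csv(out_dir / "toxpi_profiles.csv", index=False)
    if "class_ranges" in results:
        results["class_ranges"].to_csv(out_dir / "class_ranges.csv", index=False)
    manifest["stages"]["toxpi"] = {"n_chemicals": int(len(results["toxpi_profiles"]))}

    # --- grouping ---------------------------------------------------------
    @_stage("grouping")
    def _():
        features = pod_feature_matrix(pods)
        labels, tree = grouping.cluster_chemicals(
            features, distance=config.distance, linkage=config.linkage, k=config.k
        )
        results["clusters"] = labels
        results["cluster_tree"] = tree
        if have_classing:
            reference = pd.Series(
                classing.set_index("chemical")["chem_class"].reindex(labels.index)
            )
            fm = grouping.fm_index(labels, reference)
            fm = grouping.fm_significance(fm, mode="analytic")
            results["fm"] = fm

    results["clusters"].rename("cluster").to_csv(out_dir / "clusters.csv")
    if "fm" in results:
        fm = results["fm"]
        (out_dir / "fm_index.json").write_text(
            json.dumps(
                {
                    "fm_index": fm.b,
                    "expected_under_null": fm.expected_b,
                    "z": fm.z,
                    "p_one_sided": fm.p,
                    "null_mode": fm.null_mode,
                },
                indent=2,
            )
        )
        manifest["stages"]["grouping"] = {"fm_index": fm.b, "p": fm.p}
    else:
        log.info("no classing table: FM evaluation skipped")
        manifest["stages"]["grouping"] = {"fm_index": None}

    # --- classification ---------------------------------------------------
    if have_classing:

        @_stage("classify")
        def _():
            features = pod_feature_matrix(pods)
            y = classing.set_index("chemical")["chem_class"].reindex(features.index)
            scheme = classify.CVScheme(
                folds=config.cv_folds, repeats=config.cv_repeats, seed=config.seed
            )
            model = classify.ModelConfig(n_estimators=config.n_trees)
            results["confusion"] = classify.repeated_cv_classify(features, y, scheme, model)
            results["importance"] = classify.feature_importance(
                features, y, scheme, model, k=10
            )

        results["confusion"].matrix.to_csv(out_dir / "confusion_matrix.csv")
        results["importance"].to_csv(out_dir / "feature_importance.csv", index=False)
        manifest["stages"]["classify"] = {
            "accuracy_pct": results["confusion"].accuracy,
        }
    else:
        log.info("no classing table: supervised classification skipped")

    # --- risk -------------------------------------------------------------
    if config.tk_path is not None:

        @_stage("risk_moe")
        def _():
            tk = load_tk_table(config.tk_path)
            records = risk.records_from_table(tk)
            surrogates = risk.surrogate_pod(pods, scope="all")
            results["moe"] = risk.margin_of_exposure(
                surrogates, records, benchmark=config.moe_benchmark
            )

        results["moe"].to_csv(out_dir / "moe.csv", index=False)
        manifest["stages"]["risk_moe"] = {
            "n_concern": results["moe"].attrs.get("n_concern", 0),
            "n_total": results["moe"].attrs.get("n_total", 0),
        }
    else:
        log.info("no toxicokinetic table: risk stage skipped")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
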