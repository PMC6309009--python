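"""End-to-end orchestration of the social-structure analysis.

``run_pipeline`` drives the full sequence - preparation, association
indices, permutation tests, sampling precision, structural predictors,
Mantel screens, affiliation modelling, social-unit detection, network
metrics and temporal decay models - from a single configuration dictionary,
writing every artefact plus a JSON manifest into a run directory.  Stages
can be toggled; a stage whose inputs were disabled refuses to run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, community, data_model, gai, permutations, precision, predictors, temporal
from .synthetic import simulate, study_like_scenario

__all__ = ["default_config", "run_pipeline"]


def default_config(seed: int = 0, scale: str = "test") -> dict:
    """Configuration template.

    ``scale='full'`` uses the study-scale permutation counts (40,000 swaps
    chains, 20,000 MRQAP permutations, 10,000 metric permutations, 10,000
    bootstraps); ``'test'`` scales everything down for quick runs.
    """
    full = scale == "full"
    return {
        "seed": seed,
        "half_boundary_date": "2011-01-01",
        "index_for_tests": "hwi",
        "stages": {
            "prepare": True,
            "association": True,
            "permutation_tests": True,
            "precision": True,
            "predictors": True,
            "gai": True,
            "community": True,
            "metrics": True,
            "temporal": True,
        },
        "permutations": {
            "n_permutations": 40_000 if full else 1_000,
            "flips_per_permutation": 1_000 if full else 100,
            "burn_in": 1_000,
        },
        "mrqap_permutations": 20_000 if full else 500,
        "metric_permutations": 10_000 if full else 200,
        "n_boot": 10_000 if full else 100,
        "mantel_permutations": 10_000 if full else 1_000,
        "snar_randomisations": 100 if full else 20,
        "jackknife_reps": 1000 if full else 30,
        "slar_window": None,
        "kde_cell": 250.0,
        "include_homerange": True,
        "hwig_display_threshold": 1.0,
        "anscombe_threshold": 2.5,
        "stepwise_alpha": 0.05,
        "stepwise_pc_threshold": 0.1,
    }


def _write_matrix(m, path: Path) -> None:
    m.to_frame().to_csv(path)
    m.to_long().to_csv(path.with_name(path.stem + "_long.csv"), index=False)


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    records: pd.DataFrame | None = None,
    group_meta: pd.DataFrame | None = None,
    individual_meta: pd.DataFrame | None = None,
    scenario=None,
) -> dict:
    """Execute the configured stages and return the result summary.

    Either pass the three input tables or a generator scenario (defaulting
    to the study-like preset when all are omitted).  Artefacts land in
    ``out_dir``; the returned dict collects the headline numbers and is also
    written as ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config["stages"]
    summary: dict = {"seed": seed}

    if records is None:
        scenario = scenario or study_like_scenario(seed=seed)
        sim = simulate(scenario, seed=seed)
        records, group_meta, individual_meta = sim.records, sim.group_meta, sim.individual_meta
        sim.truth.to_csv(out / "ground_truth.csv", index=False)
        summary["simulated"] = True

    state: dict = {}
    try:
        if stages.get("prepare"):
            prep = data_model.prepare(
                records, group_meta, individual_meta, config["half_boundary_date"]
            )
            prep.records.to_csv(out / "records_retained.csv", index=False)
            prep.group_exclusions.to_csv(out / "group_exclusions.csv", index=False)
            prep.individual_exclusions.to_csv(out / "individual_exclusions.csv", index=False)
            prep.classes.to_csv(out / "classes.csv", index=False)
            state["records"] = prep.records
            state["classes"] = prep.classes
            summary["n_individuals_retained"] = int(prep.records["individual_id"].nunique())
            summary["n_occasions"] = int(prep.records["occasion_id"].nunique())
            summary["n_groups_excluded"] = int(len(prep.group_exclusions))

        if stages.get("association"):
            _need(state, "records", "association", "prepare")
            counts = association.tally_counts(state["records"])
            hwi_m = association.hwi(counts)
            hwig_m = association.hwig(hwi_m)
            tgs, tgs_sd = association.typical_group_size(state["records"])
            state.update(counts=counts, hwi=hwi_m, hwig=hwig_m)
            _write_matrix(hwi_m, out / "hwi.csv")
            _write_matrix(hwig_m, out / "hwig.csv")
            tgs.to_csv(out / "typical_group_size.csv")
            vals = hwig_m.offdiag()
            summary["hwig_mean"] = float(np.nanmean(vals))
            summary["hwig_max"] = float(np.nanmax(vals))
            summary["sd_typical_group_size"] = tgs_sd
            summary["mean_group_size"] = float(
                state["records"].groupby(["occasion_id", "group_id"])["individual_id"]
                .nunique().mean()
            )

        if stages.get("permutation_tests"):
            _need(state, "records", "permutation_tests", "prepare")
            pcfg = permutations.PermutationConfig(
                seed=seed, index=config.get("index_for_tests", "hwi"),
                **config["permutations"],
            )
            comp = permutations.companionship_test(state["records"], pcfg)
            greg = permutations.gregariousness_test(state["records"], pcfg)
            rows = [
                {
                    "statistic": r.statistic,
                    "real": r.real_value,
                    "null_mean": r.null_mean,
                    "p": r.p_value,
                    "tail": r.tail,
                }
                for r in [*comp.values(), greg]
            ]
            pd.DataFrame(rows).to_csv(out / "permutation_tests.csv", index=False)
            summary["companionship_sd_p"] = comp["sd"].p_value
            summary["prop_nonzero_p"] = comp["prop_nonzero"].p_value
            summary["gregariousness_real_sd"] = greg.real_value
            summary["gregariousness_null_sd"] = greg.null_mean
            summary["gregariousness_p"] = greg.p_value

        if stages.get("precision"):
            _need(state, "counts", "precision", "association")
            inc = permutations.build_incidence(state["records"], state["counts"].ids)
            est = precision.estimate_social_differentiation(
                state["counts"], inc, n_boot=min(int(config["n_boot"]), 200),
                seed=seed,
            )
            (out / "precision.json").write_text(json.dumps(asdict(est), indent=2))
            summary["social_differentiation_S"] = est.S
            summary["precision_r"] = est.r

        if stages.get("predictors"):
            _need(state, "hwi", "predictors", "association")
            preds = predictors.build_predictor_set(
                state["records"], state["hwi"], state["classes"],
                cell=config["kde_cell"],
                include_homerange=config.get("include_homerange", True),
            )
            state["predictors"] = preds
            for name, m in preds.items():
                _write_matrix(m, out / f"predictor_{name}.csv")
            mantel_rows = []
            for cls_col, pred in (
                ("area_class", "area_match"),
                ("period_class", "period_match"),
                ("sex", "sex_match"),
            ):
                labels = state["classes"].set_index("individual_id")[cls_col]
                t, p = permutations.mantel_class_test(
                    state["hwig"], labels,
                    n_perm=config["mantel_permutations"], seed=seed,
                )
                mantel_rows.append({"class": cls_col, "t": t, "p": p})
            pd.DataFrame(mantel_rows).to_csv(out / "mantel_tests.csv", index=False)
            summary["mantel"] = {r["class"]: r["p"] for r in mantel_rows}

        if stages.get("gai"):
            _need(state, "predictors", "gai", "predictors")
            retained, table = gai.stepwise_select(
                state["hwi"], state["predictors"],
                n_perm=config["mrqap_permutations"], seed=seed,
                alpha=config["stepwise_alpha"],
                pc_threshold=config["stepwise_pc_threshold"],
            )
            if table is not None:
                table.to_csv(out / "mrqap.csv")
            model = gai.fit_dyadic_binomial(
                state["counts"], {k: state["predictors"][k] for k in retained}
            )
            state["gai"] = model
            _write_matrix(model.deviance_residuals, out / "gai.csv")
            calls = gai.call_affiliations(
                model.anscombe_residuals, config["anscombe_threshold"]
            )
            pd.DataFrame(calls.strong_affiliations, columns=["id1", "id2", "residual"]).to_csv(
                out / "strong_affiliations.csv", index=False
            )
            pd.DataFrame(calls.strong_avoidances, columns=["id1", "id2", "residual"]).to_csv(
                out / "strong_avoidances.csv", index=False
            )
            summary["gai_retained_predictors"] = retained
            summary["n_strong_affiliations"] = calls.n_affiliations
            summary["n_strong_avoidances"] = calls.n_avoidances

        if stages.get("community"):
            _need(state, "hwig", "community", "association")
            part_hwig = community.newman_eigenvector_partition(state["hwig"], kind="HWIG")
            state["partition_hwig"] = part_hwig
            part_hwig.to_frame().to_csv(out / "units_hwig.csv", index=False)
            summary["q_hwig"] = part_hwig.q
            summary["n_units_hwig"] = part_hwig.n_units
            edges = community.network_export(
                state["hwig"], config["hwig_display_threshold"], part_hwig
            )
            edges.to_csv(out / "edges_hwig.csv", index=False)
            community.write_graphml(edges, out / "edges_hwig.graphml")
            if "gai" in state:
                part_gai = community.newman_eigenvector_partition(
                    state["gai"].deviance_residuals, kind="GAI"
                )
                state["partition_gai"] = part_gai
                part_gai.to_frame().to_csv(out / "units_gai.csv", index=False)
                summary["q_gai"] = part_gai.q
                summary["n_units_gai"] = part_gai.n_units

        if stages.get("metrics"):
            _need(state, "partition_hwig", "metrics", "community")
            met = community.node_metrics(state["hwig"])
            met.to_csv(out / "node_metrics_hwig.csv")
            pcfg = permutations.PermutationConfig(
                n_permutations=config["metric_permutations"],
                flips_per_permutation=config["permutations"]["flips_per_permutation"],
                seed=seed, index="hwig",
            )
            inc = permutations.build_incidence(state["records"], state["hwig"].ids)
            cmp_tbl = community.metric_permutation_compare(inc, state["partition_hwig"], pcfg)
            cmp_tbl.to_csv(out / "metric_permutation_compare.csv", index=False)
            summary["mean_strength_hwig"] = float(met["strength"].mean())

        if stages.get("temporal"):
            _need(state, "records", "temporal", "prepare")
            window = config.get("slar_window")
            curve = temporal.slar(state["records"], window=window)
            ev = temporal.pair_events(state["records"])
            nullc = temporal.snar(
                state["records"], window=window,
                n_rand=config["snar_randomisations"], seed=seed,
            )
            try:
                with np.errstate(all="ignore"):
                    jk = temporal.jackknife_se(
                        state["records"], window=window,
                        reps=int(config.get("jackknife_reps", 1000)),
                    )
                curve.se = jk.se
            except ValueError:
                pass
            curve.null_rate = np.interp(curve.lag, nullc.lag, nullc.rate)
            curve.to_frame().to_csv(out / "slar.csv", index=False)
            fits = temporal.fit_decay_models(ev, seed=seed)
            pd.DataFrame(
                [
                    {
                        "model": f.model, "k": f.k, "loglik": f.loglik,
                        "c_hat": f.c_hat, "qaic": f.qaic,
                        "delta_qaic": f.delta_qaic, "weight": f.weight,
                        **{f"param_{k}": v for k, v in f.parameters.items()},
                    }
                    for f in fits
                ]
            ).to_csv(out / "decay_models.csv", index=False)
            summary["best_decay_model"] = fits[0].model
            summary["slar_mean"] = float(np.average(curve.rate, weights=curve.den))
    except Exception as err:
        (out / "FAILED_STAGE.txt").write_text(f"{type(err).__name__}: {err}\n")
        raise

    manifest = {
        "config": {k: v for k, v in config.items() if k != "stages"} | {"stages": stages},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def _need(state: dict, key: str, stage: str, producer: str) -> None:
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r} needs outputs of disabled stage {producer!r}"
        )
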