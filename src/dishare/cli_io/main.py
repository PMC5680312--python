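"""Command-line entry points tying the pipeline into reproducible runs.

Every command writes its resolved configuration and a provenance log
(input checksums, package versions, wall clock) next to its outputs, and
all randomness flows from one top-level seed via spawned seed sequences.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from .. import __version__, core, evaluate, screening, simulate, stability
from ..preprocess import preprocess_cohort, make_cohort_pair
from . import fixture as fixture_mod
from . import io as dio

__all__ = ["cli"]


def _write_config(outdir: Path, config: dict) -> None:
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True)
    )


def _write_log(outdir: Path, entries: dict) -> None:
    entries = {
        "dishare_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **entries,
    }
    (outdir / "log.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in entries.items()) + "\n"
    )


def _fit_options_from(config: dict, seed: int) -> core.FitOptions:
    return core.FitOptions(
        cv_folds=config["cv_folds"],
        n_lambda1=config["n_lambda1"],
        lambda2_values=tuple(config["lambda2_values"]),
        lambda1_min_ratio=config["lambda1_min_ratio"],
        seed=seed,
    )


@click.group()
@click.version_option(version=__version__)
def cli():
    """Cross-cohort penalized regression toolkit."""


@cli.command("fixture")
@click.option("--seed", type=int, required=True, help="Random seed.")
@click.option("--preset", default="small", show_default=True,
              type=click.Choice(sorted(fixture_mod.PRESETS)))
@click.option("--out", "outdir", type=click.Path(file_okay=False), required=True)
def cli_fixture(seed, preset, outdir):
    """Generate the synthetic paired-cohort fixture files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    fx = fixture_mod.make_fixture(seed=seed, preset=preset)
    paths = fixture_mod.write_fixture(fx, outdir)
    _write_config(outdir, {"command": "fixture", "seed": seed, "preset": preset})
    _write_log(outdir, {
        "wall_clock_s": round(time.time() - t0, 3),
        **{f"sha256_{k}": dio.sha256_of(v) for k, v in paths.items()},
    })
    click.echo(f"fixture written to {outdir}")


@cli.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML file with SimulationConfig keys.")
@click.option("--seed", type=int, default=None, help="Overrides the config seed.")
@click.option("--replicates", type=int, default=None)
@click.option("--p", type=int, default=None)
@click.option("--n-g", type=int, default=None)
@click.option("--n-c", type=int, default=None)
@click.option("--out", "outdir", type=click.Path(file_okay=False), required=True)
def cli_simulate(config_path, seed, replicates, p, n_g, n_c, outdir):
    """Run the replicated synthetic comparison study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict: dict = {}
    if config_path:
        cfg_dict.update(yaml.safe_load(Path(config_path).read_text()) or {})
    for key, val in (
        ("seed", seed), ("n_replicates", replicates), ("p", p),
        ("n_G", n_g), ("n_C", n_c),
    ):
        if val is not None:
            cfg_dict[key] = val
    if "seed" not in cfg_dict:
        raise click.UsageError("a seed is required (--seed or config key 'seed')")
    for key in ("lambda2_values", "methods"):
        if key in cfg_dict:
            cfg_dict[key] = tuple(cfg_dict[key])
    try:
        config = simulate.SimulationConfig(**cfg_dict)
    except (TypeError, ValueError) as exc:
        raise click.UsageError(f"invalid simulation config: {exc}") from exc
    t0 = time.time()
    result = simulate.run_simulation_study(config)
    result.replicates.to_csv(outdir / "replicates.tsv", sep="\t", index=False,
                             float_format="%.10g")
    summary_rows = []
    for name, summ in {**result.mse_summaries}.items():
        summary_rows.append({"metric": f"mse_{name}", **dict(zip(
            ("min", "q1", "median", "q3", "max"), summ.as_tuple()))})
    for name, summ in {**result.corr_summaries}.items():
        summary_rows.append({"metric": f"corr_{name}", **dict(zip(
            ("min", "q1", "median", "q3", "max"), summ.as_tuple()))})
    pd.DataFrame(summary_rows).to_csv(outdir / "summaries.tsv", sep="\t",
                                      index=False, float_format="%.10g")
    _plot_mse_boxes(result, outdir / "test_error_boxplot.png")
    cfg_echo = dataclasses.asdict(config)
    cfg_echo["lambda2_values"] = list(config.lambda2_values)
    cfg_echo["methods"] = list(config.methods)
    _write_config(outdir, {"command": "simulate", **cfg_echo})
    _write_log(outdir, {"wall_clock_s": round(time.time() - t0, 3)})
    click.echo(f"simulation study written to {outdir}")


def _plot_mse_boxes(result, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cols = [c for c in result.replicates.columns if c.startswith("mse_")]
    fig, ax = plt.subplots(figsize=(1.5 * len(cols) + 2, 4))
    ax.boxplot([result.replicates[c] for c in cols],
               tick_labels=[c.removeprefix("mse_") for c in cols])
    ax.set_ylabel("test MSE")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


_ANALYZE_DEFAULTS = dict(
    screen_k=30,
    stability_runs=200,
    cv_folds=10,
    n_lambda1=10,
    lambda2_values=[0.01, 0.1],
    lambda1_min_ratio=0.01,
    max_missing_count=10_000,
    max_missing_rate=0.3,
    include_copy_number=True,
    formulation="F1",
)


def _load_drug_cohorts(features, responses, drug, config):
    resp = responses[responses["drug"] == drug]
    resp = resp.set_index("cell_line")["response_value"]
    rows = [i for i, rid in enumerate(features.row_ids) if rid in resp.index]
    if not rows:
        return None
    table = features.take_rows(rows)
    y = resp.loc[list(table.row_ids)].to_numpy(dtype=float)
    kinds = None
    if not config["include_copy_number"]:
        kinds = ("mutation", "expression", "tissue")
    return preprocess_cohort(
        table, y,
        max_missing_count=config["max_missing_count"],
        max_missing_rate=config["max_missing_rate"],
        include_kinds=kinds,
    )


@cli.command("analyze")
@click.option("--features-g", type=click.Path(exists=True), required=True)
@click.option("--responses-g", type=click.Path(exists=True), required=True)
@click.option("--features-c", type=click.Path(exists=True), required=True)
@click.option("--responses-c", type=click.Path(exists=True), required=True)
@click.option("--out", "outdir", type=click.Path(file_okay=False), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--screen-k", type=int, default=None)
@click.option("--stability-runs", type=int, default=None)
@click.option("--cv-folds", type=int, default=None)
@click.option("--exclude-copy-number", is_flag=True, default=False)
@click.option("--formulation", type=click.Choice(["F1", "F2"]), default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def cli_analyze(features_g, responses_g, features_c, responses_c, outdir, seed,
                screen_k, stability_runs, cv_folds, exclude_copy_number,
                formulation, config_path):
    """Full per-drug pipeline: preprocess, screen, fit, stability, signature."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(_ANALYZE_DEFAULTS)
    if config_path:
        config.update(yaml.safe_load(Path(config_path).read_text()) or {})
    for key, val in (
        ("screen_k", screen_k), ("stability_runs", stability_runs),
        ("cv_folds", cv_folds),
        ("formulation", formulation),
    ):
        if val is not None:
            config[key] = val
    if exclude_copy_number:
        config["include_copy_number"] = False
    config["seed"] = seed
    t0 = time.time()
    inputs = {
        "features_G": features_g, "responses_G": responses_g,
        "features_C": features_c, "responses_C": responses_c,
    }
    feat_G = dio.read_feature_table(features_g)
    feat_C = dio.read_feature_table(features_c)
    resp_G = dio.read_response_table(responses_g)
    resp_C = dio.read_response_table(responses_c)
    drugs = sorted(set(resp_G["drug"]) & set(resp_C["drug"]))
    if not drugs:
        raise click.ClickException("the two cohorts share no drugs")
    form = core.Formulation(config["formulation"])
    ss = np.random.SeedSequence(seed)
    drug_seeds = ss.spawn(len(drugs))
    results = {}
    for drug, dseed in zip(drugs, drug_seeds):
        ddir = outdir / drug
        ddir.mkdir(parents=True, exist_ok=True)
        cg = _load_drug_cohorts(feat_G, resp_G, drug, config)
        cc = _load_drug_cohorts(feat_C, resp_C, drug, config)
        if cg is None or cc is None:
            click.echo(f"skipping {drug}: no overlapping cell lines", err=True)
            continue
        (ddir / "preprocess_log.json").write_text(
            json.dumps({"G": cg.log, "C": cc.log}, indent=2, sort_keys=True)
        )
        pair = make_cohort_pair(cg, cc)
        scr = screening.sis_union_screen(pair, config["screen_k"])
        pd.DataFrame({
            "feature": [pair.feature_names[j] for j in scr.selected_indices],
            "abs_corr_G": scr.per_cohort_rank[0][scr.selected_indices],
            "abs_corr_C": scr.per_cohort_rank[1][scr.selected_indices],
        }).to_csv(ddir / "screen.tsv", sep="\t", index=False)
        pair_s = scr.screened
        s_fit, s_stab = (int(x.generate_state(1)[0]) for x in dseed.spawn(2))
        opts = _fit_options_from(config, s_fit)
        fit = core.fit_shared(pair_s, formulation=form, options=opts)
        coef = {"feature": list(pair_s.feature_names), "beta": fit.beta}
        if form == core.Formulation.F1:
            coef["delta"] = fit.delta
        else:
            coef["delta_G"] = fit.delta_G
            coef["delta_C"] = fit.delta_C
        pd.DataFrame(coef).to_csv(ddir / "coefficients.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        vlist = stability.run_stability(
            pair_s, n_runs=config["stability_runs"], seed=s_stab,
            formulation=form, options=opts,
        )
        for ledger in vlist.ledgers:
            vlist.to_frame(ledger).to_csv(
                ddir / f"variable_list_{ledger}.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        results[drug] = vlist
    sig = stability.build_signature_matrix(results)
    sig_df = sig.to_frame()
    sig_df.to_csv(outdir / "signature_matrix.tsv", sep="\t",
                  float_format="%.10g")
    stability.plot_signature(sig, outdir / "signature_matrix.png")
    _write_config(outdir, {"command": "analyze", **config})
    _write_log(outdir, {
        "wall_clock_s": round(time.time() - t0, 3),
        "drugs": ",".join(results),
        **{f"sha256_{k}": dio.sha256_of(v) for k, v in inputs.items()},
    })
    click.echo(f"analysis written to {outdir}")


@cli.command("evaluate")
@click.option("--features-g", type=click.Path(exists=True), required=True)
@click.option("--responses-g", type=click.Path(exists=True), required=True)
@click.option("--features-c", type=click.Path(exists=True), required=True)
@click.option("--responses-c", type=click.Path(exists=True), required=True)
@click.option("--drug", required=True)
@click.option("--out", "outdir", type=click.Path(file_okay=False), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--scenario", type=click.Choice(["1", "2"]), default="2")
@click.option("--splits", type=int, default=200, show_default=True)
@click.option("--test-cohort", type=click.Choice(["G", "C"]), default="G")
@click.option("--screen-k", type=int, default=30)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def cli_evaluate(features_g, responses_g, features_c, responses_c, drug, outdir,
                 seed, scenario, splits, test_cohort, screen_k, config_path):
    """Repeated-split test-error comparison for one drug."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(_ANALYZE_DEFAULTS)
    if config_path:
        config.update(yaml.safe_load(Path(config_path).read_text()) or {})
    config.update({"seed": seed, "scenario": int(scenario), "splits": splits,
                   "test_cohort": test_cohort, "screen_k": screen_k,
                   "drug": drug})
    t0 = time.time()
    feat_G = dio.read_feature_table(features_g)
    feat_C = dio.read_feature_table(features_c)
    resp_G = dio.read_response_table(responses_g)
    resp_C = dio.read_response_table(responses_c)
    cg = _load_drug_cohorts(feat_G, resp_G, drug, config)
    cc = _load_drug_cohorts(feat_C, resp_C, drug, config)
    if cg is None or cc is None:
        raise click.ClickException(f"drug {drug!r} is absent from a cohort")
    pair = make_cohort_pair(cg, cc)
    opts = _fit_options_from(config, seed)
    comparison = evaluate.compare_methods(
        pair, scenario=int(scenario), n_splits=splits, seed=seed,
        test_cohort=test_cohort, screen_k=screen_k, options=opts,
    )
    comparison.errors.to_csv(outdir / "errors.tsv", sep="\t", index=False,
                             float_format="%.10g")
    rows = [{"method": m, **dict(zip(("min", "q1", "median", "q3", "max"),
                                     s.as_tuple()))}
            for m, s in comparison.summaries.items()]
    pd.DataFrame(rows).to_csv(outdir / "summaries.tsv", sep="\t", index=False,
                              float_format="%.10g")
    comparison.comparisons.to_csv(outdir / "bdm_ovs.tsv", sep="\t", index=False)
    _write_config(outdir, {"command": "evaluate", **config})
    _write_log(outdir, {
        "wall_clock_s": round(time.time() - t0, 3),
        "sha256_features_G": dio.sha256_of(features_g),
        "sha256_features_C": dio.sha256_of(features_c),
    })
    click.echo(f"evaluation written to {outdir}")


if __name__ == "__main__":  # pragma: no cover
    cli()
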