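"""End-to-end valuation pipeline: QC -> weights -> candidate fits ->
selection -> bootstrap -> value set and summaries.

Driven by a single structured config (YAML/JSON or an equivalent dict):

.. code-block:: yaml

    seed: 7
    output_dir: results/run
    simulate:              # or data: {ctto: ..., dce: ..., respondents: ...}
      n_respondents: 400
    candidates:
      - {form: multiplicative8, intercept: false, data: hybrid}
      - {form: multiplicative8, intercept: true, data: hybrid}
    weighting:
      enabled: true        # margins default to the bundled population margins
    bootstrap_B: 200
    fit: {n_quad: 31, n_starts: 3}

Artifacts (all delimited text / JSON) are written under ``output_dir``:
qc_report.json, comparison_table.csv, selected_coefficients.csv,
value_set.csv (3,125 rows with SEs and CIs when bootstrapped), summary.json,
and run_log.txt.  Every artifact is deterministic given the config: the log
records the config hash, seeds and package versions, never wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fitting import FitOptions, qc_exclude, select_model
from .io import read_interview_data, write_interview_data
from .models import ModelSpec
from .state_space import score_all_states, valueset_summary, write_coefficients
from .synthetic_data import NORWAY_POPULATION_MARGINS, DEFAULT_TRUTH, simulate_study
from .uncertainty import bootstrap
from .weighting import compute_weights, read_margins

__all__ = ["run_pipeline", "load_config"]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[
        :16
    ]


def _spec_from(entry: dict) -> ModelSpec:
    return ModelSpec(
        form=entry.get("form", "multiplicative8"),
        intercept=bool(entry.get("intercept", False)),
        data=entry.get("data", "hybrid"),
    )


def run_pipeline(config) -> Path:
    """Run the full valuation analysis; returns the artifacts directory.

    Any stage failure raises with the stage name prefixed.
    """
    config = load_config(config)
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: list[str] = [
        f"eqvalue {__version__}",
        f"config_hash {_config_hash(config)}",
        f"seed {seed}",
    ]

    def stage(name):
        log.append(f"stage {name}")

    try:
        stage("data")
        if "simulate" in config:
            sim = dict(config["simulate"])
            n = int(sim.pop("n_respondents", 400))
            dataset = simulate_study(DEFAULT_TRUTH, n_respondents=n, seed=seed, **sim)
            log.append(f"simulated study n={n} seed={seed}")
            write_interview_data(dataset, out / "data")
        else:
            d = config["data"]
            dataset = read_interview_data(d["ctto"], d["dce"], d["respondents"])
            log.append(f"read data from {d}")
    except Exception as exc:
        raise RuntimeError(f"stage 'data' failed: {exc}") from exc

    try:
        stage("qc")
        dataset, qc_report = qc_exclude(dataset)
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2, default=int))
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    try:
        stage("weights")
        wcfg = config.get("weighting", {"enabled": False})
        weights = None
        weights_procedure = None
        if wcfg.get("enabled", False):
            margins = (
                read_margins(wcfg["margins"]) if "margins" in wcfg else NORWAY_POPULATION_MARGINS
            )
            chars = wcfg.get("characteristics")
            method = wcfg.get("method", "raking")

            def weights_procedure(respondents, _m=margins, _c=chars, _me=method):
                w = compute_weights(respondents, _m, characteristics=_c, method=_me)
                return pd.Series(w.to_numpy(), index=respondents["id"].to_numpy())

            weights = weights_procedure(dataset.respondents)
            log.append(f"raked weights: min {weights.min():.3f} max {weights.max():.3f}")
    except Exception as exc:
        raise RuntimeError(f"stage 'weights' failed: {exc}") from exc

    try:
        stage("fit_select")
        fit_cfg = config.get("fit", {})
        options = FitOptions(
            n_quad=int(fit_cfg.get("n_quad", 31)),
            n_starts=int(fit_cfg.get("n_starts", 3)),
            seed=seed,
        )
        candidates = [_spec_from(e) for e in config.get("candidates", [{}])]
        selection = select_model(candidates, dataset, weights, options)
        selection["comparison"].to_csv(out / "comparison_table.csv")
        selected = selection["selected"]
        write_coefficients(selected.params.coeffs, out / "selected_coefficients.csv")
        log.append(f"selected {selection['selected_spec'].label()}")
        for label, cv in selection["cv"].items():
            log.append(f"cv {label} rmse {cv['rmse']:.4f}")
    except Exception as exc:
        raise RuntimeError(f"stage 'fit_select' failed: {exc}") from exc

    try:
        stage("bootstrap")
        B = int(config.get("bootstrap_B", 0))
        if B >= 2:
            boot = bootstrap(
                selection["selected_spec"],
                dataset,
                B=B,
                seed=seed + 1,
                weights_procedure=weights_procedure,
                options=FitOptions(**{**options.__dict__, "n_starts": 1}),
                base_fit=selected,
            )
            boot.coefficients.to_csv(out / "coefficients_ci.csv")
            value_table = boot.values
            log.append(f"bootstrap B={B} converged {boot.n_converged}")
        else:
            value_table = score_all_states(selected.params.coeffs).table
    except Exception as exc:
        raise RuntimeError(f"stage 'bootstrap' failed: {exc}") from exc

    try:
        stage("value_set")
        value_table.to_csv(out / "value_set.csv")
        vs = score_all_states(
            selected.params.coeffs,
            provenance={"config_hash": _config_hash(config), "seed": seed},
        )
        summary = valueset_summary(vs)
        summary["selected_model"] = selection["selected_spec"].label()
        summary["fit_metrics"] = selected.metrics
        summary["config_hash"] = _config_hash(config)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage 'value_set' failed: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
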