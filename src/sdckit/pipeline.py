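"""End-to-end orchestration: simulate/load -> score -> model -> test -> report.

The pipeline mirrors the analysis workflow of a display-complexity study:

1. obtain focal data (synthetic study, or event logs + metadata from disk);
2. score every sequence (richness, versatility, SDC);
3. AICc model selection + zero-method averaging for each display response
   (gaussian) and for breeding status (binomial);
4. breeder vs non-breeder rank test;
5. randomization tests of age- and SDC-assortative mating;
6. prediction curve of SDC against age from the age + age^2 + date model.

Every artifact embeds the seed and a hash of the configuration so a run can
be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ethogram import load_repertoire, load_metadata, parse_focal_log, filter_complete
from .complexity import score_batch
from .multimodel import (
    DISPLAY_TERMS, BREEDING_TERMS, DEFAULT_EXCLUSIONS,
    build_predictor_table, generate_model_set, fit_glm, rank_models,
    model_average_zero, selection_table, predict_response,
)
from .inference import breeding_comparison, random_pairing_null, predicted_sdc_for_pairs
from .synthetic import GeneratorConfig, generate_study

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]

log = logging.getLogger(__name__)

#: Day-of-season (Nov 1 = 0) used for prediction curves: February 3.
FIXED_PREDICTION_DATE = 94.0


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run.

    With ``logs_dir``/``metadata_path`` unset the pipeline generates a
    synthetic study from ``generator`` (seeded by ``seed``).  Breeding and
    pairing stages run only when their tables are available; otherwise they
    are skipped and flagged in the run log.
    """

    out_dir: str | Path = "sdckit-run"
    seed: int = 0
    logs_dir: str | Path | None = None
    metadata_path: str | Path | None = None
    status_path: str | Path | None = None
    pairs_path: str | Path | None = None
    repertoire_path: str | Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    versatility_mode: str = "change-count"
    delta_threshold: float = 2.0
    n_sim: int = 1000
    fixed_date: float = FIXED_PREDICTION_DATE
    display_responses: tuple[str, ...] = ("sdc", "richness", "versatility")

    def config_hash(self) -> str:
        # out_dir is excluded: the same analysis written elsewhere is the same run
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _model_stage(scores: pd.DataFrame, response: str, family: str,
                 terms: tuple[str, ...], exclusions, delta: float):
    table, scaling = build_predictor_table(scores, response, terms)
    term_sets = generate_model_set(terms, exclusions=exclusions)
    fits = [fit_glm(table, response, ts, family) for ts in term_sets]
    ranked, top = rank_models(fits, delta_threshold=delta)
    averaged = model_average_zero(top)
    return table, scaling, ranked, top, averaged


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns a dict of the in-memory results (scores table, ranked models per
    response, averaged coefficients, test results).  Any stage failure
    removes partial outputs and raises :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tag = f"seed={config.seed} config_hash={config.config_hash()} sdckit={__version__}"
    results: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    skipped: list[str] = []
    stage = "setup"
    try:
        # ------------------------------------------------------------- data
        stage = "data"
        repertoire = load_repertoire(config.repertoire_path)
        if config.logs_dir is None:
            study = generate_study(config.generator, seed=config.seed, repertoire=repertoire)
            metadata, sequences = study.metadata, study.sequences
            status = study.breeding
            pairs = study.pairs
        else:
            metadata = load_metadata(config.metadata_path)
            sequences = [
                parse_focal_log(p, repertoire)
                for p in sorted(Path(config.logs_dir).glob("*.csv"))
            ]
            sequences = filter_complete(sequences)
            status = pd.read_csv(config.status_path) if config.status_path else None
            pairs = pd.read_csv(config.pairs_path) if config.pairs_path else None

        # ------------------------------------------------------------ score
        stage = "score"
        scores = score_batch(sequences, metadata, repertoire, mode=config.versatility_mode)
        path = out / "scores.csv"
        _write_csv(scores, path, tag)
        written.append(path)
        results["scores"] = scores

        # ------------------------------------------------------------ model
        stage = "model"
        selection_rows, averaged_rows = [], []
        display_fit = {}
        for response in config.display_responses:
            _, scaling, ranked, top, averaged = _model_stage(
                scores, response, "gaussian", DISPLAY_TERMS,
                DEFAULT_EXCLUSIONS, config.delta_threshold,
            )
            sel = selection_table(ranked)
            sel.insert(0, "response", response)
            selection_rows.append(sel)
            avg = averaged.reset_index()
            avg.insert(0, "response", response)
            averaged_rows.append(avg)
            display_fit[response] = {"ranked": ranked, "top": top,
                                     "averaged": averaged, "scaling": scaling}
        results["display_models"] = display_fit

        if status is not None and len(status) > 0:
            stage = "breeding-model"
            cohort = scores.merge(status, on="id")
            _, scaling_b, ranked_b, top_b, averaged_b = _model_stage(
                cohort, "breeder", "binomial", BREEDING_TERMS, (), config.delta_threshold,
            )
            sel = selection_table(ranked_b)
            sel.insert(0, "response", "breeder")
            selection_rows.append(sel)
            avg = averaged_b.reset_index()
            avg.insert(0, "response", "breeder")
            averaged_rows.append(avg)
            results["breeding_models"] = {"ranked": ranked_b, "top": top_b,
                                          "averaged": averaged_b}
        else:
            skipped.append("breeding-model")

        path = out / "model_selection.csv"
        _write_csv(pd.concat(selection_rows, ignore_index=True), path, tag)
        written.append(path)
        path = out / "averaged_coefficients.csv"
        _write_csv(pd.concat(averaged_rows, ignore_index=True), path, tag)
        written.append(path)

        # ----------------------------------------------------- breeding test
        if status is not None and len(status) > 0:
            stage = "breeding-test"
            test, summary = breeding_comparison(scores, status)
            payload = {
                "seed": config.seed, "config_hash": config.config_hash(),
                "statistic": test.statistic_name, "value": test.statistic,
                "pvalue": test.pvalue, "method": test.method,
                "groups": summary.to_dict(orient="records"),
            }
            path = out / "breeding_test.json"
            _write_json(payload, path)
            written.append(path)
            results["breeding_test"] = (test, summary)
        else:
            skipped.append("breeding-test")

        # -------------------------------------------------- prediction curve
        stage = "prediction"
        sdc_table, sdc_scaling = build_predictor_table(scores, "sdc")
        best = fit_glm(sdc_table, "sdc", ("age", "age2", "date"), "gaussian")
        ages = np.arange(int(scores["age"].min()), int(scores["age"].max()) + 1)
        curve = predict_response(best.params, sdc_scaling, ages,
                                 fixed_date=config.fixed_date)
        path = out / "prediction_curve.csv"
        _write_csv(curve, path, tag)
        written.append(path)
        results["prediction_curve"] = curve

        # ------------------------------------------------------ pairing tests
        if pairs is not None and len(pairs) >= 2:
            stage = "pairing"
            rng = np.random.default_rng(config.seed + 1)
            rand_age = random_pairing_null(pairs, "age", n_sim=config.n_sim, rng=rng)
            pairs_sdc = predicted_sdc_for_pairs(pairs, best.params, sdc_scaling,
                                                fixed_date=config.fixed_date)
            rand_sdc = random_pairing_null(pairs_sdc, "sdc", n_sim=config.n_sim, rng=rng)
            for name, rand in (("age", rand_age), ("sdc", rand_sdc)):
                payload = {
                    "seed": config.seed, "config_hash": config.config_hash(),
                    "attribute": name, "observed_mean_abs_diff": rand.observed,
                    "ci": list(rand.ci), "verdict": rand.verdict,
                    "n_sim": rand.n_sim,
                }
                path = out / f"randomization_{name}.json"
                _write_json(payload, path)
                written.append(path)
                hist = pd.DataFrame({"null_mean_abs_diff": rand.null_draws})
                path = out / f"randomization_{name}_null.csv"
                _write_csv(hist, path, tag)
                written.append(path)
            results["randomization"] = {"age": rand_age, "sdc": rand_sdc}
        else:
            skipped.append("pairing")

        # ---------------------------------------------------------- run log
        stage = "run-log"
        _write_json(
            {
                "sdckit_version": __version__,
                "numpy": np.__version__, "pandas": pd.__version__,
                "seed": config.seed, "config_hash": config.config_hash(),
                "skipped_stages": skipped,
                "artifacts": [p.name for p in written],
            },
            out / "run_log.json",
        )
        results["skipped_stages"] = skipped
        return results
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
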