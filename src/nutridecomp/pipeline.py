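"""Weighted prevalence trends, phase differences and the end-to-end pipeline.

The trend stage tabulates weighted underweight prevalence (percent) by
subgroup for each survey and the percentage-point differences between
survey pairs ("phases", later minus earlier, so a decline is negative).
The pipeline chains: generate or read surveys -> trend table ->
survey-weighted logistic fits -> detailed decomposition -> CSV report
bundle with a JSON run log.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core_data import (
    ContractError,
    Schema,
    SurveyDataset,
    build_design,
    read_survey_csv,
    write_results,
)
from .decomposition import DecompositionResult, detailed_decompose
from .synthetic_data import (
    GeneratorConfig,
    config_from_dict,
    default_config,
    generate_all,
)
from .weighted_logit import fit as logit_fit

logger = logging.getLogger("nutridecomp")

__all__ = [
    "TrendTable",
    "PipelineError",
    "weighted_prevalence",
    "phase_differences",
    "build_trend_table",
    "run_pipeline",
]


class PipelineError(ContractError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# weighted prevalence

def weighted_prevalence(dataset: SurveyDataset,
                        stratifier: str | None = None):
    """Weighted underweight prevalence in percent.

    With no stratifier, returns a float (overall).  With a stratifier,
    returns ``{category: percent}`` over the stratifier's schema
    categories; a category with zero total weight is reported as NaN and
    logged.
    """
    f = dataset.frame
    w = np.asarray(f["weight"], dtype=float)
    y = np.asarray(f["underweight"], dtype=float)
    if stratifier is None:
        return 100.0 * dataset.weighted_prevalence()
    if stratifier not in dataset.schema.names:
        raise ContractError(f"stratifier {stratifier!r} not in schema")
    out: dict[str, float] = {}
    vals = f[stratifier].to_numpy()
    for cat in dataset.schema[stratifier].categories:
        m = vals == cat
        sw = w[m].sum()
        if sw <= 0:
            logger.warning("survey %s: empty stratum %s=%s",
                           dataset.survey, stratifier, cat)
            out[cat] = float("nan")
        else:
            out[cat] = float(100.0 * (w[m] * y[m]).sum() / sw)
    return out


# ---------------------------------------------------------------------------
# trend table

@dataclass
class TrendTable:
    """Prevalence-by-subgroup-and-survey rows plus phase differences.

    ``rows`` has columns ``variable``, ``category``, one prevalence column
    per survey label (percent) and one ``"later-earlier"`` column per
    phase pair (percentage points).  ``overall`` maps survey label to the
    overall weighted prevalence in percent.
    """

    rows: pd.DataFrame
    overall: dict[str, float]
    surveys: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    def to_frame(self) -> pd.DataFrame:
        head = {"variable": "Overall", "category": ""}
        head.update(self.overall)
        for earlier, later in self.pairs:
            head[f"{later}-{earlier}"] = self.overall[later] - self.overall[earlier]
        return pd.concat([pd.DataFrame([head]), self.rows], ignore_index=True)


def phase_differences(rows: pd.DataFrame,
                      pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Add percentage-point phase columns (later minus earlier) per row.

    ``pairs`` are (earlier, later) survey labels; both must be prevalence
    columns of ``rows``.  A decline shows as a negative difference.
    """
    out = rows.copy()
    for earlier, later in pairs:
        for s in (earlier, later):
            if s not in out.columns:
                raise ContractError(
                    f"survey {s!r} missing for phase pair ({earlier}, {later})"
                )
        out[f"{later}-{earlier}"] = out[later] - out[earlier]
    return out


def build_trend_table(datasets: Mapping[str, SurveyDataset],
                      stratifiers: Sequence[str],
                      pairs: Sequence[tuple[str, str]] | None = None) -> TrendTable:
    """Stratified weighted-prevalence trends across surveys."""
    surveys = tuple(datasets.keys())
    if pairs is None:
        pairs = [(surveys[i], surveys[j])
                 for i in range(len(surveys)) for j in range(i + 1, len(surveys))]
    schema = next(iter(datasets.values())).schema
    rows = []
    for var in stratifiers:
        for cat in schema[var].categories:
            rows.append({"variable": var, "category": cat})
    rows_df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["variable", "category"])
    for label, ds in datasets.items():
        col = []
        for var in stratifiers:
            strat = weighted_prevalence(ds, var)
            col.extend(strat[c] for c in ds.schema[var].categories)
        rows_df[label] = col if rows else []
    rows_df = phase_differences(rows_df, pairs)
    overall = {label: float(weighted_prevalence(ds))
               for label, ds in datasets.items()}
    return TrendTable(rows=rows_df, overall=overall,
                      surveys=surveys, pairs=tuple(tuple(p) for p in pairs))


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    trend: TrendTable
    decomposition: DecompositionResult
    datasets: dict[str, SurveyDataset]
    run_log: dict
    out_dir: Path | None


def _load_datasets(config: Mapping, seed: int | None) -> dict[str, SurveyDataset]:
    if "inputs" in config and config["inputs"]:
        schema = _schema_from_config(config)
        column_map = config.get("column_map") or {}
        out = {}
        for item in config["inputs"]:
            if isinstance(item, str):
                item = {"path": item}
            ds = read_survey_csv(item["path"], schema, column_map,
                                 survey=item.get("survey"))
            out[ds.survey] = ds
        return out
    gen = config.get("generator", "default")
    if gen in (None, "default"):
        gcfg = default_config(seed=0 if seed is None else seed)
    elif isinstance(gen, GeneratorConfig):
        gcfg = gen
    else:
        gen = dict(gen)
        if seed is not None:
            gen["seed"] = seed
        gcfg = config_from_dict(gen)
    return generate_all(gcfg)


def _schema_from_config(config: Mapping) -> Schema:
    from .core_data import Variable
    spec = config.get("schema")
    if spec is None:
        return default_config().schema
    return Schema(tuple(
        Variable(v["name"], tuple(v["categories"]), v.get("reference", ""))
        for v in spec
    ))


def run_pipeline(config: Mapping, out_dir=None, seed: int | None = None) -> ReportBundle:
    """Run generation/reading, trends, decomposition and reporting.

    ``config`` keys: ``generator`` (``"default"`` or a generator-config
    mapping) or ``inputs`` (list of CSV paths with optional survey
    labels) plus ``schema``/``column_map``; ``stratifiers``;
    ``decomposition`` with ``baseline``, ``comparison``, ``normalize``,
    ``covariance``.  Deterministic given (config, seed).  When
    ``out_dir`` is given, writes ``trend.csv``, ``decomposition.csv``,
    ``overall_trend.csv`` and ``run_log.json`` there.
    """
    config = dict(config)
    with _stage("load"):
        datasets = _load_datasets(config, seed)
        labels = list(datasets.keys())

    stratifiers = config.get("stratifiers")
    if stratifiers is None:
        schema = next(iter(datasets.values())).schema
        stratifiers = list(schema.names)

    dconf = dict(config.get("decomposition") or {})
    baseline = str(dconf.get("baseline", labels[0]))
    comparison = str(dconf.get("comparison", labels[-1]))
    for s in (baseline, comparison):
        if s not in datasets:
            raise PipelineError(f"stage 'decompose' failed: survey {s!r} not loaded")

    with _stage("trends"):
        trend = build_trend_table(datasets, stratifiers)

    with _stage("fit"):
        covariance = dconf.get("covariance", "sandwich")
        design_B = build_design(datasets[baseline])
        design_A = build_design(datasets[comparison])
        fit_B = logit_fit(design_B, covariance=covariance)
        fit_A = logit_fit(design_A, covariance=covariance)

    with _stage("decompose"):
        result = detailed_decompose(design_A, design_B, fit_A, fit_B,
                                    normalize=bool(dconf.get("normalize", True)))
        result.baseline_survey = baseline
        result.comparison_survey = comparison

    run_log = {
        "package_version": _pkg_version,
        "seed": seed,
        "surveys": {label: {"n_obs": len(ds), "n_dropped": ds.n_dropped,
                            "weighted_prevalence_pct": float(
                                weighted_prevalence(ds))}
                    for label, ds in datasets.items()},
        "fits": {
            baseline: {"converged": fit_B.converged,
                       "iterations": fit_B.iterations,
                       "loglik": fit_B.loglik},
            comparison: {"converged": fit_A.converged,
                         "iterations": fit_A.iterations,
                         "loglik": fit_A.loglik},
        },
        "decomposition": {
            "baseline": baseline, "comparison": comparison,
            "normalized": result.normalized,
            "total": result.total, "E": result.E, "C": result.C,
            "E_se": result.E_se, "C_se": result.C_se,
            "pct_E": result.pct_E, "pct_C": result.pct_C,
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        with _stage("report"):
            out_dir.mkdir(parents=True, exist_ok=True)
            write_results(trend.to_frame(), out_dir / "trend.csv")
            write_results(result.to_frame(), out_dir / "decomposition.csv")
            overall = pd.DataFrame(
                {"survey": labels,
                 "prevalence_pct": [trend.overall[s] for s in labels]})
            write_results(overall, out_dir / "overall_trend.csv")
            (out_dir / "run_log.json").write_text(
                json.dumps(run_log, indent=2, sort_keys=True))
            if config.get("plot"):
                _plot_overall(overall, out_dir / "overall_trend.png")

    return ReportBundle(trend=trend, decomposition=result,
                        datasets=datasets, run_log=run_log,
                        out_dir=Path(out_dir) if out_dir is not None else None)


def _plot_overall(overall: pd.DataFrame, path: Path) -> None:
    # cosmetic; the pipeline never depends on the figure
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        logger.warning("matplotlib unavailable; skipping plot")
        return
    figure, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(overall["survey"], overall["prevalence_pct"], marker="o")
    ax.set_ylabel("underweight prevalence (%)")
    ax.set_xlabel("survey")
    ax.set_ylim(bottom=0)
    figure.tight_layout()
    figure.savefig(path, dpi=120)
    plt.close(figure)
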