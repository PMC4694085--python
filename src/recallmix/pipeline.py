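"""End-to-end orchestration: simulate -> preprocess -> fit -> compare -> report.

A :class:`PipelineConfig` selects a built-in design (or a CSV trial table),
the models to fit, and sampler settings; :func:`run_pipeline` writes JSON
fits, filter reports, an information-criterion comparison when both mixture
variants are fit, and a plain-text summary table (condition medians with
50%/95% HDIs plus contrasts).  A single global seed fans out to fixed
per-stage seeds, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._engine import derive_seed
from .compare import compare
from .datasets import Dataset, GenParams, experiment_design, generate_experiment, read_dataset
from .glm import (AbsoluteErrorModel, LogRtModel, MultilevelLogistic,
                  VonMisesDispersionModel)
from .mixture import VonMisesUniformMixture
from .preprocess import (conditionalize_color_trials, filter_probe_rts,
                         filter_recognition_trials, independent_know_subset)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "summarize_fit",
           "format_summary_table"]

_KNOWN_MODELS = ("logistic", "rt", "abs_error", "vonmises",
                 "mixture_fixed", "mixture_variable")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    seed: int
    design: str | None = "e4"
    csv: str | None = None
    models: tuple = ("mixture_fixed", "mixture_variable")
    gen_params: dict = field(default_factory=dict)
    chains: int = 2
    draws: int = 1200
    warmup: int | None = None
    out_dir: str = "recallmix-out"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("field 'seed' is mandatory")
        unknown = [m for m in self.models if m not in _KNOWN_MODELS]
        if unknown:
            raise ConfigError(f"field 'models': unknown model(s) {unknown}; "
                              f"choose from {_KNOWN_MODELS}")
        if self.design is None and self.csv is None:
            raise ConfigError("one of 'design' or 'csv' is required")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = dict(d)
        if "models" in cfg:
            cfg["models"] = tuple(cfg["models"])
        return cls(**cfg)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def summarize_fit(fit, scale=None):
    """Tidy rows (quantity, median, hdi50, hdi95, scale) for any fitted model."""
    rows = []

    def add(summary):
        rows.append({"quantity": summary.name, "median": summary.median,
                     "hdi50": list(summary.hdi50), "hdi95": list(summary.hdi95),
                     "scale": summary.scale})

    if isinstance(fit, VonMisesUniformMixture):
        for c in ("R", "F"):
            add(fit.rho_[c])
            add(fit.sigma_[c])
        add(fit.rho_contrast("R", "F"))
        add(fit.sigma_contrast("F", "R"))
        if hasattr(fit, "vp_spread_"):
            add(fit.vp_spread_)
        return rows
    if isinstance(fit, LogRtModel):
        for cond, draws in fit._condition_link_draws.items():
            from .summaries import PosteriorSummary
            add(PosteriorSummary(f"logRT[{cond}]", draws, "log"))
        for cond, summ in fit.condition_means_.items():
            add(summ)
        conds = list(fit.condition_means_)
        if len(conds) == 2:
            add(fit.contrast(conds[1], conds[0]))
        return rows
    # logistic / absolute error / von Mises dispersion
    for summ in fit.condition_means_.values():
        add(summ)
    conds = list(fit.condition_means_)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            add(fit.contrast(conds[j], conds[i]))
    return rows


def format_summary_table(rows, title="") -> str:
    lines = [title, "-" * max(len(title), 1)] if title else []
    lines.append(f"{'quantity':<28}{'median':>10}  {'50% HDI':>20}  {'95% HDI':>22}  scale")
    for r in rows:
        h50 = "[{: .3f}, {: .3f}]".format(*r["hdi50"])
        h95 = "[{: .3f}, {: .3f}]".format(*r["hdi95"])
        lines.append(f"{r['quantity']:<28}{r['median']:>10.3f}  {h50:>20}  {h95:>22}  {r['scale']}")
    return "\n".join(lines)


def _load_data(config: PipelineConfig) -> Dataset:
    if config.csv:
        return read_dataset(config.csv)
    design = experiment_design(config.design)
    params = GenParams(**config.gen_params)
    return generate_experiment(design, params,
                               seed=derive_seed(config.seed, "simulate"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analyses; returns the report bundle as a dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    bundle = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in asdict(config).items()},
              "filters": {}, "fits": {}, "comparison": {}}

    ds = _load_data(config)
    design = ds.design
    logger.info("stage=data design=%s records=%d (%.1fs)",
                design.name, len(ds.records), time.time() - t_start)

    records = ds.records
    has_recog = design.response_protocol in ("old_new", "remember_know_no")
    recog_records = None
    if has_recog:
        rep = filter_recognition_trials(records[records.phase == "test"])
        bundle["filters"]["recognition"] = rep.to_dict()
        recog_records = rep.retained

    sampler_kw = dict(n_steps=config.draws, n_ensembles=config.chains)
    mix_common = None
    fits = {}
    for model in config.models:
        t0 = time.time()
        seed = derive_seed(config.seed, f"fit-{model}")
        if model == "logistic":
            if not has_recog:
                raise ConfigError("model 'logistic' needs a recognition protocol")
            if design.response_protocol == "old_new":
                fit = MultilevelLogistic(positive=("old",), seed=seed,
                                         **sampler_kw).fit(recog_records)
            else:
                fit = MultilevelLogistic(positive=("remember",), seed=seed,
                                         **sampler_kw).fit(recog_records)
                know = MultilevelLogistic(positive=("know",), seed=seed + 1,
                                          **sampler_kw).fit(
                    independent_know_subset(recog_records))
                fits["logistic_know"] = know
        elif model == "rt":
            rep = filter_probe_rts(records)
            bundle["filters"]["probe_rt"] = rep.to_dict()
            fit = LogRtModel(with_task=design.has_baseline_blocks, seed=seed,
                             **sampler_kw).fit(rep.retained)
        elif model in ("abs_error", "vonmises"):
            base = recog_records if has_recog else records
            if design.response_protocol == "old_new":
                color = conditionalize_color_trials(base, on={"old"})
            elif design.response_protocol == "remember_know_no":
                color = conditionalize_color_trials(base, on={"remember"})
            else:
                color = conditionalize_color_trials(base, on=())
            cls = AbsoluteErrorModel if model == "abs_error" else VonMisesDispersionModel
            fit = cls(seed=seed, **sampler_kw).fit(color)
        elif model.startswith("mixture"):
            if mix_common is None:
                base = recog_records if has_recog else records
                mix_common = conditionalize_color_trials(base, on=())
            variant = model.split("_")[1]
            fit = VonMisesUniformMixture(
                variant=variant, seed=derive_seed(config.seed, "fit-mixture"),
                **sampler_kw).fit(mix_common)
        fits[model] = fit
        logger.info("stage=fit model=%s (%.1fs)", model, time.time() - t0)

    for name, fit in fits.items():
        rows = summarize_fit(fit)
        bundle["fits"][name] = {
            "summary": rows,
            "diagnostics": {k: (v if not isinstance(v, dict)
                                else {p: float(x) for p, x in v.items()})
                            for k, v in fit.diagnostics_.items()},
        }
        with open(out_dir / f"fit_{name}.json", "w") as fh:
            json.dump(bundle["fits"][name], fh, indent=1, default=float)

    if "mixture_fixed" in fits and "mixture_variable" in fits:
        pw_fp = fits["mixture_fixed"].pointwise_loglik_
        pw_vp = fits["mixture_variable"].pointwise_loglik_
        for method in ("waic", "psis_loo"):
            res = compare(pw_fp, pw_vp, method=method)  # delta = FP - VP (elpd)
            bundle["comparison"][method] = res.to_dict()
        with open(out_dir / "comparison.json", "w") as fh:
            json.dump(bundle["comparison"], fh, indent=1)

    with open(out_dir / "filters.json", "w") as fh:
        json.dump(bundle["filters"], fh, indent=1)
    text = []
    for name, fit in fits.items():
        text.append(format_summary_table(bundle["fits"][name]["summary"],
                                         title=f"model: {name}"))
        text.append("")
    if bundle["comparison"]:
        text.append("model comparison (delta = fixed - variable, elpd scale):")
        for method, res in bundle["comparison"].items():
            text.append(f"  {method}: delta={res['delta']:.2f} "
                        f"(SE {res['se_delta']:.2f})")
    (out_dir / "summary.txt").write_text("\n".join(text))
    logger.info("stage=done total=%.1fs out=%s", time.time() - t_start, out_dir)
    return bundle
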