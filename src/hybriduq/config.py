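"""Run configuration: schema, (de)serialization, and the artifact-bundle runner.

A run config names a model (the built-in arsenic case study or an inline
model declared as parameters plus an arithmetic expression), the engine
settings (Monte Carlo size, seed, α-steps) and the summary settings
(fractiles, range percentiles, quantile mode). ``run()`` executes the full
propagation and writes a reproducible artifact bundle:

    family.csv            long-format CDF family (pass, alpha, curve, index, value)
    pbox_umf.csv/.json    bounding curves + interval summaries, UMF pass
    pbox_lmf.csv/.json    same for the LMF pass
    fractile_p<..>.json   fractile membership functions
    manifest.json         seed, settings, package version (timestamp lives here only)

Identical config + seed ⇒ byte-identical CSV/JSON payloads (floats are
serialized at 9 significant digits); only the manifest carries a timestamp.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .case_study import arsenic_risk_model
from .engine import CDFFamily, MembershipPass, ModelSpec, propagate
from .fuzzy import GeneralizedFuzzyNumber, IntervalValuedFuzzyNumber
from .sampling import DistributionSpec
from .summaries import fractile_mf, pbox, pbox_mean, pbox_range, pbox_variance

__all__ = ["RunConfig", "EngineSettings", "SummarySettings", "InlineModel",
           "load_config", "save_config", "build_model", "run"]

BUILTIN_MODELS = {"arsenic_case_study": arsenic_risk_model}

FLOAT_FORMAT = "%.9g"


class EngineSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_mc: int = Field(default=5000, ge=1)
    seed: int  # required: every run is reproducible by construction
    alpha_steps: int = Field(default=10, ge=1)
    refine_nonmonotone: bool = False
    refine_points: int = Field(default=16, ge=3)


class SummarySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fractiles: list[float] = Field(default_factory=lambda: [0.95, 0.85])
    range_percentiles: tuple[float, float] = (0.005, 0.995)
    quantile_mode: Literal["empirical", "analytic"] = "empirical"
    variance_ddof: int = Field(default=0, ge=0)

    @field_validator("fractiles")
    @classmethod
    def _fractiles_in_open_unit(cls, v: list[float]) -> list[float]:
        bad = [p for p in v if not 0.0 < p < 1.0]
        if bad:
            raise ValueError(f"fractiles must lie in (0, 1), got {bad}")
        return v

    @field_validator("range_percentiles")
    @classmethod
    def _percentiles_ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not 0.0 < lo < hi < 1.0:
            raise ValueError(f"range_percentiles must satisfy 0 < low < high < 1, got {v}")
        return v


class InlineModel(BaseModel):
    """A model declared in the config: named parameters + an expression.

    Parameter entries are dispatched on their keys:
      {"dist": "normal", "mean": .., "sd": ..} | {"dist": "constant", "value": ..}
      {"type": "tri"|"trap", "knots": [...], "height": w}
      {"umf": {...}, "lmf": {...}}
      {"value": x}   (bare constant)
    The expression is plain arithmetic over the parameter names plus numpy
    elementwise functions (exp, log, sqrt, ...).
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "custom"
    expression: str
    parameters: dict[str, dict]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: Union[str, InlineModel] = "arsenic_case_study"
    engine: EngineSettings
    summaries: SummarySettings = Field(default_factory=SummarySettings)
    out_dir: str = "hybriduq_out"

    @field_validator("model")
    @classmethod
    def _model_known(cls, v):
        if isinstance(v, str) and v not in BUILTIN_MODELS:
            raise ValueError(
                f"unknown built-in model {v!r}; available: {sorted(BUILTIN_MODELS)}"
            )
        return v


# numpy elementwise functions permitted in inline-model expressions
def _expression_namespace():
    import numpy as np

    return {
        "exp": np.exp, "log": np.log, "log10": np.log10, "sqrt": np.sqrt,
        "abs": np.abs, "minimum": np.minimum, "maximum": np.maximum,
        "where": np.where, "pi": np.pi, "e": np.e,
    }


def _parse_parameter(name: str, entry: dict):
    keys = set(entry)
    if "dist" in keys:
        return "probabilistic", DistributionSpec.from_dict(entry)
    if {"umf", "lmf"} <= keys:
        return "interval_fuzzy", IntervalValuedFuzzyNumber.from_dict(entry)
    if "knots" in keys:
        return "fuzzy", GeneralizedFuzzyNumber.from_dict(entry)
    if keys == {"value"}:
        return "constant", float(entry["value"])
    raise ValueError(
        f"parameter {name!r}: cannot classify entry with keys {sorted(keys)}; expected "
        "a distribution ('dist'), fuzzy number ('type'/'knots'), IVFN ('umf'+'lmf') "
        "or constant ('value')"
    )


def build_model(model: Union[str, InlineModel]) -> ModelSpec:
    """Resolve a config model reference into an engine :class:`ModelSpec`."""
    if isinstance(model, str):
        return BUILTIN_MODELS[model]()
    groups: dict[str, dict] = {
        "constant": {}, "probabilistic": {}, "fuzzy": {}, "interval_fuzzy": {}
    }
    for name, entry in model.parameters.items():
        kind, value = _parse_parameter(name, entry)
        groups[kind][name] = value
    code = compile(model.expression, f"<model {model.name}>", "eval")
    namespace = _expression_namespace()

    def evaluator(assignment):
        return eval(code, {"__builtins__": {}}, {**namespace, **assignment})

    return ModelSpec(
        name=model.name,
        evaluator=evaluator,
        constants=groups["constant"],
        probabilistic=groups["probabilistic"],
        fuzzy=groups["fuzzy"],
        interval_fuzzy=groups["interval_fuzzy"],
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run config; errors list every violation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def _round9(x: float) -> float:
    return float(FLOAT_FORMAT % x)


def _summary_dict(pb, settings: SummarySettings) -> dict:
    p_low, p_high = settings.range_percentiles
    rng = pbox_range(pb, p_low, p_high, mode=settings.quantile_mode)
    mean = pbox_mean(pb)
    var = pbox_variance(pb, ddof=settings.variance_ddof)
    return {
        "pass": pb.pass_.value,
        "range": [_round9(rng.lo), _round9(rng.hi)],
        "range_percentiles": list(settings.range_percentiles),
        "mean": [_round9(mean.lo), _round9(mean.hi)],
        "variance": [_round9(var.lo), _round9(var.hi)],
        "variance_ddof": settings.variance_ddof,
        "quantile_mode": settings.quantile_mode,
    }


def _json_round(obj):
    if isinstance(obj, float):
        return _round9(obj)
    if isinstance(obj, dict):
        return {k: _json_round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_round(v) for v in obj]
    return obj


def run(config: RunConfig) -> dict[str, Path]:
    """Execute a config end to end and write the artifact bundle.

    Returns the mapping of artifact names to written paths.
    """
    model = build_model(config.model)
    family: CDFFamily = propagate(
        model,
        n_mc=config.engine.n_mc,
        seed=config.engine.seed,
        alpha_steps=config.engine.alpha_steps,
        refine_nonmonotone=config.engine.refine_nonmonotone,
        refine_points=config.engine.refine_points,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    family_path = out / "family.csv"
    family.to_frame().to_csv(family_path, index=False, float_format=FLOAT_FORMAT)
    paths["family"] = family_path

    for pass_ in (MembershipPass.UMF, MembershipPass.LMF):
        pb = pbox(family, pass_)
        tag = pass_.value.lower()
        csv_path = out / f"pbox_{tag}.csv"
        pb.to_frame().to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
        json_path = out / f"pbox_{tag}.json"
        json_path.write_text(json.dumps(_summary_dict(pb, config.summaries), indent=2) + "\n")
        paths[f"pbox_{tag}_csv"] = csv_path
        paths[f"pbox_{tag}_json"] = json_path

    for p in config.summaries.fractiles:
        mf = fractile_mf(family, p, mode=config.summaries.quantile_mode)
        mf_path = out / f"fractile_p{100 * p:g}.json"
        mf_path.write_text(json.dumps(_json_round(mf.to_dict()), indent=2) + "\n")
        paths[f"fractile_{p:g}"] = mf_path

    manifest = {
        "package": "hybriduq",
        "version": __version__,
        "model": model.name,
        "seed": config.engine.seed,
        "n_mc": config.engine.n_mc,
        "alpha_levels": [_round9(a) for a in family.grid.levels],
        "settings": config.model_dump(mode="json"),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = manifest_path
    return paths


def case_study_config(
    seed: int = 20170131,
    n_mc: int = 5000,
    fractiles: list[float] | None = None,
    quantile_mode: str = "empirical",
    out_dir: str = "hybriduq_out",
) -> RunConfig:
    """The packaged arsenic case-study configuration."""
    return RunConfig(
        model="arsenic_case_study",
        engine=EngineSettings(seed=seed, n_mc=n_mc),
        summaries=SummarySettings(
            fractiles=fractiles if fractiles is not None else [0.95, 0.85],
            quantile_mode=quantile_mode,
        ),
        out_dir=out_dir,
    )
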