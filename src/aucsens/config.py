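"""Structured configuration documents (YAML or JSON) for an analysis run.

Schema (top-level keys; unknown keys are rejected with the field path)::

    model: linear_chain            # registered model name (required)
    horizon: 10.0                  # simulation end time T (required)
    params: {k: 2.0}               # optional nominal-value overrides
    output_variable: x             # optional override of the model output
    exclude: [hill_K]              # optional extra non-ranked parameters
    n_points: 1000                 # output grid size
    rtol: 1.0e-6
    atol: 1.0e-9
    stiff_solver: true
    distribution:                  # alteration-factor law
      kind: lognormal              # lognormal | degenerate
      log_location: -2.08
      log_scale: 0.61
      point_value: 1.0             # degenerate only
    n_samples: 1000                # alpha draws per parameter
    seed: 0
    neutral_band: 0.01
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .demo_models import MODEL_REGISTRY, get_model
from .errors import ConfigurationError, ValidationError
from .ode_core import OdeModel, SimulationConfig
from .randomized import DEFAULT_NEUTRAL_BAND, AlterationDistribution

__all__ = ["AnalysisSettings", "load_model_config"]

_TOP_KEYS = {
    "model", "horizon", "params", "output_variable", "exclude", "n_points",
    "rtol", "atol", "stiff_solver", "distribution", "n_samples", "seed",
    "neutral_band",
}
_DIST_KEYS = {"kind", "log_location", "log_scale", "point_value"}


@dataclass(frozen=True)
class AnalysisSettings:
    """Analysis-level settings attached to a loaded configuration."""

    distribution: AlterationDistribution
    n_samples: int = 1000
    seed: int = 0
    neutral_band: float = DEFAULT_NEUTRAL_BAND


def _read_document(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"{path}: unparsable document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return doc


def _parse_distribution(spec) -> AlterationDistribution:
    if spec is None:
        return AlterationDistribution()
    if not isinstance(spec, dict):
        raise ConfigurationError("distribution: must be a mapping")
    unknown = set(spec) - _DIST_KEYS
    if unknown:
        raise ConfigurationError(f"distribution: unknown keys {sorted(unknown)}")
    kind = spec.get("kind", "lognormal")
    try:
        if kind == "lognormal":
            return AlterationDistribution(
                kind="lognormal",
                log_location=float(spec.get("log_location", -2.08)),
                log_scale=float(spec.get("log_scale", 0.61)),
            )
        if kind == "degenerate":
            if "point_value" not in spec:
                raise ConfigurationError("distribution.point_value: required for degenerate kind")
            return AlterationDistribution(kind="degenerate", point_value=float(spec["point_value"]))
    except ValidationError as exc:
        raise ConfigurationError(f"distribution: {exc}") from exc
    raise ConfigurationError(f"distribution.kind: unknown kind {kind!r}")


def load_model_config(
    path: str | Path,
) -> tuple[OdeModel, SimulationConfig, AnalysisSettings]:
    """Load and validate a model + analysis configuration document.

    The model must name one of the registered demonstration models;
    ``params`` overrides nominal values, ``exclude`` adds parameters to the
    non-ranked set, and ``output_variable`` re-targets the analysis at a
    different state.  Every field is validated; unknown keys are an error.
    """
    doc = _read_document(path)
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    if "model" not in doc:
        raise ConfigurationError("model: required field is missing")
    name = doc["model"]
    if name not in MODEL_REGISTRY:
        raise ConfigurationError(
            f"model: unknown model {name!r}; registered models: {sorted(MODEL_REGISTRY)}"
        )
    model = get_model(name)

    overrides = doc.get("params") or {}
    if not isinstance(overrides, dict):
        raise ConfigurationError("params: must be a mapping of parameter -> value")
    bad = set(overrides) - set(model.param_names)
    if bad:
        raise ConfigurationError(f"params: unknown parameters {sorted(bad)}")
    nominal = dict(model.nominal_params)
    for k, v in overrides.items():
        nominal[k] = float(v)

    output = doc.get("output_variable", model.output_variable)
    if output not in model.state_names:
        raise ConfigurationError(
            f"output_variable: {output!r} is not a state of model {name!r}"
        )
    exclude = doc.get("exclude") or []
    if not isinstance(exclude, list):
        raise ConfigurationError("exclude: must be a list of parameter names")
    bad = set(exclude) - set(model.param_names)
    if bad:
        raise ConfigurationError(f"exclude: unknown parameters {sorted(bad)}")

    model = replace(
        model,
        nominal_params=nominal,
        output_variable=output,
        non_ranked_params=model.non_ranked_params | frozenset(exclude),
    )

    if "horizon" not in doc:
        raise ConfigurationError("horizon: required field is missing")
    try:
        sim = SimulationConfig(
            horizon_T=float(doc["horizon"]),
            n_points=int(doc.get("n_points", 1000)),
            rtol=float(doc.get("rtol", 1e-6)),
            atol=float(doc.get("atol", 1e-9)),
            stiff_solver=bool(doc.get("stiff_solver", True)),
        )
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc

    n_samples = int(doc.get("n_samples", 1000))
    if n_samples < 1:
        raise ConfigurationError(f"n_samples: must be >= 1, got {n_samples}")
    neutral_band = float(doc.get("neutral_band", DEFAULT_NEUTRAL_BAND))
    if neutral_band < 0:
        raise ConfigurationError(f"neutral_band: must be >= 0, got {neutral_band}")
    settings = AnalysisSettings(
        distribution=_parse_distribution(doc.get("distribution")),
        n_samples=n_samples,
        seed=int(doc.get("seed", 0)),
        neutral_band=neutral_band,
    )
    return model, sim, settings
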