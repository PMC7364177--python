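"""Run configuration: a single structured text file drives the whole run.

The configuration is YAML with a fixed schema.  Loading merges the user's
file over the defaults (every materialised default — c=1, k=11, 500 trees,
variance threshold 0.95, epsilon p=0.1 — appears explicitly in the resolved
config), rejects unknown keys outright, and validation reports *every*
problem found, not just the first.  ``save_config(load_config(p))`` is
lossless, so a finished analysis can be replayed or varied one parameter at
a time.
"""

from __future__ import annotations

import copy
import glob as globmod
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import preprocess as pp
from .crossval import LassoStep, PCAStep, Pipeline, SelectStep, ZScoreStep
from .data_io import DataError
from .models import make_model

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "default_config", "build_pipeline"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; lists every problem."""


_DEFAULTS: dict = {
    "task": "classify",           # "classify" | "regress"
    "seed": 0,
    "input": {
        "samples": None,          # list of NIfTI paths, or a glob pattern
        "samples_table": None,    # delimited matrix alternative
        "mask": None,
        "labels": None,           # labels column (classify) / scores (regress)
        "folds": None,            # fold-column file; or use k below
        "k": None,                # number of random (stratified) folds
    },
    "preprocessing": [],          # ordered steps, see build_pipeline
    "model": {
        "algorithm": "svm",
        "params": None,           # validated/materialised by make_model
    },
    "mode": {
        "type": "roi",            # "roi" | "searchlight"
        "radius": 4.0,
        "units": "voxel",         # "voxel" | "mm"
        "cluster_min_voxels": 0,  # reporting threshold, in voxels
    },
    "statistics": {
        "permutations": 0,
        "fwe": False,
    },
    "outputs": {
        "directory": "results",
        "weight_maps": True,
        "per_fold": True,
        "roc": True,
        "predictions": True,
    },
    "fusion": None,               # {strategy, blocks: [...]} or None
}

_FUSION_BLOCK_DEFAULTS = {
    "name": None,
    "samples": None,
    "samples_table": None,
    "mask": None,
    "normalize": "none",
}

_STEP_DEFAULTS = {
    "zscore": {"step": "zscore", "direction": "columns"},
    "pca": {"step": "pca", "variance_threshold": 0.95, "n_components": None},
    "select": {"step": "select", "method": "fscore", "amount": 1.0},
    "lasso": {"step": "lasso", "inner_folds": 10, "n_lambdas": 100,
              "grid_eps": 1.0e-4, "lam": None},
}


def _merge(defaults, user, path: str, errors: list):
    """Deep-merge user over defaults; unknown keys are collected as errors."""
    if user is None:
        return copy.deepcopy(defaults)
    if isinstance(defaults, dict) and isinstance(user, dict):
        out = {}
        for key, dval in defaults.items():
            if key in user:
                out[key] = _merge(dval, user[key],
                                  f"{path}.{key}" if path else key, errors)
            else:
                out[key] = copy.deepcopy(dval)
        for key in user:
            if key not in defaults:
                errors.append(f"unknown key {path + '.' if path else ''}{key}")
        return out
    return copy.deepcopy(user)


def _resolve_steps(steps, errors: list) -> list:
    resolved = []
    for i, step in enumerate(steps or []):
        if not isinstance(step, dict) or "step" not in step:
            errors.append(f"preprocessing[{i}]: each step needs a 'step' key")
            continue
        kind = step["step"]
        if kind not in _STEP_DEFAULTS:
            errors.append(
                f"preprocessing[{i}]: unknown step {kind!r}; valid: "
                f"{sorted(_STEP_DEFAULTS)}"
            )
            continue
        sub_errors: list = []
        resolved.append(_merge(_STEP_DEFAULTS[kind], step,
                               f"preprocessing[{i}]", sub_errors))
        errors.extend(sub_errors)
    return resolved


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration (all defaults materialised)."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.data == other.data


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def resolve(user: dict) -> RunConfig:
    """Merge a raw dict over the defaults; raise on unknown keys."""
    errors: list = []
    merged = _merge(_DEFAULTS, user, "", errors)
    merged["preprocessing"] = _resolve_steps(merged.get("preprocessing"),
                                             errors)
    if merged.get("fusion"):
        fusion = merged["fusion"]
        f_errors: list = []
        fusion = _merge({"strategy": "concatenate", "blocks": []}, fusion,
                        "fusion", f_errors)
        fusion["blocks"] = [
            _merge(_FUSION_BLOCK_DEFAULTS, b, f"fusion.blocks[{i}]", f_errors)
            for i, b in enumerate(fusion["blocks"] or [])
        ]
        merged["fusion"] = fusion
        errors.extend(f_errors)
    # materialise model defaults so the resolved config is explicit
    if not errors:
        try:
            spec = make_model(merged["model"]["algorithm"], merged["task"],
                              merged["model"]["params"] or {})
            merged["model"]["params"] = dict(spec.params)
        except DataError as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError("invalid configuration:\n  - " +
                          "\n  - ".join(errors))
    return RunConfig(merged)


def validate(config: RunConfig) -> list[str]:
    """Collect every validation problem; an empty list means runnable."""
    c = config.data
    errors: list[str] = []
    fusion = c.get("fusion")
    if fusion:
        if fusion.get("strategy") not in ("concatenate", "vote"):
            errors.append("fusion.strategy must be 'concatenate' or 'vote'")
        if len(fusion.get("blocks") or []) < 1:
            errors.append("fusion.blocks must list at least one block")
        for i, b in enumerate(fusion.get("blocks") or []):
            if not b.get("samples") and not b.get("samples_table"):
                errors.append(f"fusion.blocks[{i}]: samples or samples_table "
                              "is required")
    else:
        if not c["input"]["samples"] and not c["input"]["samples_table"]:
            errors.append("input.samples or input.samples_table is required")
    if not c["input"]["labels"]:
        errors.append("input.labels is required")
    if not c["input"]["folds"] and not c["input"]["k"]:
        errors.append("input.folds (file) or input.k (fold count) is required")
    if c["task"] not in ("classify", "regress"):
        errors.append(f"task must be 'classify' or 'regress', got {c['task']!r}")
    if c["mode"]["type"] not in ("roi", "searchlight"):
        errors.append("mode.type must be 'roi' or 'searchlight'")
    if c["mode"]["type"] == "searchlight" and c["mode"]["radius"] < 0:
        errors.append("mode.radius must be non-negative")
    if c["statistics"]["permutations"] < 0:
        errors.append("statistics.permutations must be >= 0")
    return errors


def load_config(path: str | Path) -> RunConfig:
    """Load, merge over defaults and reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return resolve(raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Write the fully resolved configuration; load(save(c)) == c."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.data, sort_keys=False))
    return path


# --------------------------------------------------------------------------
# pipeline construction
# --------------------------------------------------------------------------

def _step_from_dict(entry: dict, seed: int):
    kind = entry["step"]
    if kind == "zscore":
        return ZScoreStep(direction=entry["direction"])
    if kind == "pca":
        return PCAStep(variance_threshold=entry["variance_threshold"],
                       n_components=entry["n_components"])
    if kind == "select":
        return SelectStep(amount=entry["amount"], method=entry["method"])
    if kind == "lasso":
        return LassoStep(pp.LassoConfig(lam=entry["lam"],
                                        inner_folds=entry["inner_folds"],
                                        n_lambdas=entry["n_lambdas"],
                                        grid_eps=entry["grid_eps"],
                                        seed=seed))
    raise ConfigError(f"unknown preprocessing step {kind!r}")


def build_pipeline(config: RunConfig, amount_override=None) -> Pipeline:
    """Materialise the Pipeline described by a resolved config.

    ``amount_override`` substitutes the selection amount when a config
    lists several amounts and the run fans out into independent analyses.
    """
    c = config.data
    steps = []
    for entry in c["preprocessing"]:
        entry = dict(entry)
        if entry["step"] == "select" and amount_override is not None:
            entry["amount"] = amount_override
        steps.append(_step_from_dict(entry, c["seed"]))
    spec = make_model(c["model"]["algorithm"], c["task"],
                      c["model"]["params"])
    return Pipeline(model=spec, steps=tuple(steps))


def selection_amounts(config: RunConfig) -> list | None:
    """The list of selection amounts when the config fans out, else None."""
    for entry in config.data["preprocessing"]:
        if entry["step"] == "select" and isinstance(entry["amount"], list):
            return list(entry["amount"])
    return None


def expand_samples(samples) -> list[str]:
    """A list of paths stays ordered; a glob pattern sorts alphabetically."""
    if isinstance(samples, str):
        return sorted(globmod.glob(samples))
    return [str(s) for s in samples]
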