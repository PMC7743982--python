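"""YAML model-definition files: load, validate, save, round-trip safe.

The schema mirrors the in-memory types: top-level keys ``variables``,
``thresholds``, ``switches``, ``equations``.  Floats survive a round trip
bit-for-bit (they are emitted with full ``repr`` precision).  Schema errors
report the offending key path and, where YAML node marks are available, the
line in the file.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from .model import (
    PLDEModel,
    RateTerm,
    SwitchedCoefficient,
    SwitchingVariable,
    ThresholdSpec,
    VariableSpec,
)

__all__ = ["ConfigError", "model_to_dict", "model_from_dict", "save_model",
           "load_model", "model_hash"]


class ConfigError(ValueError):
    """A model config file failed schema validation."""


class _LineLoader(yaml.SafeLoader):
    """SafeLoader that records the source line of every mapping."""


def _construct_mapping(loader, node, deep=False):
    mapping = yaml.SafeLoader.construct_mapping(loader, node, deep=deep)
    mapping["__line__"] = node.start_mark.line + 1
    return mapping


_LineLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


def _strip_lines(obj):
    if isinstance(obj, dict):
        return {k: _strip_lines(v) for k, v in obj.items() if k != "__line__"}
    if isinstance(obj, list):
        return [_strip_lines(v) for v in obj]
    return obj


def _line(obj) -> str:
    if isinstance(obj, dict) and "__line__" in obj:
        return f" (line {obj['__line__']})"
    return ""


def _need(d: dict, key: str, path: str):
    if not isinstance(d, dict) or key not in d:
        raise ConfigError(f"missing key {path}.{key}{_line(d)}")
    return d[key]


def _number(value, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{path} must be a number, got {value!r}")
    return float(value)


def model_from_dict(data: dict, source: str = "<dict>") -> PLDEModel:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    variables = []
    for i, v in enumerate(_need(data, "variables", source)):
        path = f"{source}.variables[{i}]"
        variables.append(
            VariableSpec(
                str(_need(v, "name", path)),
                _number(_need(v, "initial", path), path + ".initial"),
                str(v.get("description", "")),
            )
        )
    thresholds = []
    for i, t in enumerate(_need(data, "thresholds", source)):
        path = f"{source}.thresholds[{i}]"
        thresholds.append(
            ThresholdSpec(
                str(_need(t, "name", path)),
                str(_need(t, "variable", path)),
                _number(_need(t, "value", path), path + ".value"),
            )
        )
    switches = []
    for i, s in enumerate(_need(data, "switches", source)):
        path = f"{source}.switches[{i}]"
        switches.append(
            SwitchingVariable(
                str(_need(s, "name", path)), str(_need(s, "threshold", path))
            )
        )
    equations = {}
    eqs = _need(data, "equations", source)
    if not isinstance(eqs, dict):
        raise ConfigError(f"{source}.equations must be a mapping{_line(eqs)}")
    for var, terms in eqs.items():
        if var == "__line__":
            continue
        term_list = []
        for i, term in enumerate(terms):
            path = f"{source}.equations.{var}[{i}]"
            deltas = []
            for j, pair in enumerate(term.get("deltas", [])):
                if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                    raise ConfigError(
                        f"{path}.deltas[{j}] must be a [switch, increment] pair"
                        f"{_line(term)}"
                    )
                deltas.append(
                    (str(pair[0]), _number(pair[1], f"{path}.deltas[{j}][1]"))
                )
            kind = str(_need(term, "kind", path))
            source_var = term.get("source")
            term_list.append(
                RateTerm(
                    name=str(_need(term, "name", path)),
                    kind=kind,
                    coefficient=SwitchedCoefficient(
                        _number(_need(term, "base", path), path + ".base"),
                        tuple(deltas),
                    ),
                    source=str(source_var) if source_var is not None else None,
                    stress_scaled=bool(term.get("stress_scaled", False)),
                )
            )
        equations[var] = term_list
    model = PLDEModel(
        variables=variables,
        thresholds=thresholds,
        switches=switches,
        equations=equations,
        name=str(data.get("name", "model")),
    )
    try:
        model.validate()
    except Exception as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    return model


def model_to_dict(model: PLDEModel) -> dict:
    return {
        "name": model.name,
        "variables": [
            {"name": v.name, "initial": v.initial, "description": v.description}
            for v in model.variables
        ],
        "thresholds": [
            {"name": t.name, "variable": t.variable, "value": t.value}
            for t in model.thresholds
        ],
        "switches": [
            {"name": s.name, "threshold": s.threshold} for s in model.switches
        ],
        "equations": {
            var: [
                {
                    "name": term.name,
                    "kind": term.kind,
                    "base": term.coefficient.base,
                    **(
                        {"deltas": [[n, inc] for n, inc in term.coefficient.deltas]}
                        if term.coefficient.deltas
                        else {}
                    ),
                    **({"source": term.source} if term.source else {}),
                    **({"stress_scaled": True} if term.stress_scaled else {}),
                }
                for term in terms
            ]
            for var, terms in model.equations.items()
        },
    }


class _FullPrecisionDumper(yaml.SafeDumper):
    pass


_FullPrecisionDumper.add_representer(
    float,
    lambda dumper, value: dumper.represent_scalar(
        "tag:yaml.org,2002:float", repr(value)
    ),
)


def save_model(model: PLDEModel, path) -> None:
    Path(path).write_text(
        yaml.dump(
            model_to_dict(model),
            Dumper=_FullPrecisionDumper,
            sort_keys=False,
            default_flow_style=None,
        )
    )


def load_model(path) -> PLDEModel:
    text = Path(path).read_text()
    try:
        data = yaml.load(text, Loader=_LineLoader)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return model_from_dict(_line_aware(data), source=str(path))


def _line_aware(data):
    # keep the __line__ markers for error messages; they are stripped before
    # reaching the model constructor via dict access patterns above
    return data


def model_hash(model: PLDEModel) -> str:
    """Stable content hash of a model definition (for run provenance logs)."""
    canon = yaml.dump(model_to_dict(model), Dumper=_FullPrecisionDumper, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
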