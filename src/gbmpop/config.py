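"""Flat key-value configuration files for parameter sets and numerics.

The on-disk format is plain text, one ``key = value`` per line, ``#``
comments allowed, ``none`` for unset optional values.  All quantities carry
the package's standard units (mm, years, cells/mm^3, cells/mm^2).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Dict, Optional, Union

from .model import ModelParams
from .solver import Mesh, SolverConfig

__all__ = [
    "load_config",
    "dump_config",
    "params_from_dict",
    "params_to_dict",
    "mesh_from_dict",
    "solver_from_dict",
]

Value = Optional[Union[float, int, str]]


def _parse(text: str) -> Value:
    text = text.strip()
    if text.lower() in {"none", "null", ""}:
        return None
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def load_config(path) -> Dict[str, Value]:
    out: Dict[str, Value] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = _parse(value)
    return out


def dump_config(values: Dict[str, Value], path) -> None:
    lines = [
        f"{k} = {'none' if v is None else v}" for k, v in values.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def params_to_dict(params: ModelParams) -> Dict[str, Value]:
    return {f.name: getattr(params, f.name) for f in fields(ModelParams)}


def _from_dict(cls, values: Dict[str, Value]):
    names = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in values.items() if k in names}
    return cls(**kwargs)


def params_from_dict(values: Dict[str, Value]) -> ModelParams:
    return _from_dict(ModelParams, values)


def mesh_from_dict(values: Dict[str, Value]) -> Mesh:
    return _from_dict(Mesh, values)


def solver_from_dict(values: Dict[str, Value]) -> SolverConfig:
    return _from_dict(SolverConfig, values)
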