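"""Plain-text serialization: configs, particle tables, manifests.

Everything is written as either tab-separated tables (one header row, floats
at 6 significant digits) or flat ``key: value`` text.  Config round trips are
bit-exact: floats serialize via ``repr``.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Type, TypeVar

import numpy as np
import pandas as pd

from .abc_engine import ABCConfig, PosteriorSample, TargetProportions
from .embryo_model import ModelConfig

__all__ = [
    "config_to_text",
    "config_from_text",
    "write_table",
    "write_posterior",
    "read_posterior",
    "read_target_file",
    "write_target_file",
    "write_manifest",
]

T = TypeVar("T")

FLOAT_FMT = "%.6g"


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def config_to_text(config) -> str:
    """Serialize a config dataclass to flat ``key: value`` lines."""
    lines = [f"{f.name}: {_format_value(getattr(config, f.name))}" for f in dataclasses.fields(config)]
    return "\n".join(lines) + "\n"


def _parse_kv(text: str) -> dict[str, str]:
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out


def config_from_text(cls: Type[T], text: str) -> T:
    """Rebuild a config dataclass from ``key: value`` text (bit-exact for
    floats written by :func:`config_to_text`)."""
    raw = _parse_kv(text)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if f.type in ("int", int):
            kwargs[f.name] = int(v)
        elif f.type in ("float", float):
            kwargs[f.name] = float(v)
        elif f.type in ("bool", bool):
            kwargs[f.name] = v.lower() in ("true", "1", "yes")
        elif v == "None":
            kwargs[f.name] = None
        else:
            try:
                kwargs[f.name] = int(v)
            except ValueError:
                try:
                    kwargs[f.name] = float(v)
                except ValueError:
                    kwargs[f.name] = v
    return cls(**kwargs)


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    """Tab-separated table, single header row, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_posterior(out_dir: str | Path, posterior: PosteriorSample) -> None:
    """Particle table (theta, weight, distance) plus run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(posterior.thetas, columns=list(posterior.param_names))
    df["weight"] = posterior.weights
    df["distance"] = posterior.distances
    df.to_csv(out / "particles.tsv", sep="\t", index=False, float_format="%.10g")
    lines = [
        f"n_iterations: {posterior.n_iterations}",
        f"param_names: {','.join(posterior.param_names)}",
        f"tolerance_history: {','.join(repr(x) for x in posterior.tolerance_history)}",
        f"p_acc_history: {','.join(repr(x) for x in posterior.p_acc_history)}",
    ]
    for k, v in posterior.meta.items():
        lines.append(f"meta.{k}: {v}")
    (out / "abc_meta.txt").write_text("\n".join(lines) + "\n")


def read_posterior(out_dir: str | Path) -> PosteriorSample:
    out = Path(out_dir)
    meta = _parse_kv((out / "abc_meta.txt").read_text())
    df = pd.read_csv(out / "particles.tsv", sep="\t")
    param_names = tuple(meta["param_names"].split(","))
    extra = {
        k.removeprefix("meta."): v for k, v in meta.items() if k.startswith("meta.")
    }
    return PosteriorSample(
        thetas=df[list(param_names)].to_numpy(),
        weights=df["weight"].to_numpy(),
        distances=df["distance"].to_numpy(),
        tolerance_history=[float(x) for x in meta["tolerance_history"].split(",")],
        p_acc_history=[float(x) for x in meta["p_acc_history"].split(",") if x],
        n_iterations=int(meta["n_iterations"]),
        param_names=param_names,
        meta=extra,
    )


def write_target_file(path: str | Path, target: TargetProportions) -> None:
    Path(path).write_text(
        f"label: {target.label}\n"
        f"prop_euploid: {target.prop_euploid!r}\n"
        f"prop_mosaic: {target.prop_mosaic!r}\n"
        f"prop_aneuploid: {target.prop_aneuploid!r}\n"
        f"n_biopsies: {target.n_biopsies}\n"
    )


def read_target_file(path: str | Path) -> TargetProportions:
    raw = _parse_kv(Path(path).read_text())
    n = raw.get("n_biopsies", "None")
    return TargetProportions(
        label=raw.get("label", Path(path).stem),
        prop_euploid=float(raw["prop_euploid"]),
        prop_mosaic=float(raw["prop_mosaic"]),
        prop_aneuploid=float(raw["prop_aneuploid"]),
        n_biopsies=None if n == "None" else int(n),
    )


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    config_echo: dict,
    outputs: list[str],
    started: datetime.datetime | None = None,
) -> None:
    """One manifest per output directory: command, config echo, seed,
    timestamps, software version, output files."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    now = datetime.datetime.now().isoformat(timespec="seconds")
    lines = [
        f"command: {command}",
        f"version: {__version__}",
        f"seed: {seed}",
        f"started: {(started.isoformat(timespec='seconds') if started else now)}",
        f"finished: {now}",
    ]
    lines += [f"config.{k}: {_format_value(v)}" for k, v in config_echo.items()]
    lines += [f"output: {name}" for name in outputs]
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
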