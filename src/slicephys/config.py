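"""Pipeline configuration.

A :class:`PipelineConfig` bundles the tunable parameters of every stage
plus the random seed and output directory.  It round-trips losslessly
through a plain-text key/value file (one stage per section, INI syntax);
unknown keys are an error, not a warning — a silently ignored typo in a
threshold name would invalidate an analysis.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .ripples import RippleDetectParams
from .spectral import SpectrogramParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    detect: RippleDetectParams = field(default_factory=RippleDetectParams)
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    seed: int = 0
    out_dir: str = "."


_SECTIONS = {"detect": RippleDetectParams, "spectrogram": SpectrogramParams}
_GENERAL = {"seed": int, "out_dir": str}


def _coerce(kind, raw: str):
    if kind is bool:
        return raw.lower() in ("1", "true", "yes")
    if kind in (int, float, str):
        return kind(raw)
    raise TypeError(f"unsupported config field type {kind}")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a config file, rejecting unknown sections or keys."""
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    cfg = PipelineConfig()
    for section in cp.sections():
        if section == "general":
            for key, raw in cp.items(section):
                if key not in _GENERAL:
                    raise KeyError(f"unknown key [general] {key}")
                setattr(cfg, key, _coerce(_GENERAL[key], raw))
            continue
        if section not in _SECTIONS:
            raise KeyError(f"unknown config section [{section}]")
        cls = _SECTIONS[section]
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, raw in cp.items(section):
            if key not in fields:
                raise KeyError(f"unknown key [{section}] {key}")
            current = getattr(getattr(cfg, section), key)
            kwargs[key] = _coerce(type(current), raw)
        setattr(cfg, section, dataclasses.replace(getattr(cfg, section), **kwargs))
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the full configuration, one stage per section."""
    cp = configparser.ConfigParser()
    cp["general"] = {"seed": str(cfg.seed), "out_dir": cfg.out_dir}
    for name in _SECTIONS:
        params = getattr(cfg, name)
        cp[name] = {
            f.name: repr(getattr(params, f.name))
            if isinstance(getattr(params, f.name), str)
            else str(getattr(params, f.name))
            for f in dataclasses.fields(params)
            if not isinstance(getattr(params, f.name), (tuple, list))
        }
        # plain strings without quotes
        for f in dataclasses.fields(params):
            v = getattr(params, f.name)
            if isinstance(v, str):
                cp[name][f.name] = v
    with Path(path).open("w") as fh:
        cp.write(fh)
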