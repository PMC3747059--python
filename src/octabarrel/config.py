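"""Flat key = value run configuration.

The config file format is deliberately plain text (diffable, language
agnostic): one ``section.key = value`` per line, ``#`` comments.  Sections
map onto the dataclasses they configure: ``barrel.*`` -> BarrelParams,
``design.*`` -> DesignConfig, ``filter.*`` -> FilterThresholds.  Unknown
keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .barrel import BarrelParams
from .design import DesignConfig, FilterThresholds

_SECTIONS = {
    "barrel": BarrelParams,
    "design": DesignConfig,
    "filter": FilterThresholds,
}


def _coerce(value: str, typ):
    if typ is int:
        return int(value)
    if typ is float:
        return float(value)
    return value


def parse_config_text(text: str) -> dict:
    """Parse config text into {"barrel": {...}, "design": {...}, "filter": {...}}."""
    out: dict = {name: {} for name in _SECTIONS}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'section.key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if "." not in key:
            raise ValueError(f"line {lineno}: key {key!r} lacks a section prefix")
        section, _, name = key.partition(".")
        if section not in _SECTIONS:
            raise ValueError(f"line {lineno}: unknown section {section!r}")
        fields = {f.name: f for f in dataclasses.fields(_SECTIONS[section])}
        if name not in fields or name == "weights":
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        out[section][name] = _coerce(value, fields[name].type
                                     if isinstance(fields[name].type, type)
                                     else type(getattr(_SECTIONS[section](), name)))
    return out


def load_config(path) -> dict:
    return parse_config_text(Path(path).read_text())


def build_objects(cfg: dict, seed: int | None = None):
    """(BarrelParams, DesignConfig, FilterThresholds) from parsed config."""
    params = BarrelParams(**cfg.get("barrel", {}))
    design_kwargs = dict(cfg.get("design", {}))
    if seed is not None:
        design_kwargs["seed"] = seed
    design = DesignConfig(**design_kwargs)
    thresholds = FilterThresholds(**cfg.get("filter", {}))
    return params, design, thresholds


def resolved_config_text(params: BarrelParams, design: DesignConfig,
                         thresholds: FilterThresholds) -> str:
    """Render the fully resolved configuration back to the flat format."""
    lines = ["# resolved configuration"]
    for section, obj in (("barrel", params), ("design", design),
                         ("filter", thresholds)):
        for f in dataclasses.fields(obj):
            if f.name == "weights":
                continue
            lines.append(f"{section}.{f.name} = {getattr(obj, f.name)}")
    return "\n".join(lines) + "\n"
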