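"""Analysis configuration files (YAML, with JSON accepted).

A config file carries up to two sections, ``query`` and ``heatmap``, whose
keys mirror :class:`~gexmap.expression_query.QuerySpec` and
:class:`~gexmap.heatmap_export.HeatmapSpec`, plus a handful of top-level
I/O keys used by the command line (``store``, ``out``, ``format``,
``cell_size``).  Command-line flags override file values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ValidationError
from .expression_query import QuerySpec
from .heatmap_export import HeatmapSpec

__all__ = ["load_config_file", "query_spec_from_config", "heatmap_spec_from_config"]

_TOP_LEVEL_KEYS = {"query", "heatmap", "store", "out", "format", "cell_size", "csv", "per_disease"}


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Parse and shape-check a YAML/JSON config file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValidationError(
            f"{path}: unknown config key(s): {', '.join(sorted(unknown))} "
            f"(allowed: {', '.join(sorted(_TOP_LEVEL_KEYS))})"
        )
    for section in ("query", "heatmap"):
        if section in data and not isinstance(data[section], Mapping):
            raise ValidationError(f"{path}: section {section!r} must be a mapping")
    return dict(data)


def query_spec_from_config(config: Mapping[str, Any],
                           default_samples: list[str]) -> QuerySpec:
    """Build a QuerySpec from the ``query`` section, defaulting ``samples``
    to the full cohort when the section leaves them unset."""
    section = dict(config.get("query", {}))
    section.setdefault("samples", default_samples)
    return QuerySpec.from_dict(section)


def heatmap_spec_from_config(config: Mapping[str, Any]) -> HeatmapSpec:
    return HeatmapSpec.from_dict(dict(config.get("heatmap", {})))
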