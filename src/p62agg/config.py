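"""Flat key-value run configuration.

Config files are flat YAML mappings (no nesting), e.g.::

    n: 5
    kappa1: 1.0
    kappa2: 1.0
    kappa3: 1.0
    kappa_m1: 1.0
    kappa_m: 0.6
    p0: 2.0
    q0: 4.0
    r0: 3.0
    t_end: 100.0
    rtol: 1.0e-8
    atol: 1.0e-10

CLI flags override file values.  ``parse(serialize(cfg)) == cfg`` holds for
any mapping of scalars.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import DomainError

__all__ = ["load_config", "dump_config", "merge"]

_SCALARS = (str, int, float, bool, type(None))


def load_config(path) -> dict:
    """Parse a flat YAML mapping; rejects nested structures."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise DomainError(f"config {path} must be a flat mapping")
    for key, value in data.items():
        if not isinstance(value, _SCALARS):
            raise DomainError(
                f"config key {key!r} has non-scalar value {value!r}; "
                "the configuration format is flat"
            )
    return data


def dump_config(config: dict, path) -> None:
    """Serialize a flat mapping to YAML (round-trips through load_config)."""
    for key, value in config.items():
        if not isinstance(value, _SCALARS):
            raise DomainError(f"config key {key!r} has non-scalar value {value!r}")
    Path(path).write_text(
        yaml.safe_dump(dict(config), default_flow_style=False, sort_keys=True),
        encoding="utf-8",
    )


def merge(file_values: dict, flag_values: dict) -> dict:
    """File values overridden by any flag value that is not None."""
    merged = dict(file_values)
    for key, value in flag_values.items():
        if value is not None:
            merged[key] = value
    return merged
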