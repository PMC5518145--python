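"""Run configuration: the cfg_* parameters governing a sampling run."""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

__all__ = ["SampleConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete sampling configuration."""


@dataclass(frozen=True)
class SampleConfig:
    """All parameters governing a sampling run.

    Field names mirror the configuration keys accepted on the command line
    and in flat ``key = value`` config files, so a run can be described and
    reproduced from a single text file.
    """

    cfg_hh_per_stratum: int
    cfg_hh_per_urban: int
    cfg_hh_per_rural: int | None = None  # defaults to the urban value
    cfg_pop_per_psu: float = 0.0
    cfg_psu_growth: bool = True
    cfg_max_psu_size: float | None = None  # km^2 cap; None = uncapped
    cfg_min_pop_per_cell: float = 0.0
    cfg_desired_cell_size: int = 1
    cfg_sample_rururb: bool = False
    cfg_sample_spatial: bool = False
    cfg_sample_spatial_scale: float = 0.0  # km
    cfg_random_number: float | None = None
    sample_name: str = "sample"
    output_path: str = "."

    def __post_init__(self) -> None:
        if self.cfg_hh_per_stratum <= 0:
            raise ConfigError("cfg_hh_per_stratum must be a positive integer")
        if self.cfg_hh_per_urban <= 0:
            raise ConfigError("cfg_hh_per_urban must be a positive integer")
        if self.cfg_hh_per_rural is not None and self.cfg_hh_per_rural <= 0:
            raise ConfigError("cfg_hh_per_rural must be a positive integer")
        if self.cfg_psu_growth and self.cfg_pop_per_psu <= 0:
            raise ConfigError("cfg_pop_per_psu must be positive when growth is on")
        if self.cfg_max_psu_size is not None and self.cfg_max_psu_size <= 0:
            raise ConfigError("cfg_max_psu_size must be positive when given")
        if self.cfg_min_pop_per_cell < 0:
            raise ConfigError("cfg_min_pop_per_cell must be >= 0")
        if self.cfg_desired_cell_size < 1:
            raise ConfigError("cfg_desired_cell_size must be an integer >= 1")
        if self.cfg_sample_spatial and self.cfg_sample_spatial_scale <= 0:
            raise ConfigError(
                "cfg_sample_spatial_scale must be positive when spatial sampling is on"
            )
        if self.cfg_random_number is not None and not (0.0 <= self.cfg_random_number < 1.0):
            raise ConfigError("cfg_random_number must lie in [0, 1)")

    @property
    def hh_per_rural(self) -> int:
        """Households per rural PSU; the urban value when not specified."""
        return self.cfg_hh_per_rural if self.cfg_hh_per_rural is not None else self.cfg_hh_per_urban

    def hh_per_psu(self, urban: bool) -> int:
        return self.cfg_hh_per_urban if urban else self.hh_per_rural

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SampleConfig":
        """Build a config from a string-keyed mapping (config file / CLI)."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        unknown = []
        for key, raw in mapping.items():
            if key not in known:
                unknown.append(key)
                continue
            kwargs[key] = _coerce(known[key].type, raw)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
        missing = [
            name
            for name, f in known.items()
            if f.default is dataclasses.MISSING and name not in kwargs
        ]
        if missing:
            raise ConfigError(f"missing required configuration keys: {', '.join(missing)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | os.PathLike, overrides: dict | None = None) -> "SampleConfig":
        """Parse a flat ``key = value`` file; ``#`` starts a comment."""
        mapping: dict = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                mapping[key] = value
        if overrides:
            mapping.update(overrides)
        return cls.from_mapping(mapping)


_TRUE = {"true", "t", "yes", "1", "on"}
_FALSE = {"false", "f", "no", "0", "off"}


def _coerce(annotation: object, raw: object):
    """Coerce a raw config value (usually a string) to the annotated type."""
    if not isinstance(raw, str):
        return raw
    text = raw.strip().strip("\"'")
    ann = str(annotation)
    if text.lower() in {"none", ""}:
        return None
    if "bool" in ann:
        low = text.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ConfigError(f"cannot interpret {text!r} as a boolean")
    if "int" in ann and "float" not in ann:
        return int(text)
    if "float" in ann:
        return float(text)
    return text
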