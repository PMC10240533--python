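"""Run configuration: one flat key-value namespace with units in key names.

The reference dynamics mixes atomic units, fs, eV and nm; to prevent unit
drift every key carries its unit as a suffix (``lw_trcd_ev``, ``dt_fs``,
...).  A :class:`RunConfig` bundles the generator configuration with the
spectral and analysis settings and round-trips through YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

import yaml

from .conformers import DEFAULT_WINDOWS
from .dynamics import GeneratorConfig
from .errors import ParameterError
from .spectra import SpectralGrid

__all__ = ["RunConfig", "config_hash"]

_GEN_FIELDS = {
    f.name for f in fields(GeneratorConfig) if f.name != "surrogate"
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation + analysis run.

    Defaults mirror the reference computation: 0.1 eV line width for static
    spectra, 0.5 eV for the time-resolved signal, spectra sampled every 10
    nuclear steps (~9.7 fs delay spacing), additive combination with the
    parent reference, traces at 280/300/320 nm and the A-E analysis
    windows.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid_min_nm: float = 240.0
    grid_max_nm: float = 380.0
    grid_points: int = 141
    lw_static_ev: float = 0.1
    lw_trcd_ev: float = 0.5
    stride: int = 10
    combine_mode: str = "add"
    trace_wavelengths_nm: tuple = (280.0, 300.0, 320.0)
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self):
        if self.combine_mode not in ("add", "subtract"):
            raise ParameterError("combine_mode must be 'add' or 'subtract'")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.lw_static_ev <= 0 or self.lw_trcd_ev <= 0:
            raise ParameterError("line widths must be > 0")

    def grid(self) -> SpectralGrid:
        return SpectralGrid.default(self.grid_min_nm, self.grid_max_nm, self.grid_points)

    # -- flat serialisation --------------------------------------------
    def to_mapping(self) -> dict:
        flat: dict = {}
        for name in sorted(_GEN_FIELDS):
            flat[name] = getattr(self.generator, name)
        for f in fields(self):
            if f.name in ("generator", "windows", "trace_wavelengths_nm"):
                continue
            flat[f.name] = getattr(self, f.name)
        flat["trace_wavelengths_nm"] = list(self.trace_wavelengths_nm)
        for name, (t0, t1) in self.windows.items():
            flat[f"window_{name}_fs"] = [float(t0), float(t1)]
        return flat

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        gen_kwargs = {k: mapping.pop(k) for k in list(mapping) if k in _GEN_FIELDS}
        windows = {}
        for key in list(mapping):
            if key.startswith("window_") and key.endswith("_fs"):
                name = key[len("window_"):-len("_fs")]
                t0, t1 = mapping.pop(key)
                windows[name] = (float(t0), float(t1))
        traces = mapping.pop("trace_wavelengths_nm", None)
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(generator=GeneratorConfig(**gen_kwargs), **mapping)
        if windows:
            cfg.windows = windows
        if traces is not None:
            cfg.trace_wavelengths_nm = tuple(float(w) for w in traces)
        return cfg

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the full flat configuration."""
    text = yaml.safe_dump(config.to_mapping(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
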