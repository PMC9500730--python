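"""Filtration parameters: every default equals the published pipeline value.

Two boundary conventions coexist deliberately: the precursor screening gate
is strict (sample:blank > 5) while the fragment filtration gate is
inclusive (>= 5), mirroring the way the thresholds are stated at the two
stages.

The FWHM-shift threshold 17.4965 is printed without a unit while the width
shift itself is a dimensionless fraction; the default reads it as a
percentage (0.174965 as a fraction).  ``width_shift_literal()`` builds the
literal reading (17.4965 as a raw fraction), which effectively disables the
gate - the ambiguity is logged whenever that mode is used.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import yaml

from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class FiltrationParams:
    ppm_tol: float = 10.0  # precursor mass tolerance, ppm
    snr_min: float = 30.0  # precursor XIC S/N gate
    screen_blank_ratio_min: float = 5.0  # strict > at screening
    filter_blank_ratio_min: float = 5.0  # inclusive >= at filtration
    frag_tol_da: float = 0.05  # fragment XIC extraction half-window, Da
    rt_shift_max: float = 0.001417  # relative RT shift gate (= 0.1417%)
    width_shift_max: float = 0.174965  # relative FWHM shift gate (percent reading)
    rel_int_min_pct: float = 5.0  # observed relative-intensity floor, %
    d_threshold_pct: float = 75.0  # main-daughter tag threshold, %
    dedup_mz_tol: float = 0.01  # near-duplicate fragment collapse, Da
    fragment_blank_gate: bool = True  # re-test the blank ratio per fragment
    # scoring weights: library coverage, RT-shift closeness, intensity cosine
    w_coverage: float = 0.5
    w_rt: float = 0.3
    w_cosine: float = 0.2

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "snr_min", "screen_blank_ratio_min",
                     "filter_blank_ratio_min", "frag_tol_da", "rt_shift_max",
                     "width_shift_max", "rel_int_min_pct", "d_threshold_pct",
                     "dedup_mz_tol"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def width_shift_literal(cls, **overrides) -> "FiltrationParams":
        """Literal reading of the printed FWHM threshold (17.4965 as a fraction)."""
        log.warning("width-shift gate in LITERAL mode (17.4965 as a raw fraction): "
                    "this threshold is effectively non-filtering")
        overrides.setdefault("width_shift_max", 17.4965)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FiltrationParams":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown filtration parameters: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "FiltrationParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("params file must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kw) -> "FiltrationParams":
        return replace(self, **kw)
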