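"""Run configuration: a flat key = value file with a strict schema.

Unknown keys are an error rather than a warning — a typo in a threshold
key must not silently run with defaults.  The full configuration is
serialised verbatim into every output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .segmentation import DEFAULT_MIN_AREA_UM2


class ConfigError(ValueError):
    pass


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("true", "yes", "1"):
        return True
    if s in ("false", "no", "0"):
        return False
    raise ConfigError(f"not a boolean: {s!r}")


def _parse_floats(s: str) -> tuple[float, ...]:
    return tuple(float(x) for x in s.replace(" ", "").split(",") if x)


def _parse_ints(s: str) -> tuple[int, ...]:
    return tuple(int(x) for x in s.replace(" ", "").split(",") if x)


def _parse_opt_float(s: str) -> float | None:
    s = s.strip()
    return None if s.lower() in ("", "none") else float(s)


@dataclass
class RunConfig:
    """All pipeline and simulation parameters for one run."""

    # paths
    input_dir: str = "."
    plate_map: str = "plate_map.csv"
    output_dir: str = "out"
    # acquisition calibration and projection
    pixel_size: float = 2.0  # µm/pixel
    tile_size: int = 64  # best-focus tile edge, pixels
    # segmentation
    polarity: str = "dark_objects"
    threshold_k: float = 3.0
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    max_area_um2: float | None = None
    exclude_border: bool = False
    # readouts / normalisation
    anchor_day_policy: str = "first"  # first usable imaged day per well
    # dose-response
    dose_min: float = 0.1  # nM
    dose_max: float = 1000.0  # nM
    dose_fold: float = 10.0
    readouts_to_fit: tuple[str, ...] = (
        "relative_total_area",
        "mean_perimeter",
        "mean_size",
        "mean_diameter",
    )
    fit_days: tuple[int, ...] = ()  # empty = all imaged days
    seed: int = 0
    # simulation scenario
    sim_image_height: int = 512
    sim_image_width: int = 512
    sim_n_planes: int = 5
    sim_plane_spacing: float = 50.0
    sim_n_objects: int = 20
    sim_radius_min: float = 25.0
    sim_radius_max: float = 80.0
    sim_growth_rate: float = 0.08
    sim_days: tuple[int, ...] = tuple(range(1, 15))
    sim_doses: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)
    sim_ic50: float = 10.0
    sim_hill: float = 1.0
    sim_treatment_start: float = 2.0
    sim_treatment_duration: float = 7.0
    sim_background_level: float = 0.85
    sim_object_level: float = 0.35
    sim_noise_sd: float = 0.01
    sim_blur_per_um: float = 0.04
    sim_min_separation: float | None = None
    sim_replicates: int = 4
    sim_sample_id: str = "S1"
    sim_drug: str = "SN-38"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.tile_size < 8:
            raise ConfigError("tile_size must be at least 8")
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ConfigError(f"unknown polarity: {self.polarity!r}")
        if self.threshold_k <= 0:
            raise ConfigError("threshold_k must be positive")
        if self.min_area_um2 < 0:
            raise ConfigError("min_area_um2 must be non-negative")
        if self.anchor_day_policy != "first":
            raise ConfigError("anchor_day_policy must be 'first'")

    # -- (de)serialisation --------------------------------------------
    @classmethod
    def _converters(cls):
        conv = {}
        for fld in dataclasses.fields(cls):
            if fld.name in ("max_area_um2", "sim_min_separation"):
                conv[fld.name] = _parse_opt_float
            elif fld.type in ("float", float):
                conv[fld.name] = float
            elif fld.type in ("int", int):
                conv[fld.name] = int
            elif fld.type in ("bool", bool):
                conv[fld.name] = _parse_bool
            elif fld.name in ("fit_days", "sim_days"):
                conv[fld.name] = _parse_ints
            elif fld.name in ("readouts_to_fit",):
                conv[fld.name] = lambda s: tuple(x.strip() for x in s.split(",") if x.strip())
            elif fld.name in ("sim_doses",):
                conv[fld.name] = _parse_floats
            else:
                conv[fld.name] = str
        return conv

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "RunConfig":
        conv = cls._converters()
        unknown = sorted(set(mapping) - set(conv))
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        kwargs = {}
        for key, raw in mapping.items():
            try:
                kwargs[key] = conv[key](raw) if isinstance(raw, str) else raw
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"bad value for {key}: {raw!r} ({exc})") from exc
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = stripped.partition("=")
            key = key.strip()
            if key in mapping:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            mapping[key] = value.strip()
        return cls.from_mapping(mapping)

    def to_text(self) -> str:
        """Flat key = value serialisation, round-trippable via from_file."""
        lines = []
        for fld in dataclasses.fields(self):
            val = getattr(self, fld.name)
            if isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            elif val is None:
                val = "none"
            lines.append(f"{fld.name} = {val}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())
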