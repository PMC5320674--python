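"""Run configuration: flat key-value parameters, INI files, and the
deterministic seed fan-out that makes every pipeline stage independently
reproducible from one global seed."""

from __future__ import annotations

import configparser
import zlib
from pathlib import Path

DEFAULTS: dict[str, object] = {
    # imaging
    "pixel_size_um": 0.05,
    "modality": "PF",
    # segmentation
    "min_area_px": 100,
    "max_area_px": 500000,
    "intensity_floor": 0.0,
    "intensity_ceiling": 1.0,
    "fp_ratio_threshold": 1.2,
    "background_radius_px": 0,
    "rescale_factor": 1.0,
    "threshold_method": "otsu",
    # contour fitting
    "alpha": 0.05,
    "beta": 0.5,
    "step": 0.2,
    "tol": 1e-3,
    "max_iter": 500,
    "spacing_px": 1.0,
    # meshing
    "window_arc_um": 0.25,
    # simulator / validation
    "na": 1.4,
    "wavelength_um": 0.61,
    "magnification": 100.0,
    "refractive_index": 1.515,
    "density_per_um2": 2000.0,
    "photons_per_intensity": 200.0,
    "camera_offset": 100.0,
    "read_sigma": 2.0,
    "dark_rate": 0.0,
    "replicates": 3,
    # population / screen
    "inclusion_n": 150,
    "alpha_level": 0.05,
    "min_strata_n": 10,
    "cog_family": "classes_x_conditions",
    # global
    "seed": 0,
}


class ConfigError(ValueError):
    pass


def resolve(config_path: str | None = None,
            overrides: dict[str, str] | None = None) -> dict[str, object]:
    """Merge defaults, an optional INI file ([rodmorph] section), and
    key=value overrides. Unknown keys are rejected; values are coerced to
    the type of the default."""
    cfg = dict(DEFAULTS)
    items: dict[str, str] = {}
    if config_path:
        parser = configparser.ConfigParser()
        read = parser.read(str(config_path))
        if not read:
            raise ConfigError(f"config file not found: {config_path}")
        section = "rodmorph" if parser.has_section("rodmorph") else \
            parser.default_section
        items.update(dict(parser.items(section)))
    items.update(overrides or {})
    for key, raw in items.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key}")
        default = DEFAULTS[key]
        try:
            if isinstance(default, bool):
                cfg[key] = str(raw).lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                cfg[key] = int(raw)
            elif isinstance(default, float):
                cfg[key] = float(raw)
            else:
                cfg[key] = str(raw)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"bad value for {key}: {raw!r}") from err
    return cfg


def write_resolved(cfg: dict[str, object], out_dir) -> None:
    """Every run writes its resolved configuration alongside its outputs."""
    parser = configparser.ConfigParser()
    parser["rodmorph"] = {k: str(v) for k, v in cfg.items()}
    path = Path(out_dir) / "resolved_config.ini"
    with path.open("w", encoding="utf-8") as fh:
        parser.write(fh)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31, so stages can be rerun
    independently of one another."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)
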