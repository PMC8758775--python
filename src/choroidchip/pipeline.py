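"""End-to-end runs: synthesize or load stacks, preprocess, segment,
quantify and report; and the trace → fit → lag permeability run.

Both entry points are driven by a single YAML-serializable configuration
whose defaults are the published analysis parameters, and both persist a
manifest (config digest, software version, input checksums, stage timings,
warnings) so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocessing import PreprocessConfig, preprocess_channel
from .quantification import (
    CompartmentBins,
    MIN_OBJECT_VOXELS,
    RecruitmentReport,
    bin_by_depth,
    classify_tcells,
    measure_objects,
    size_filter,
)
from .segmentation import (
    GREEN_IMAGE_CONSTANT,
    GREEN_SEEDS_CONSTANT,
    GreenNormalization,
    WatershedParams,
    binarize_labels,
    detect_seeds,
    green_thresholds,
    watershed3d,
)
from .stack import ImageStack
from .synthetic import SceneSpec, TraceSpec, generate_kinetic_trace, generate_recruitment_scene
from .permeability import (
    FitResult,
    fit_t50,
    normalize_trace,
    read_traces_csv,
    relative_permeability,
)

__all__ = [
    "ChipGeometry",
    "ChipRunConfig",
    "PermeabilityRunConfig",
    "RunManifest",
    "run_recruitment",
    "run_permeability",
    "ConfigError",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class ChipGeometry:
    """Layer heights of the three stacked channels (RPE / endothelial /
    stromal), each 100 µm tall in the fabricated chip."""

    layer_heights_um: tuple[float, float, float] = (100.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.layer_heights_um):
            raise ConfigError("layer heights must be positive")

    @property
    def tissue_height_um(self) -> float:
        return float(sum(self.layer_heights_um))


@dataclass
class ChipRunConfig:
    """Everything one recruitment run needs. Defaults are the published
    parameter set (rescale 1.8, sigma 5, closing radius 2, red thresholds
    1000/500, green normalization constants, 30-voxel size filter,
    0–63/64–126 µm depth bins)."""

    chip_id: str = "chip"
    # input: either paths to red/green TIFFs, or a synthetic scene spec
    red_path: str | None = None
    green_path: str | None = None
    scene: SceneSpec | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    red_watershed: WatershedParams = field(default_factory=WatershedParams)
    green_seeds_constant: float = GREEN_SEEDS_CONSTANT
    green_image_constant: float = GREEN_IMAGE_CONSTANT
    min_object_voxels: int = MIN_OBJECT_VOXELS
    bins: CompartmentBins = field(default_factory=CompartmentBins)
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    out_dir: str | None = None
    save_intermediates: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.red_path is not None and self.green_path is not None
        if not has_paths and self.scene is None:
            raise ConfigError("provide either red/green TIFF paths or a scene spec")
        if self.min_object_voxels < 0:
            raise ConfigError("min_object_voxels must be >= 0")
        if self.green_seeds_constant <= 0 or self.green_image_constant <= 0:
            raise ConfigError("green normalization constants must be positive")

    # -- YAML round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ChipRunConfig":
        d = dict(d)
        if d.get("scene") is not None:
            s = dict(d["scene"])
            for key in ("shape_xyz", "spacing_xyz", "cell_radius_bounds_um"):
                if key in s:
                    s[key] = tuple(s[key])
            d["scene"] = SceneSpec(**s)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            p = dict(d["preprocess"])
            for key in ("hybrid_median_channels", "closing_channels"):
                if key in p:
                    p[key] = frozenset(p[key])
            d["preprocess"] = PreprocessConfig(**p)
        if "red_watershed" in d and isinstance(d["red_watershed"], dict):
            d["red_watershed"] = WatershedParams(**d["red_watershed"])
        if "bins" in d and isinstance(d["bins"], dict):
            b = dict(d["bins"])
            for key in ("bottom_range_um", "top_range_um"):
                if key in b:
                    b[key] = tuple(b[key])
            d["bins"] = CompartmentBins(**b)
        if "geometry" in d and isinstance(d["geometry"], dict):
            g = dict(d["geometry"])
            if "layer_heights_um" in g:
                g["layer_heights_um"] = tuple(g["layer_heights_um"])
            d["geometry"] = ChipGeometry(**g)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ChipRunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Fingerprint of the analysis parameters (output location excluded)."""
        d = _jsonable(self.to_dict())
        for key in ("out_dir", "save_intermediates"):
            d.pop(key, None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    config_digest: str
    software_version: str
    input_checksums: dict
    stage_timings_s: dict
    warnings: list

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_recruitment(config: ChipRunConfig):
    """Execute preprocess → segment → measure → classify → bin for one chip.

    Returns ``(report, objects)`` and, when ``config.out_dir`` is set, also
    persists the object table (CSV), the report (CSV + JSON) and the run
    manifest; with ``save_intermediates`` the preprocessed stacks and label
    maps are written as TIFF.
    """
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    warnings_log: list[str] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def timed(stage):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timings[stage] = round(time.perf_counter() - self_inner.t0, 4)

        return _T()

    # stage: input
    try:
        with timed("input"):
            if config.scene is not None:
                red, green, truth = generate_recruitment_scene(config.scene)
            else:
                red = ImageStack.from_tiff(config.red_path, channel="red")
                green = ImageStack.from_tiff(config.green_path, channel="green")
                truth = None
                checksums["red"] = _sha256_file(config.red_path)
                checksums["green"] = _sha256_file(config.green_path)
    except Exception as e:
        raise RuntimeError(f"stage 'input' failed: {e}") from e

    try:
        with timed("preprocess"):
            red_p = preprocess_channel(red, config.preprocess)
            green_p = preprocess_channel(green, config.preprocess)
        logger.info(
            "preprocessed: red %d voxels >= %g, green max %g",
            int(np.count_nonzero(red_p.voxels >= config.red_watershed.image_threshold)),
            config.red_watershed.image_threshold,
            float(green_p.voxels.max()),
        )
    except Exception as e:
        raise RuntimeError(f"stage 'preprocess' failed: {e}") from e

    try:
        with timed("segment_red"):
            wp = config.red_watershed
            red_seeds = detect_seeds(red_p, wp.seed_radius_vox, wp.seeds_threshold)
            red_labels = watershed3d(red_p, red_seeds, wp.image_threshold, wp.connectivity)
    except Exception as e:
        raise RuntimeError(f"stage 'segment_red' failed: {e}") from e

    try:
        with timed("segment_green"):
            max_green = float(green_p.voxels.max())
            if max_green <= 0:
                warnings_log.append("green channel empty after preprocessing; no T cells")
                green_bin = ImageStack(
                    np.zeros(green_p.shape_zyx, dtype=np.uint8), green_p.spacing_xyz, "binary"
                )
            else:
                norm = GreenNormalization(
                    max_green=max_green,
                    seeds_constant=config.green_seeds_constant,
                    image_constant=config.green_image_constant,
                )
                g_seeds_thr, g_image_thr = green_thresholds(norm)
                g_seeds = detect_seeds(green_p, wp.seed_radius_vox, g_seeds_thr)
                green_labels = watershed3d(green_p, g_seeds, g_image_thr, wp.connectivity)
                green_bin = binarize_labels(green_labels)
    except Exception as e:
        raise RuntimeError(f"stage 'segment_green' failed: {e}") from e

    try:
        with timed("quantify"):
            objects = measure_objects(red_labels)
            objects = size_filter(objects, config.min_object_voxels)
            objects = classify_tcells(objects, red_labels, green_bin)
            report = bin_by_depth(
                objects, config.bins, chip_id=config.chip_id, params_digest=config.digest()
            )
    except Exception as e:
        raise RuntimeError(f"stage 'quantify' failed: {e}") from e

    if out_dir:
        with timed("write"):
            obj_df = pd.DataFrame(
                [
                    {
                        "label": o.label,
                        "x_um": o.centroid_um[0],
                        "y_um": o.centroid_um[1],
                        "z_um": o.centroid_um[2],
                        "volume_vox": o.volume_vox,
                        "volume_um3": o.volume_um3,
                        "is_tcell": int(o.is_tcell),
                    }
                    for o in objects
                ]
            )
            obj_df.to_csv(out_dir / "objects.csv", index=False)
            pd.DataFrame([report.as_dict()]).to_csv(out_dir / "report.csv", index=False)
            (out_dir / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
            if config.save_intermediates:
                red_p.save_tiff(out_dir / "red_preprocessed.tif")
                green_p.save_tiff(out_dir / "green_preprocessed.tif")
                red_labels.save_tiff(out_dir / "red_labels.tif")
                green_bin.save_tiff(out_dir / "green_binary.tif")
            RunManifest(
                config_digest=config.digest(),
                software_version=__version__,
                input_checksums=checksums,
                stage_timings_s=timings,
                warnings=warnings_log,
            ).write(out_dir / "manifest.json")

    return report, objects


@dataclass
class PermeabilityRunConfig:
    """Inputs for one permeability run: either a long-format trace CSV or
    synthetic trace specs, one per channel (MVEC / stromal / RPE)."""

    traces_path: str | None = None
    synthetic_traces: dict[str, TraceSpec] | None = None
    normalize: bool = True
    free_asymptotes: bool = False
    molecule_label: str = ""
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.traces_path is None and not self.synthetic_traces:
            raise ConfigError("provide a trace CSV or synthetic trace specs")


def run_permeability(config: PermeabilityRunConfig):
    """Fit t50 per channel and tabulate all pairwise lag times.

    Returns ``(fits, lag_table)``: a dict of per-channel
    :class:`~choroidchip.permeability.FitResult` and a DataFrame with one
    row per ordered channel pair. Unconverged fits stay in the fit table
    (flagged) and their pairs carry a NaN lag rather than being dropped.
    """
    if config.traces_path is not None:
        traces = read_traces_csv(config.traces_path)
    else:
        traces = {
            ch: generate_kinetic_trace(spec) for ch, spec in config.synthetic_traces.items()
        }
        for ch, tr in traces.items():
            tr.channel_id = ch
    if len(traces) < 2:
        raise ConfigError(f"need traces for >= 2 channels, got {len(traces)}")

    fits: dict[str, FitResult] = {}
    for ch, tr in traces.items():
        if config.normalize and not tr.normalized:
            tr = normalize_trace(tr)
        fits[ch] = fit_t50(tr, free_asymptotes=config.free_asymptotes)
        if not fits[ch].converged:
            logger.warning("fit did not converge for channel %s", ch)

    rows = []
    channels = list(traces)
    for src in channels:
        for tgt in channels:
            if src == tgt:
                continue
            if fits[src].converged and fits[tgt].converged:
                lag = relative_permeability(fits[src], fits[tgt], config.molecule_label).lag_s
            else:
                lag = float("nan")
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "t50_source_s": fits[src].t50_s,
                    "t50_target_s": fits[tgt].t50_s,
                    "lag_s": lag,
                    "molecule": config.molecule_label,
                }
            )
    lag_table = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit_df = pd.DataFrame(
            [
                {
                    "channel": ch,
                    "t50_s": f.t50_s,
                    "slope": f.slope,
                    "rms_residual": f.fit_quality,
                    "converged": f.converged,
                }
                for ch, f in fits.items()
            ]
        )
        fit_df.to_csv(out / "fits.csv", index=False)
        lag_table.to_csv(out / "lags.csv", index=False)
    return fits, lag_table
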