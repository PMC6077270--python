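"""File formats and experiment configuration.

Images come in as single-channel 8/16-bit grayscale TIFF or PNG (one file
per channel) or as one multichannel TIFF with a role → plane-index map;
internally all intensities are non-negative float64. Sections are written
back as per-channel 16-bit TIFFs named ``{sample_id}_{channel}.tif`` with
values clipped to the fixed [0, 65535] dynamic range. Masks round-trip as
8-bit 0/255 TIFFs with a JSON provenance sidecar. Detections and ROIs are
plain CSV.

The experiment configuration is a single YAML file; every stage parameter
has a default, and ``eduquant config --defaults`` prints the full
defaulted file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import DetectionParams
from .errors import ConfigError, FormatError, ValidationError
from .segmentation import SegmentationParams
from .types import AreaMask, CellDetectionSet, CircularRoi, FluorescenceSection

__all__ = [
    "read_image",
    "read_section",
    "write_section",
    "read_mask",
    "write_mask",
    "detections_to_csv",
    "detections_from_csv",
    "rois_to_csv",
    "rois_from_csv",
    "LocalizationConfig",
    "SamplingConfig",
    "QuantificationConfig",
    "SampleSpec",
    "ExperimentConfig",
    "load_config",
    "default_config_yaml",
    "config_hash",
]

_ALLOWED_DTYPES = (np.uint8, np.uint16)


def read_image(path) -> np.ndarray:
    """Read one grayscale image plane (TIFF or PNG) as float64."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with the filename
        raise FormatError(f"could not read image {path}: {exc}") from exc
    if arr.dtype not in _ALLOWED_DTYPES:
        raise FormatError(
            f"{path}: unsupported bit depth {arr.dtype}; expected 8- or "
            "16-bit unsigned grayscale"
        )
    return arr.astype(np.float64)


def read_section(
    paths,
    pixel_size_um: float,
    sample_id: str | None = None,
    group_label: str | None = None,
    target_name: str | None = None,
    channel_index: dict[str, int] | None = None,
) -> FluorescenceSection:
    """Load a section from per-channel files or one multichannel TIFF.

    ``paths`` is either a mapping role → file path (each a 2-D grayscale
    image), or a single path to a multichannel TIFF together with
    ``channel_index`` mapping role → plane index along the smallest axis.
    Channel shapes must match exactly.
    """
    channels: dict[str, np.ndarray] = {}
    if isinstance(paths, (str, os.PathLike)):
        if not channel_index:
            raise ValidationError(
                "a multichannel file needs a channel_index map (role -> plane)"
            )
        path = Path(paths)
        if not path.exists():
            raise FormatError(f"image file not found: {path}")
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read image {path}: {exc}") from exc
        if arr.dtype not in _ALLOWED_DTYPES:
            raise FormatError(f"{path}: unsupported bit depth {arr.dtype}")
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected a 3-D multichannel TIFF")
        axis = int(np.argmin(arr.shape))
        planes = np.moveaxis(arr, axis, 0)
        for role, idx in channel_index.items():
            if not (0 <= idx < planes.shape[0]):
                raise FormatError(f"{path}: channel index {idx} out of range")
            channels[role] = planes[idx].astype(np.float64)
    else:
        shapes = {}
        for role, p in dict(paths).items():
            channels[role] = read_image(p)
            shapes[str(p)] = channels[role].shape
        if len(set(shapes.values())) > 1:
            raise FormatError(f"channel shape mismatch: {shapes}")
        sample_id = sample_id or Path(next(iter(dict(paths).values()))).stem
    return FluorescenceSection(
        sample_id=sample_id or "section",
        channels=channels,
        pixel_size_um=pixel_size_um,
        group_label=group_label,
        target_name=target_name,
    )


def write_section(section: FluorescenceSection, directory) -> dict[str, str]:
    """Write per-channel 16-bit TIFFs ``{sample_id}_{channel}.tif``.

    Float intensities are clipped to [0, 65535] and rounded; the package
    treats that range as the fixed dynamic range of rendered images.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for role, arr in section.channels.items():
        path = directory / f"{section.sample_id}_{role}.tif"
        tifffile.imwrite(path, np.clip(np.rint(arr), 0, 65535).astype(np.uint16))
        out[role] = str(path)
    return out


def write_mask(mask: AreaMask, path) -> str:
    """8-bit 0/255 TIFF plus a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255))
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"role": mask.role, "provenance": mask.provenance}, fh, indent=1)
    return str(path)


def read_mask(path) -> AreaMask:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    role, prov = "proliferating", {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        role = meta.get("role", role)
        prov = meta.get("provenance", {})
    return AreaMask(arr > 0, role, prov)


def detections_to_csv(detections: list[CellDetectionSet], path) -> None:
    rows = []
    for det in detections:
        for (r, c), peak in zip(det.centroids, det.peak_intensity):
            rows.append(
                {
                    "sample_id": det.section_id,
                    "channel": det.channel_role,
                    "row": r,
                    "col": c,
                    "peak_intensity": peak,
                }
            )
    df = pd.DataFrame(rows, columns=["sample_id", "channel", "row", "col", "peak_intensity"])
    if len(df):
        df = df.sort_values(["sample_id", "channel", "row", "col"]).reset_index(drop=True)
    # %.17g: staged runs re-read this file; floats must round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def detections_from_csv(path) -> list[CellDetectionSet]:
    df = pd.read_csv(path)
    out = []
    for (sid, chan), grp in df.groupby(["sample_id", "channel"], sort=True):
        out.append(
            CellDetectionSet(
                section_id=str(sid),
                channel_role=str(chan),
                centroids=grp[["row", "col"]].to_numpy(float),
                peak_intensity=grp["peak_intensity"].to_numpy(float),
            )
        )
    return out


def rois_to_csv(rois_by_sample: dict[tuple[str, str], list[CircularRoi]], path) -> None:
    """``rois_by_sample`` maps (sample_id, channel) to that section's ROIs."""
    rows = []
    for (sid, chan), rois in rois_by_sample.items():
        for roi in rois:
            rows.append(
                {
                    "sample_id": sid,
                    "channel": chan,
                    "roi_id": roi.roi_id,
                    "row": roi.center[0],
                    "col": roi.center[1],
                    "radius_px": roi.radius_px,
                    "compartment": roi.compartment,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "channel", "roi_id", "row", "col", "radius_px", "compartment"],
    )
    if len(df):
        df = df.sort_values(["sample_id", "channel", "roi_id"]).reset_index(drop=True)
    # %.17g: staged runs re-read this file; floats must round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def rois_from_csv(path) -> dict[tuple[str, str], list[CircularRoi]]:
    df = pd.read_csv(path)
    out: dict[tuple[str, str], list[CircularRoi]] = {}
    for _, row in df.iterrows():
        roi = CircularRoi(
            roi_id=str(row["roi_id"]),
            center=(float(row["row"]), float(row["col"])),
            radius_px=float(row["radius_px"]),
            compartment=str(row["compartment"]),
        )
        out.setdefault((str(row["sample_id"]), str(row["channel"])), []).append(roi)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LocalizationConfig:
    metric: str = "cells"  # 'cells' or 'area'
    low: float = 0.25
    high: float = 0.75
    force_compartment: str | None = None  # override an ambiguous call

    def __post_init__(self):
        if self.metric not in ("cells", "area"):
            raise ConfigError(f"localization.metric must be cells|area, got {self.metric}")


@dataclass(frozen=True)
class SamplingConfig:
    k: int = 3
    radius_px: float | None = None  # None -> area-fraction rule
    area_fraction: float = 0.06
    no_overlap: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("sampling.k must be >= 1")


@dataclass(frozen=True)
class QuantificationConfig:
    n_boot: int = 0


@dataclass(frozen=True)
class TissueConfig:
    enabled: bool = False
    smooth_sigma_px: float = 8.0
    threshold: float | None = None


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str
    files: dict[str, str]  # role -> path (resolved relative to config file)
    channel_index: dict[str, int] | None = None

    def __post_init__(self):
        if self.group not in ("control", "treated"):
            raise ConfigError(
                f"sample '{self.sample_id}': group must be control|treated"
            )


@dataclass(frozen=True)
class ExperimentConfig:
    pixel_size_um: float
    seed: int
    samples: tuple[SampleSpec, ...]
    target_name: str = ""
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    quantification: QuantificationConfig = field(default_factory=QuantificationConfig)
    tissue: TissueConfig = field(default_factory=TissueConfig)

    def __post_init__(self):
        if not (self.pixel_size_um > 0):
            raise ConfigError("pixel_size_um must be > 0")
        if not self.samples:
            raise ConfigError("config lists no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate sample ids in config")


def _build(cls, block: dict, where: str):
    try:
        return cls(**(block or {}))
    except TypeError as exc:
        raise ConfigError(f"bad '{where}' block: {exc}") from exc


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config.

    File references are resolved relative to the config file's directory
    and must exist; validation happens before any computation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "pixel_size_um" not in raw:
        raise ConfigError("config is missing pixel_size_um")
    if "seed" not in raw:
        raise ConfigError("config is missing seed (required: ROI sampling is stochastic)")
    base = path.parent
    samples = []
    for s in raw.get("samples", []):
        try:
            files = {
                role: str((base / p).resolve()) for role, p in (s.get("files") or {}).items()
            }
            spec = SampleSpec(
                sample_id=s["sample_id"],
                group=s["group"],
                files=files,
                channel_index=s.get("channel_index"),
            )
        except KeyError as exc:
            raise ConfigError(f"sample entry missing field {exc}") from exc
        roles = set(spec.files)
        if spec.channel_index is None and roles != {"edu", "protein"}:
            raise ConfigError(
                f"sample '{spec.sample_id}': files must cover roles edu and "
                f"protein, got {sorted(roles)}"
            )
        for role, p in spec.files.items():
            if not Path(p).exists():
                raise ConfigError(f"sample '{spec.sample_id}': missing file {p}")
        samples.append(spec)
    try:
        seg = _build(SegmentationParams, raw.get("segmentation"), "segmentation")
        det_block = dict(raw.get("detection") or {})
        if "sigma_factors" in det_block:
            det_block["sigma_factors"] = tuple(det_block["sigma_factors"])
        det = _build(DetectionParams, det_block, "detection")
        return ExperimentConfig(
            pixel_size_um=float(raw["pixel_size_um"]),
            seed=int(raw["seed"]),
            samples=tuple(samples),
            target_name=str(raw.get("target_name", "")),
            segmentation=seg,
            detection=det,
            localization=_build(LocalizationConfig, raw.get("localization"), "localization"),
            sampling=_build(SamplingConfig, raw.get("sampling"), "sampling"),
            quantification=_build(QuantificationConfig, raw.get("quantification"), "quantification"),
            tissue=_build(TissueConfig, raw.get("tissue"), "tissue"),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["samples"] = [dataclasses.asdict(s) for s in config.samples]
    d["detection"]["sigma_factors"] = list(config.detection.sigma_factors)
    return d


def default_config_yaml() -> str:
    """The full config with every default spelled out, as YAML text."""
    cfg = ExperimentConfig(
        pixel_size_um=4.0,
        seed=0,
        samples=(
            SampleSpec(
                sample_id="control_01",
                group="control",
                files={"edu": "control_01_edu.tif", "protein": "control_01_protein.tif"},
            ),
        ),
    )
    return yaml.safe_dump(config_to_dict(cfg), sort_keys=False)


def config_hash(config: ExperimentConfig) -> str:
    """Stable hash of the full configuration, for provenance records."""
    canon = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
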