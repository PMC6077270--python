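"""Ground-truthed synthetic two-channel section images.

The simulator emulates the statistical structure the quantification method
assumes about an EdU / immunofluorescence section scan:

* a single connected, blob-shaped *proliferating region* inside the frame
  (a smoothed union of overlapping disks);
* EdU-positive cells as a homogeneous Poisson point process with one
  intensity (cells/mm²) inside the region and another outside;
* protein-positive cells likewise, with their own pair of intensities, so a
  target can be concentrated inside (Akt-like) or outside (HIF-like) the
  region;
* each cell rendered as an isotropic Gaussian spot on a constant background,
  with optional photon (Poisson) noise and additive Gaussian read noise.

Defaults describe a low-magnification whole-section scan: a 3.1 x 3.1 mm
field at 4 µm/pixel with a proliferating region covering roughly 40%
of the frame and a few hundred positive cells per mm². All randomness flows
through ``numpy.random.Generator``; identical (scenario, seed) pairs
reproduce identical arrays bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage as ndi

from .errors import GeometryError, ValidationError
from .types import AreaMask, FluorescenceSection

__all__ = [
    "RegionGeometry",
    "NoiseModel",
    "SimulationScenario",
    "GroundTruth",
    "SimulatedExperiment",
    "sample_region_mask",
    "sample_cells",
    "thin_min_separation",
    "render_section",
    "generate_experiment",
    "section_rng",
    "scenario_to_yaml",
    "scenario_from_yaml",
]


@dataclass(frozen=True)
class RegionGeometry:
    """Parameters of the proliferating-region shape.

    The region is the union of ``n_blobs`` disks placed so that each new
    disk overlaps an earlier one (guaranteeing connectivity), smoothed with
    a Gaussian of ``smoothing_sigma_px`` and re-thresholded at 0.5.
    """

    n_blobs: int = 4
    blob_radius_range_px: tuple[float, float] = (130.0, 210.0)
    smoothing_sigma_px: float = 18.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian read noise, optionally preceded by photon noise."""

    gaussian_sigma: float = 50.0
    poisson: bool = False


@dataclass(frozen=True)
class SimulationScenario:
    """Full parameterization of one simulated section.

    Cell intensities ``lambda_*`` are in cells/mm²; ``_in`` applies inside
    the proliferating region, ``_out`` outside it. Intensity units are
    arbitrary but written to disk as 16-bit counts, so amplitude and
    background should stay within [0, 65535].
    """

    image_height_px: int = 768
    image_width_px: int = 768
    pixel_size_um: float = 4.0
    region_geometry: RegionGeometry = field(default_factory=RegionGeometry)
    lambda_edu_in: float = 250.0
    lambda_edu_out: float = 5.0
    lambda_prot_in: float = 250.0
    lambda_prot_out: float = 12.0
    psf_sigma_px: float = 1.5
    spot_amplitude: float = 2000.0
    background_level: float = 200.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px < 8 or self.image_width_px < 8:
            raise ValidationError("image must be at least 8x8 px")
        if not (self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be > 0")
        for name in ("lambda_edu_in", "lambda_edu_out", "lambda_prot_in", "lambda_prot_out"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (self.psf_sigma_px > 0):
            raise ValidationError("psf_sigma_px must be > 0")
        lo, hi = self.region_geometry.blob_radius_range_px
        if not (0 < lo <= hi):
            raise ValidationError("blob radius range must satisfy 0 < lo <= hi")
        if 2 * hi > min(self.image_height_px, self.image_width_px):
            raise GeometryError(
                "largest blob diameter exceeds the image's short side"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height_px, self.image_width_px)


@dataclass
class GroundTruth:
    """Everything the simulator knows about one generated section."""

    sample_id: str
    region_mask: np.ndarray  # bool, the true proliferating region
    edu_cells: np.ndarray  # (n, 2) float (row, col)
    prot_cells: np.ndarray
    counts: dict  # {"edu": {"in": n, "out": n}, "protein": {...}}
    scenario: SimulationScenario

    def __post_init__(self):
        h, w = self.region_mask.shape
        for pts in (self.edu_cells, self.prot_cells):
            if len(pts) and (
                pts[:, 0].min() < -0.5
                or pts[:, 0].max() > h - 0.5
                or pts[:, 1].min() < -0.5
                or pts[:, 1].max() > w - 0.5
            ):
                raise ValidationError("ground-truth cell outside image bounds")
        assert self.counts["edu"]["in"] + self.counts["edu"]["out"] == len(self.edu_cells)
        assert self.counts["protein"]["in"] + self.counts["protein"]["out"] == len(self.prot_cells)


@dataclass
class SimulatedExperiment:
    """A control + treated two-group dataset with per-section ground truth.

    ``true_percent_change`` maps ``(channel, compartment)`` to the
    generator's 100 * (1 - lambda_treated / lambda_control), or ``None``
    where the control intensity is zero (undefined change).
    """

    sections: list[FluorescenceSection]
    truths: list[GroundTruth]
    true_percent_change: dict[tuple[str, str], float | None]
    master_seed: int


def section_rng(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-section generator.

    Sub-seeds mix ``(master_seed, index)`` through ``numpy.random.SeedSequence``,
    which is stable across platforms and releases, so a dataset is fully
    reproducible from its master seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def _rasterize_disks(shape, centers, radii) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    h, w = shape
    for (cr, cc), r in zip(centers, radii):
        r0 = max(int(np.floor(cr - r)), 0)
        r1 = min(int(np.ceil(cr + r)) + 1, h)
        c0 = max(int(np.floor(cc - r)), 0)
        c1 = min(int(np.ceil(cc + r)) + 1, w)
        rows = np.arange(r0, r1)[:, None] - cr
        cols = np.arange(c0, c1)[None, :] - cc
        out[r0:r1, c0:c1] |= rows**2 + cols**2 <= r * r
    return out


def sample_region_mask(
    scenario: SimulationScenario,
    rng: np.random.Generator,
    max_redraws: int = 100,
    min_fraction: float = 0.05,
    max_fraction: float = 0.80,
) -> AreaMask:
    """Draw one connected blob-shaped proliferating region.

    Disk centers are chained: the first is uniform in the subframe where its
    disk fits entirely inside the image; each later disk is placed at a
    center-to-center distance below the sum of radii from a randomly chosen
    earlier disk, so the raw union is connected. Geometry is redrawn until
    the smoothed, re-thresholded mask is a single connected component whose
    area fraction lies in [min_fraction, max_fraction].
    """
    geom = scenario.region_geometry
    h, w = scenario.shape
    lo, hi = geom.blob_radius_range_px
    for _ in range(max_redraws):
        radii = rng.uniform(lo, hi, geom.n_blobs)
        centers: list[tuple[float, float]] = []
        for i, r in enumerate(radii):
            if i == 0:
                cr = rng.uniform(r, h - r)
                cc = rng.uniform(r, w - r)
            else:
                j = int(rng.integers(0, i))
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0.3, 0.9) * (radii[j] + r)
                cr = float(np.clip(centers[j][0] + dist * np.sin(ang), r, h - r))
                cc = float(np.clip(centers[j][1] + dist * np.cos(ang), r, w - r))
            centers.append((float(cr), float(cc)))
        union = _rasterize_disks((h, w), centers, radii)
        smooth = ndi.gaussian_filter(union.astype(np.float32), geom.smoothing_sigma_px)
        mask = smooth > 0.5
        frac = mask.mean()
        if not (min_fraction <= frac <= max_fraction):
            continue
        _, n_comp = ndi.label(mask)
        if n_comp != 1:
            continue
        return AreaMask(
            mask,
            "proliferating",
            provenance={
                "source": "synthetic",
                "n_blobs": geom.n_blobs,
                "blob_radius_range_px": list(geom.blob_radius_range_px),
                "smoothing_sigma_px": geom.smoothing_sigma_px,
                "area_fraction": float(frac),
            },
        )
    raise GeometryError(
        f"could not draw a region with area fraction in "
        f"[{min_fraction}, {max_fraction}] after {max_redraws} attempts"
    )


def sample_cells(
    mask: np.ndarray | AreaMask,
    lambda_in: float,
    lambda_out: float,
    pixel_size_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homogeneous Poisson cells per compartment; returns (n, 2) (row, col).

    Counts are Poisson(lambda * compartment area in mm²); positions are
    uniform over the compartment (a uniformly chosen pixel plus uniform
    sub-pixel jitter). Inside-region points come first in the output.
    """
    if lambda_in < 0 or lambda_out < 0:
        raise ValidationError("cell intensities must be >= 0")
    grid = mask.grid if isinstance(mask, AreaMask) else np.asarray(mask, bool)
    px_mm2 = (pixel_size_um / 1000.0) ** 2

    def _draw(compartment: np.ndarray, lam: float) -> np.ndarray:
        n_px = int(compartment.sum())
        area = n_px * px_mm2
        n = int(rng.poisson(lam * area)) if lam > 0 and n_px > 0 else 0
        if n == 0:
            return np.empty((0, 2))
        flat = np.flatnonzero(compartment)
        idx = flat[rng.integers(0, n_px, n)]
        rows, cols = np.unravel_index(idx, compartment.shape)
        jitter = rng.uniform(-0.5, 0.5, (n, 2))
        return np.column_stack([rows, cols]).astype(float) + jitter

    inside = _draw(grid, lambda_in)
    outside = _draw(~grid, lambda_out)
    return np.concatenate([inside, outside], axis=0)


def thin_min_separation(points: np.ndarray, min_sep: float) -> np.ndarray:
    """Matérn-style hard-core thinning: greedily keep points at least
    ``min_sep`` apart (first-come order). Used to build well-separated
    scenes for resolution-limited detection checks."""
    pts = np.asarray(points, float).reshape(-1, 2)
    kept: list[np.ndarray] = []
    for p in pts:
        if all(np.hypot(*(p - q)) >= min_sep for q in kept):
            kept.append(p)
    return np.array(kept).reshape(-1, 2)


def _render_channel(
    shape: tuple[int, int],
    points: np.ndarray,
    amplitude: float,
    sigma: float,
    background: float,
) -> np.ndarray:
    img = np.full(shape, float(background))
    h, w = shape
    half = int(np.ceil(4.0 * sigma))
    for row, col in np.asarray(points, float).reshape(-1, 2):
        r0 = max(int(np.floor(row)) - half, 0)
        r1 = min(int(np.ceil(row)) + half + 1, h)
        c0 = max(int(np.floor(col)) - half, 0)
        c1 = min(int(np.ceil(col)) + half + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        dr = np.arange(r0, r1)[:, None] - row
        dc = np.arange(c0, c1)[None, :] - col
        img[r0:r1, c0:c1] += amplitude * np.exp(-(dr**2 + dc**2) / (2.0 * sigma**2))
    return img


def render_section(
    mask: AreaMask | None,
    edu_cells: np.ndarray,
    prot_cells: np.ndarray,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    sample_id: str = "synthetic",
    group_label: str | None = None,
    target_name: str | None = None,
) -> FluorescenceSection:
    """Render cell point sets into a two-channel section image.

    Each cell becomes an isotropic Gaussian spot (``spot_amplitude``,
    ``psf_sigma_px``) on ``background_level``. If the noise model asks for
    photon noise the noiseless image is Poisson-resampled pixelwise, then
    Gaussian read noise is added; intensities are clipped at zero. The
    ``mask`` argument is accepted for provenance symmetry but not used in
    rendering. Noise order is fixed (EdU channel first) so a given rng state
    yields identical images.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    noise = scenario.noise_model
    channels = {}
    for role, pts in (("edu", edu_cells), ("protein", prot_cells)):
        img = _render_channel(
            scenario.shape, pts, scenario.spot_amplitude,
            scenario.psf_sigma_px, scenario.background_level,
        )
        if noise.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if noise.gaussian_sigma > 0:
            img = img + rng.normal(0.0, noise.gaussian_sigma, scenario.shape)
        channels[role] = np.clip(img, 0.0, None)
    return FluorescenceSection(
        sample_id=sample_id,
        channels=channels,
        pixel_size_um=scenario.pixel_size_um,
        group_label=group_label,
        target_name=target_name,
    )


def _true_change(lam_c: float, lam_t: float) -> float | None:
    if lam_c == 0:
        return None
    return 100.0 * (1.0 - lam_t / lam_c)


def simulate_section(
    scenario: SimulationScenario,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
    group_label: str | None = None,
    target_name: str | None = None,
) -> tuple[FluorescenceSection, GroundTruth]:
    """Draw region, cells and rendered image for one section.

    Consumes the rng in a fixed order (region, EdU cells, protein cells,
    noise), which is the package's determinism contract.
    """
    mask = sample_region_mask(scenario, rng)
    edu = sample_cells(
        mask, scenario.lambda_edu_in, scenario.lambda_edu_out,
        scenario.pixel_size_um, rng,
    )
    prot = sample_cells(
        mask, scenario.lambda_prot_in, scenario.lambda_prot_out,
        scenario.pixel_size_um, rng,
    )
    section = render_section(
        mask, edu, prot, scenario, rng,
        sample_id=sample_id, group_label=group_label, target_name=target_name,
    )
    grid = mask.grid

    def _split(pts):
        if len(pts) == 0:
            return 0, 0
        rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, grid.shape[0] - 1)
        cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, grid.shape[1] - 1)
        inside = int(grid[rows, cols].sum())
        return inside, len(pts) - inside

    e_in, e_out = _split(edu)
    p_in, p_out = _split(prot)
    truth = GroundTruth(
        sample_id=sample_id,
        region_mask=grid,
        edu_cells=edu,
        prot_cells=prot,
        counts={"edu": {"in": e_in, "out": e_out}, "protein": {"in": p_in, "out": p_out}},
        scenario=scenario,
    )
    return section, truth


def generate_experiment(
    control_scenario: SimulationScenario,
    treated_scenario: SimulationScenario,
    n_per_group: int,
    seed: int,
    target_name: str | None = None,
) -> SimulatedExperiment:
    """Generate a two-group dataset of 2 x n_per_group sections.

    Section i of each group uses the deterministic sub-seed
    ``SeedSequence([seed, index])`` with control sections at indices
    ``0..n-1`` and treated at ``n..2n-1``, so the dataset is byte-identical
    across runs and platforms for a fixed master seed.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    sections: list[FluorescenceSection] = []
    truths: list[GroundTruth] = []
    for g, (label, scen) in enumerate(
        (("control", control_scenario), ("treated", treated_scenario))
    ):
        for i in range(n_per_group):
            idx = g * n_per_group + i
            sid = f"{label}_{i + 1:02d}"
            rng = section_rng(seed, idx)
            section, truth = simulate_section(
                scen, rng, sample_id=sid, group_label=label, target_name=target_name
            )
            sections.append(section)
            truths.append(truth)
    change = {
        ("edu", "in"): _true_change(control_scenario.lambda_edu_in, treated_scenario.lambda_edu_in),
        ("edu", "out"): _true_change(control_scenario.lambda_edu_out, treated_scenario.lambda_edu_out),
        ("protein", "in"): _true_change(control_scenario.lambda_prot_in, treated_scenario.lambda_prot_in),
        ("protein", "out"): _true_change(control_scenario.lambda_prot_out, treated_scenario.lambda_prot_out),
    }
    return SimulatedExperiment(
        sections=sections,
        truths=truths,
        true_percent_change=change,
        master_seed=int(seed),
    )


def treated_from_control(
    control: SimulationScenario, reduction_pct: float
) -> SimulationScenario:
    """Treated scenario with in-region EdU and protein intensities reduced
    by ``reduction_pct`` percent (out-of-region intensities unchanged)."""
    f = 1.0 - reduction_pct / 100.0
    if f < 0:
        raise ValidationError("reduction cannot exceed 100%")
    return replace(
        control,
        lambda_edu_in=control.lambda_edu_in * f,
        lambda_prot_in=control.lambda_prot_in * f,
    )


# ---------------------------------------------------------------------------
# serialization

def scenario_to_yaml(scenario: SimulationScenario, path) -> None:
    d = asdict(scenario)
    d["region_geometry"]["blob_radius_range_px"] = list(
        d["region_geometry"]["blob_radius_range_px"]
    )
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def scenario_from_yaml(path) -> SimulationScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        geom = d.pop("region_geometry", {})
        if "blob_radius_range_px" in geom:
            geom["blob_radius_range_px"] = tuple(geom["blob_radius_range_px"])
        noise = d.pop("noise_model", {})
        return SimulationScenario(
            region_geometry=RegionGeometry(**geom),
            noise_model=NoiseModel(**noise),
            **d,
        )
    except TypeError as exc:
        raise ValidationError(f"bad scenario file {path}: {exc}") from exc


def mask_to_rle(mask: np.ndarray) -> str:
    """Run-length encode a boolean mask (row-major, starting with the run
    length of zeros) into a compact string for JSON ground-truth files."""
    flat = np.asarray(mask, bool).ravel()
    if flat.size == 0:
        return ""
    edges = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds)
    if flat[0]:  # encoding starts with a zero-run by convention
        runs = np.concatenate([[0], runs])
    return " ".join(str(int(r)) for r in runs)


def rle_to_mask(rle: str, shape: tuple[int, int]) -> np.ndarray:
    runs = [int(tok) for tok in rle.split()] if rle else []
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


def ground_truth_to_json(truth: GroundTruth, path) -> None:
    d = {
        "sample_id": truth.sample_id,
        "shape": list(truth.region_mask.shape),
        "region_mask_rle": mask_to_rle(truth.region_mask),
        "edu_cells": np.round(truth.edu_cells, 4).tolist(),
        "prot_cells": np.round(truth.prot_cells, 4).tolist(),
        "counts": truth.counts,
        "scenario": asdict(truth.scenario),
    }
    with open(path, "w") as fh:
        json.dump(d, fh)
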