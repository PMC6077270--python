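"""End-to-end orchestration of the quantification procedure.

Stage order mirrors the bench procedure: segment each section's
proliferating area from its EdU channel; detect positive cells in both
channels; call the protein's compartment from the pooled control sections
(a treated group with strong target knockdown has too few cells for a
stable call); sample k circles in the relevant compartment of every
section — the proliferating area for the EdU readout, the called
compartment for the protein readout; convert circle counts to densities;
and compare group means as a percent change.

Every stage writes its artifacts under the output directory and the whole
run is deterministic given the config (ROI seeds derive from the master
seed and the sample index), so a rerun reproduces every file byte for
byte. Stages can equally be run one at a time via the CLI; the composition
yields identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .detection import detect_positive_cells
from .errors import EduQuantError, StageError
from .io import (
    ExperimentConfig,
    config_hash,
    config_to_dict,
    detections_from_csv,
    detections_to_csv,
    read_mask,
    read_section,
    rois_from_csv,
    rois_to_csv,
    write_mask,
)
from .localization import classify_compartment, compute_overlap_fraction, mask_overlap_fraction
from .quantify import ExperimentReport, compare_groups, estimate_density, summarize_experiment
from .roi import sample_circles
from .segmentation import derive_compartment_masks, detect_tissue, segment_proliferating_area
from .types import AreaMask, CellDetectionSet, CompartmentCall, FluorescenceSection

logger = logging.getLogger("eduquant")

__all__ = [
    "load_sections",
    "stage_segment",
    "stage_detect",
    "stage_classify",
    "stage_sample",
    "stage_quantify",
    "stage_compare",
    "run_pipeline",
]

_CHANNEL_SEED_CODE = {"edu": 0, "protein": 1}


def _wrap(stage: str, sample_id: str | None):
    def decorator(fn):
        try:
            return fn()
        except StageError:
            raise
        except EduQuantError as exc:
            raise StageError(stage, sample_id, exc) from exc

    return decorator


def load_sections(config: ExperimentConfig) -> list[FluorescenceSection]:
    sections = []
    for spec in config.samples:
        if spec.channel_index:
            paths = next(iter(spec.files.values()))
        else:
            paths = spec.files
        sections.append(
            read_section(
                paths,
                pixel_size_um=config.pixel_size_um,
                sample_id=spec.sample_id,
                group_label=spec.group,
                target_name=config.target_name or None,
                channel_index=spec.channel_index,
            )
        )
    return sections


def _masks_dir(output_dir) -> Path:
    d = Path(output_dir) / "masks"
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_segment(
    config: ExperimentConfig,
    output_dir,
    sections: list[FluorescenceSection] | None = None,
    detections: dict[tuple[str, str], CellDetectionSet] | None = None,
) -> dict[str, tuple[AreaMask, AreaMask]]:
    """Per-section (proliferating, non_proliferating) masks, written as
    0/255 TIFFs under ``masks/``.

    When the smoothing scale is automatic, the EdU spot count steers it;
    counts come from ``detections`` when available and are recomputed with
    the config's detection parameters otherwise, so staged and end-to-end
    runs produce identical masks.
    """
    sections = sections if sections is not None else load_sections(config)
    masks_dir = _masks_dir(output_dir)
    out: dict[str, tuple[AreaMask, AreaMask]] = {}
    for section in sections:
        def _run(section=section):
            tissue = (
                detect_tissue(section, config.tissue.smooth_sigma_px, config.tissue.threshold)
                if config.tissue.enabled
                else None
            )
            n_spots = None
            if config.segmentation.smooth_sigma_px is None:
                if detections is not None:
                    n_spots = len(detections[(section.sample_id, "edu")])
                else:
                    n_spots = len(
                        detect_positive_cells(section, "edu", config.detection)
                    )
            prol = segment_proliferating_area(
                section, config.segmentation, n_spots=n_spots
            )
            prol, non = derive_compartment_masks(prol, tissue)
            write_mask(prol, masks_dir / f"{section.sample_id}_proliferating.tif")
            write_mask(non, masks_dir / f"{section.sample_id}_non_proliferating.tif")
            logger.info(
                "segment %s: proliferating area %d px (%.1f%% of frame)",
                section.sample_id, prol.area_px,
                100.0 * prol.area_px / prol.grid.size,
            )
            return prol, non

        out[section.sample_id] = _wrap("segment", section.sample_id)(_run)
    return out


def _read_masks(config: ExperimentConfig, output_dir) -> dict[str, tuple[AreaMask, AreaMask]]:
    masks_dir = Path(output_dir) / "masks"
    out = {}
    for spec in config.samples:
        prol = read_mask(masks_dir / f"{spec.sample_id}_proliferating.tif")
        non = read_mask(masks_dir / f"{spec.sample_id}_non_proliferating.tif")
        out[spec.sample_id] = (prol, non)
    return out


def stage_detect(
    config: ExperimentConfig,
    output_dir,
    sections: list[FluorescenceSection] | None = None,
) -> dict[tuple[str, str], CellDetectionSet]:
    """Detect positive cells in both channels of every section; writes
    ``detections.csv``."""
    sections = sections if sections is not None else load_sections(config)
    out: dict[tuple[str, str], CellDetectionSet] = {}
    for section in sections:
        for role in ("edu", "protein"):
            def _run(section=section, role=role):
                det = detect_positive_cells(section, role, config.detection)
                logger.info("detect %s/%s: %d cells", section.sample_id, role, len(det))
                return det

            out[(section.sample_id, role)] = _wrap("detect", section.sample_id)(_run)
    detections_to_csv(list(out.values()), Path(output_dir) / "detections.csv")
    return out


def stage_classify(
    config: ExperimentConfig,
    output_dir,
    masks: dict[str, tuple[AreaMask, AreaMask]] | None = None,
    detections: dict[tuple[str, str], CellDetectionSet] | None = None,
    sections: list[FluorescenceSection] | None = None,
) -> CompartmentCall:
    """Call the target protein's compartment from the control group.

    With the default cell-count metric, protein detections of all control
    sections are pooled against their own proliferating masks; the 'area'
    metric instead segments the protein channel with the same recipe and
    pools mask areas. Writes ``calls.csv``.
    """
    masks = masks if masks is not None else _read_masks(config, output_dir)
    if detections is None:
        det_list = detections_from_csv(Path(output_dir) / "detections.csv")
        detections = {(d.section_id, d.channel_role): d for d in det_list}
    control_ids = [s.sample_id for s in config.samples if s.group == "control"]

    def _run():
        loc = config.localization
        if loc.metric == "area":
            if sections is None:
                secs = load_sections(config)
            else:
                secs = sections
            by_id = {s.sample_id: s for s in secs}
            inter = total = 0
            for sid in control_ids:
                pmask = segment_proliferating_area(
                    _protein_as_edu(by_id[sid]), config.segmentation
                )
                frac = mask_overlap_fraction(pmask, masks[sid][0])
                inter += frac * pmask.area_px
                total += pmask.area_px
            f = inter / total
            n_cells = 0
        else:
            inside = total = 0
            for sid in control_ids:
                det = detections.get((sid, "protein"))
                if det is None or len(det) == 0:
                    continue
                f_s = compute_overlap_fraction(det, masks[sid][0])
                inside += f_s * len(det)
                total += len(det)
            if total == 0:
                from .errors import UndefinedFractionError

                raise UndefinedFractionError(
                    "no protein cells detected in any control section"
                )
            f = inside / total
            n_cells = total
        call = classify_compartment(
            f, loc.low, loc.high,
            target_name=config.target_name or "target", n_cells=int(n_cells),
        )
        logger.info(
            "classify %s: overlap fraction %.3f over %d cells -> %s",
            call.target_name, call.overlap_fraction, call.n_cells, call.call,
        )
        return call

    call = _wrap("classify", None)(_run)
    report = summarize_experiment([call], [], [])
    report.calls.to_csv(
        Path(output_dir) / "calls.csv", index=False, float_format="%.10g",
        lineterminator="\n",
    )
    return call


def _protein_as_edu(section: FluorescenceSection) -> FluorescenceSection:
    """View the protein channel through the region segmenter (which reads
    the 'edu' role)."""
    return FluorescenceSection(
        sample_id=section.sample_id,
        channels={"edu": section.channel("protein")},
        pixel_size_um=section.pixel_size_um,
        group_label=section.group_label,
        target_name=section.target_name,
    )


def _resolve_compartment(call: CompartmentCall, config: ExperimentConfig) -> str:
    if call.call != "ambiguous":
        return call.call
    forced = config.localization.force_compartment
    if forced in ("proliferating", "non_proliferating"):
        logger.warning(
            "ambiguous compartment call (f=%.3f) overridden to '%s'",
            call.overlap_fraction, forced,
        )
        return forced
    raise StageError(
        "sample_rois", None,
        EduQuantError(
            f"compartment call is ambiguous (f={call.overlap_fraction:.3f}); "
            "set localization.force_compartment to proceed"
        ),
    )


def stage_sample(
    config: ExperimentConfig,
    output_dir,
    masks: dict[str, tuple[AreaMask, AreaMask]] | None = None,
    call: CompartmentCall | None = None,
) -> dict[tuple[str, str], list]:
    """Sample ROIs: EdU circles in each section's proliferating mask,
    protein circles in the called compartment. Writes ``rois.csv``.

    The per-section, per-channel seed is ``SeedSequence([master_seed,
    sample_index, channel_code])``, so single-stage runs and full runs
    place identical circles.
    """
    masks = masks if masks is not None else _read_masks(config, output_dir)
    if call is None:
        import pandas as pd

        df = pd.read_csv(Path(output_dir) / "calls.csv")
        row = df.iloc[0]
        call = CompartmentCall(
            target_name=str(row["target_name"]),
            overlap_fraction=float(row["overlap_fraction"]),
            call=str(row["call"]),
            low=config.localization.low,
            high=config.localization.high,
            n_cells=int(row["n_cells"]),
        )
    protein_compartment = _resolve_compartment(call, config)
    samp = config.sampling
    out: dict[tuple[str, str], list] = {}
    for idx, spec in enumerate(config.samples):
        prol, non = masks[spec.sample_id]
        for role, mask in (
            ("edu", prol),
            ("protein", prol if protein_compartment == "proliferating" else non),
        ):
            def _run(idx=idx, spec=spec, role=role, mask=mask):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed, idx, _CHANNEL_SEED_CODE[role]]
                    )
                )
                rois = sample_circles(
                    mask, k=samp.k, radius_px=samp.radius_px, rng=rng,
                    no_overlap=samp.no_overlap, area_fraction=samp.area_fraction,
                )
                logger.info(
                    "sample %s/%s: %d circles of radius %.1f px in %s",
                    spec.sample_id, role, len(rois), rois[0].radius_px,
                    rois[0].compartment,
                )
                return rois

            out[(spec.sample_id, role)] = _wrap("sample_rois", spec.sample_id)(_run)
    rois_to_csv(out, Path(output_dir) / "rois.csv")
    return out


def stage_quantify(
    config: ExperimentConfig,
    output_dir,
    detections: dict[tuple[str, str], CellDetectionSet] | None = None,
    rois: dict[tuple[str, str], list] | None = None,
):
    """Per-section densities for both readouts; returns the estimates and
    writes the per-sample table to ``densities.csv``."""
    if detections is None:
        det_list = detections_from_csv(Path(output_dir) / "detections.csv")
        detections = {(d.section_id, d.channel_role): d for d in det_list}
    rois = rois if rois is not None else rois_from_csv(Path(output_dir) / "rois.csv")
    groups = {s.sample_id: s.group for s in config.samples}
    densities = []
    for (sid, role), roi_list in sorted(rois.items()):
        def _run(sid=sid, role=role, roi_list=roi_list):
            det = detections.get(
                (sid, role),
                CellDetectionSet(sid, role, np.empty((0, 2)), np.empty(0)),
            )
            d = estimate_density(
                det, roi_list, config.pixel_size_um,
                sample_id=sid, channel_role=role,
            )
            logger.info(
                "density %s/%s: counts %s -> %.1f cells/mm^2 in %s",
                sid, role, d.counts, d.mean_density, d.compartment,
            )
            return d

        densities.append(_wrap("quantify", sid)(_run))
    report = summarize_experiment([], densities, [], groups=groups)
    report.samples.to_csv(
        Path(output_dir) / "densities.csv", index=False, float_format="%.10g",
        lineterminator="\n",
    )
    return densities


def stage_compare(
    config: ExperimentConfig,
    output_dir,
    densities=None,
):
    """Control-vs-treated percent change per channel; writes
    ``comparisons.csv``."""
    if densities is None:
        detections = {
            (d.section_id, d.channel_role): d
            for d in detections_from_csv(Path(output_dir) / "detections.csv")
        }
        densities = stage_quantify(config, output_dir, detections=detections)
    groups = {s.sample_id: s.group for s in config.samples}
    comparisons = []
    for role in ("edu", "protein"):
        def _run(role=role):
            control = [
                d for d in densities
                if d.channel_role == role and groups[d.sample_id] == "control"
            ]
            treated = [
                d for d in densities
                if d.channel_role == role and groups[d.sample_id] == "treated"
            ]
            comp = compare_groups(
                control, treated,
                n_boot=config.quantification.n_boot,
                seed=config.seed,
            )
            logger.info(
                "compare %s (%s): control %.1f vs treated %.1f cells/mm^2 "
                "-> %.1f%% change",
                role, comp.compartment, comp.control_mean, comp.treated_mean,
                comp.percent_change,
            )
            return comp

        comparisons.append(_wrap("compare", None)(_run))
    report = summarize_experiment([], [], comparisons)
    report.comparisons.to_csv(
        Path(output_dir) / "comparisons.csv", index=False, float_format="%.10g",
        lineterminator="\n",
    )
    return comparisons


def run_pipeline(config: ExperimentConfig, output_dir) -> ExperimentReport:
    """Execute every stage and return the assembled report.

    Artifacts (masks, detections, ROIs, density/call/comparison tables, a
    provenance record and a run log) land under ``output_dir``; rerunning
    with the same config and seed regenerates each byte-identically.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log_path = output_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("eduquant %s, config hash %s, seed %d",
                    __version__, config_hash(config), config.seed)
        sections = load_sections(config)
        detections = stage_detect(config, output_dir, sections)
        masks = stage_segment(config, output_dir, sections, detections)
        call = stage_classify(config, output_dir, masks, detections, sections)
        rois = stage_sample(config, output_dir, masks, call)
        densities = stage_quantify(config, output_dir, detections, rois)
        comparisons = stage_compare(config, output_dir, densities)
        groups = {s.sample_id: s.group for s in config.samples}
        report = summarize_experiment([call], densities, comparisons, groups=groups)
        report.provenance = {
            "package": "eduquant",
            "version": __version__,
            "config_hash": config_hash(config),
            "seed": config.seed,
            "config": config_to_dict(config),
        }
        with open(output_dir / "provenance.json", "w") as fh:
            json.dump(report.provenance, fh, indent=1, default=str, sort_keys=True)
        report.to_csv(output_dir)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def analyze_experiment(
    sections: list[FluorescenceSection],
    seed: int,
    segmentation=None,
    detection=None,
    localization=None,
    sampling=None,
) -> tuple[CompartmentCall, list, list]:
    """In-memory end-to-end analysis of a two-group section list.

    Runs the same stage functions and per-section ROI seed derivation as
    :func:`run_pipeline` but keeps everything in memory (no artifacts),
    which suits simulation studies that analyze hundreds of generated
    experiments. Returns (compartment call, density estimates, group
    comparisons).
    """
    from .detection import DetectionParams
    from .io import LocalizationConfig, SamplingConfig
    from .localization import classify_compartment, compute_overlap_fraction
    from .segmentation import SegmentationParams

    seg = segmentation or SegmentationParams()
    det_params = detection or DetectionParams()
    loc = localization or LocalizationConfig()
    samp = sampling or SamplingConfig()

    detections = {
        (s.sample_id, role): detect_positive_cells(s, role, det_params)
        for s in sections
        for role in ("edu", "protein")
    }
    masks = {}
    for s in sections:
        prol = segment_proliferating_area(
            s, seg, n_spots=len(detections[(s.sample_id, "edu")])
        )
        masks[s.sample_id] = derive_compartment_masks(prol)

    inside = total = 0
    for s in sections:
        if s.group_label != "control":
            continue
        det = detections[(s.sample_id, "protein")]
        if len(det) == 0:
            continue
        f = compute_overlap_fraction(det, masks[s.sample_id][0])
        inside += f * len(det)
        total += len(det)
    if total == 0:
        from .errors import UndefinedFractionError

        raise UndefinedFractionError("no protein cells detected in controls")
    call = classify_compartment(
        inside / total, loc.low, loc.high,
        target_name=sections[0].target_name or "target", n_cells=int(total),
    )
    protein_compartment = call.call
    if protein_compartment == "ambiguous":
        forced = loc.force_compartment
        if forced not in ("proliferating", "non_proliferating"):
            raise StageError(
                "sample_rois", None,
                EduQuantError("ambiguous compartment call"),
            )
        protein_compartment = forced

    densities = []
    for idx, s in enumerate(sections):
        prol, non = masks[s.sample_id]
        for role, mask in (
            ("edu", prol),
            ("protein", prol if protein_compartment == "proliferating" else non),
        ):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, idx, _CHANNEL_SEED_CODE[role]])
            )
            rois = sample_circles(
                mask, k=samp.k, radius_px=samp.radius_px, rng=rng,
                no_overlap=samp.no_overlap, area_fraction=samp.area_fraction,
            )
            densities.append(
                estimate_density(
                    detections[(s.sample_id, role)], rois, s.pixel_size_um,
                    sample_id=s.sample_id, channel_role=role,
                )
            )
    groups = {s.sample_id: s.group_label for s in sections}
    comparisons = []
    for role in ("edu", "protein"):
        control = [d for d in densities if d.channel_role == role and groups[d.sample_id] == "control"]
        treated = [d for d in densities if d.channel_role == role and groups[d.sample_id] == "treated"]
        comparisons.append(compare_groups(control, treated))
    return call, densities, comparisons
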