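"""End-to-end pipeline: synthetic scene -> outlines -> features -> statistics.

Sequences the stages with a single serialisable configuration, applies the
cell inclusion filter (cells touching another labelled cell, or whose outline
could not be composed, are excluded with a recorded reason), and writes all
stage outputs plus a reproducibility manifest.  Runs are deterministic for a
fixed config: re-running produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from . import geometry, morphometry, segmentation, stats, synthetic, vasculature
from .segmentation import compose_outline, extract_particles, project_std, select_regions_at
from .synthetic import SceneParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "CellRecord", "apply_inclusion_filter", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; round-trips losslessly through YAML."""

    scene: SceneParams = field(default_factory=SceneParams)
    channel_roles: dict = field(
        default_factory=lambda: {name: i for i, name in enumerate(synthetic.CHANNELS)}
    )
    global_threshold: str = "otsu"
    phansalkar_radius: int = 15
    phansalkar_k: float = 0.25
    phansalkar_r: float = 0.5
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    min_particle_area_um2: float = 3.0
    contact_tolerance_px: int = 1
    wrap_envelope_deg: float = 300.0
    wrap_mural_deg: float = 120.0
    min_mass_fraction: float = 0.5
    class_shell_um: float = 2.0
    pairing_criterion: str = "collinearity"
    onh_xy_um: tuple[float, float] = (0.0, 0.0)
    dorsal_angle_deg: float = 90.0
    umap_n_neighbors: int = 15
    hdbscan_min_samples: int = 3
    hdbscan_min_cluster_size: int = 10
    embed_scale: bool = True
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["scene"] = dataclasses.asdict(self.scene)
        return yaml.safe_dump(_plain(d), sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        scene_d = d.pop("scene", {})
        for key in ("shape", "cell_area_range_um2", "motif_pool", "motifs_per_cell", "class_fractions"):
            if key in scene_d and isinstance(scene_d[key], list):
                scene_d[key] = tuple(scene_d[key])
        cfg = PipelineConfig(scene=SceneParams(**scene_d))
        for k, v in d.items():
            if k == "onh_xy_um":
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class CellRecord:
    """Measured record for one cell, plus inclusion status."""

    cell_id: int
    included: bool
    exclusion_reason: str | None
    metrics: morphometry.ShapeMetrics | None = None
    connection: vasculature.ConnectionClass | None = None
    contacts: list = field(default_factory=list)
    coordinate: geometry.RetinalCoordinate | None = None
    dist_to_vessel_um: float | None = None


def apply_inclusion_filter(
    cell_masks: dict[int, np.ndarray], failed: dict[int, str] | None = None
) -> tuple[list[int], dict[int, str]]:
    """Exclude cells touching another labelled cell (within 1 px) or unsegmentable.

    Returns (included ids, {excluded id: reason}).
    """
    failed = dict(failed or {})
    ids = sorted(cell_masks)
    excluded: dict[int, str] = dict(failed)
    dilated = {
        i: ndi.binary_dilation(cell_masks[i], structure=np.ones((3, 3), bool))
        for i in ids
    }
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1 :]:
            if (dilated[a] & cell_masks[b]).any() or (dilated[b] & cell_masks[a]).any():
                excluded.setdefault(a, "contact with labeled cell")
                excluded.setdefault(b, "contact with labeled cell")
    included = [i for i in ids if i not in excluded]
    return included, excluded


def _segment_cell(stack, truth_cell, cfg: PipelineConfig, pixel_size: float):
    """Outline one cell: crop, std-project, threshold, particles, XOR-compose."""
    nz, nc, ny, nx_ = stack.shape
    px = pixel_size
    minx, miny, maxx, maxy = truth_cell.polygon.bounds
    pad = 12
    j0 = max(int(minx / px) - pad, 0)
    j1 = min(int(maxx / px) + pad, nx_)
    i0 = max(int(miny / px) - pad, 0)
    i1 = min(int(maxy / px) + pad, ny)
    crop = stack[:, cfg.channel_roles["membrane"], i0:i1, j0:j1]
    proj = project_std(crop, pixel_size=px)
    try:
        mask = segmentation.threshold_global(proj, cfg.global_threshold)
    except ValueError as exc:
        return None, (i0, j0), str(exc)
    regions = extract_particles(mask, px, cfg.min_particle_area_um2)
    seed_pt = truth_cell.polygon.representative_point()
    seed_xy = (seed_pt.x / px - j0, seed_pt.y / px - i0)
    selected = select_regions_at(regions, seed_xy)
    if not selected:
        return None, (i0, j0), "outline composition failed: no particle at seed"
    try:
        outline = compose_outline(regions, selected, px)
    except (ValueError, KeyError) as exc:
        return None, (i0, j0), f"outline composition failed: {exc}"
    return outline, (i0, j0), None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic scene and write the results bundle.

    Returns a dict with the in-memory results (records, feature matrix,
    summary, association table, truth) and writes CSV/JSON/TIFF/GraphML
    outputs plus ``manifest.json`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    px = cfg.scene.pixel_size_um

    stack, truth = synthetic.render_flatmount(cfg.scene)
    synthetic.write_stack(outdir / "scene.tif", stack)
    (outdir / "ground_truth.json").write_text(synthetic.truth_to_json(truth))
    annotations = synthetic.generate_annotation_table(truth)
    annotations.to_csv(outdir / "annotations.csv", index=False)

    positions = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in truth.cells],
            "x_um": [c.retina_xy_um[0] for c in truth.cells],
            "y_um": [c.retina_xy_um[1] for c in truth.cells],
            "eye": cfg.scene.eye,
            "onh_x": cfg.onh_xy_um[0],
            "onh_y": cfg.onh_xy_um[1],
            "rim_dist_um": cfg.scene.rim_distance_um,
            "dorsal_angle_deg": cfg.dorsal_angle_deg,
        }
    )
    positions.to_csv(outdir / "positions.csv", index=False)

    # --- segmentation per cell
    ny, nx_ = stack.shape[2], stack.shape[3]
    outlines: dict[int, segmentation.CellOutline] = {}
    offsets: dict[int, tuple[int, int]] = {}
    failures: dict[int, str] = {}
    full_masks: dict[int, np.ndarray] = {}
    for cell in truth.cells:
        outline, (i0, j0), err = _segment_cell(stack, cell, cfg, px)
        if err is not None:
            failures[cell.cell_id] = err
            continue
        outlines[cell.cell_id] = outline
        offsets[cell.cell_id] = (i0, j0)
        full = np.zeros((ny, nx_), bool)
        h, w = outline.mask.shape
        full[i0 : i0 + h, j0 : j0 + w] = outline.mask
        full_masks[cell.cell_id] = full

    included_ids, excluded = apply_inclusion_filter(full_masks, failures)
    for cid, reason in sorted(excluded.items()):
        logger.info("cell %s excluded: %s", cid, reason)

    # --- vessels
    vessel_proj = project_std(stack, cfg.channel_roles["vessel"], px)
    vessel_mask = segmentation.threshold_global(vessel_proj, cfg.global_threshold)
    network = vasculature.skeletonize_vessels(vessel_mask, px)
    vasculature.split_unique_vessels(network, cfg.pairing_criterion)
    vasculature.export_graphml(network, outdir / "vessels.graphml")

    gfap_proj = project_std(stack, cfg.channel_roles["gfap"], px)
    gfap_mask = segmentation.threshold_phansalkar(
        gfap_proj,
        cfg.phansalkar_radius,
        cfg.phansalkar_k,
        cfg.phansalkar_r,
        cfg.phansalkar_p,
        cfg.phansalkar_q,
    )
    membrane_proj = project_std(stack, cfg.channel_roles["membrane"], px)

    records: list[CellRecord] = []
    contact_rows = []
    feature_rows = []
    for cell in truth.cells:
        cid = cell.cell_id
        if cid in excluded:
            records.append(CellRecord(cell_id=cid, included=False, exclusion_reason=excluded[cid]))
            continue
        outline = outlines[cid]
        i0, j0 = offsets[cid]
        h, w = outline.mask.shape
        metrics = morphometry.shape_metrics(
            outline,
            intensity_image=membrane_proj.data[i0 : i0 + h, j0 : j0 + w],
            marker_mask=gfap_mask[i0 : i0 + h, j0 : j0 + w],
        )
        full = full_masks[cid]
        contacts = vasculature.find_contacts(
            full, network, vessel_mask, cfg.contact_tolerance_px, cell_id=cid
        )
        connection = vasculature.classify_connection(
            full,
            network,
            vessel_mask,
            cfg.contact_tolerance_px,
            cfg.wrap_envelope_deg,
            cfg.wrap_mural_deg,
            cfg.min_mass_fraction,
            cfg.class_shell_um,
        )
        cvh_cx = metrics.cvh_centroid[0] + j0 * px
        cvh_cy = metrics.cvh_centroid[1] + i0 * px
        dist = vasculature.distance_to_nearest_vessel((cvh_cx, cvh_cy), vessel_mask, px)
        coord = geometry.harmonize_eye(
            geometry.map_to_sphere(
                cell.retina_xy_um,
                cfg.onh_xy_um,
                cfg.scene.rim_distance_um,
                cfg.dorsal_angle_deg,
                cfg.scene.eye,
                cfg.scene.phi0_deg,
            )
        )
        records.append(
            CellRecord(
                cell_id=cid,
                included=True,
                exclusion_reason=None,
                metrics=metrics,
                connection=connection,
                contacts=contacts,
                coordinate=coord,
                dist_to_vessel_um=dist,
            )
        )
        for ct in contacts:
            contact_rows.append(
                {
                    "cell_id": cid,
                    "vessel_id": ct.vessel_id,
                    "n_pixels": ct.n_pixels,
                    "d_min": ct.d_min,
                    "d_mean": ct.d_mean,
                    "d_max": ct.d_max,
                }
            )
        diam = [c.d_mean for c in contacts]
        feature_rows.append(
            {
                "cell_id": cid,
                "fo_area": metrics.fo_area,
                "fo_perimeter": metrics.fo_perimeter,
                "fo_major_axis": metrics.fo_major_axis,
                "fo_minor_axis": metrics.fo_minor_axis,
                "fo_circularity": metrics.fo_circularity,
                "fo_feret_diameter": metrics.fo_feret_diameter,
                "fo_roundness": metrics.fo_roundness,
                "fo_solidity": metrics.fo_solidity,
                "cvh_area": metrics.cvh_area,
                "cvh_perimeter": metrics.cvh_perimeter,
                "cvh_feret_diameter": metrics.cvh_feret_diameter,
                "latitude_rad": coord.latitude,
                "longitude_rad": coord.longitude,
                "pct_gfap": metrics.marker_pct,
                "dist_cvh_centroid_to_vessel": dist,
                "dist_cvh_centroid_to_fo_com": metrics.centroid_com_distance,
                "mean_vessel_diameter": float(np.mean(diam)) if diam else 0.0,
                "min_vessel_diameter": min((c.d_min for c in contacts), default=0.0),
                "max_vessel_diameter": max((c.d_max for c in contacts), default=0.0),
                "n_unique_vessels": len(contacts),
                "connection_class": connection.label,
            }
        )

    features = pd.DataFrame(feature_rows).set_index("cell_id") if feature_rows else pd.DataFrame()
    if len(features):
        matrix = stats.build_feature_matrix(features)
        matrix.to_csv(outdir / "features.csv", float_format="%.6g")
    else:
        matrix = pd.DataFrame()
    pd.DataFrame(
        contact_rows, columns=["cell_id", "vessel_id", "n_pixels", "d_min", "d_mean", "d_max"]
    ).to_csv(outdir / "contacts.csv", index=False, float_format="%.6g")

    association = stats.motif_structure_probabilities(annotations)
    association.to_csv(outdir / "association.csv", index=False, float_format="%.6g")

    summary = None
    if len(features):
        axon_proj = project_std(stack, cfg.channel_roles["axon"], px)
        try:
            neuron_mask = segmentation.threshold_global(axon_proj, cfg.global_threshold)
        except ValueError:
            neuron_mask = np.zeros((ny, nx_), bool)
        touches_neuron = {
            cid: bool(
                (
                    ndi.binary_dilation(full_masks[cid], iterations=cfg.contact_tolerance_px)
                    & neuron_mask
                ).any()
            )
            for cid in features.index
        }
        pop = features.assign(
            contacts_axon=[touches_neuron[c] for c in features.index],
            contacts_soma=[touches_neuron[c] for c in features.index],
        )
        summary = stats.population_summaries(pop)
        (outdir / "summary.json").write_text(
            json.dumps(dataclasses.asdict(summary), indent=1, sort_keys=True)
        )

    embedding = None
    needed = max(cfg.umap_n_neighbors + 1, cfg.hdbscan_min_cluster_size)
    if len(matrix) >= needed:
        emb, labels, meta = stats.embed_cluster(
            matrix,
            seed=cfg.seed,
            n_neighbors=cfg.umap_n_neighbors,
            min_samples=cfg.hdbscan_min_samples,
            min_cluster_size=cfg.hdbscan_min_cluster_size,
            scale=cfg.embed_scale,
        )
        embedding = pd.DataFrame(
            {"cell_id": matrix.index, "u1": emb[:, 0], "u2": emb[:, 1], "cluster": labels}
        )
        embedding.to_csv(outdir / "embedding.csv", index=False, float_format="%.6g")

    dendrogram = None
    if len(matrix) >= 4:
        try:
            _, order, newick = stats.correlation_dendrogram(matrix)
            (outdir / "dendrogram.nwk").write_text(newick + "\n")
            dendrogram = order
        except ValueError:
            pass

    manifest = {
        "config_hash": cfg.config_hash(),
        "n_cells_generated": len(truth.cells),
        "n_cells_segmented": len(outlines),
        "n_cells_included": len(included_ids),
        "n_unique_vessels_measured": network.n_unique,
        "n_unique_vessels_true": truth.vessels.n_unique,
        "exclusions": {str(k): v for k, v in sorted(excluded.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "config.yaml").write_text(cfg.to_yaml())

    return {
        "records": records,
        "features": features,
        "matrix": matrix,
        "summary": summary,
        "association": association,
        "embedding": embedding,
        "dendrogram": dendrogram,
        "network": network,
        "truth": truth,
        "manifest": manifest,
    }
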