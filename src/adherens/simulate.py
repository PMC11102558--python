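"""Synthetic endothelial-monolayer image generator with known junction truth.

Real cadherin-5 micrographs of confluent HUVEC monolayers show a bright,
ridge-like junctional signal along shared cell borders; inflammatory
stimulation fragments that signal into discontinuous stretches. No imaging
data accompanies the analysis this package reimplements, so this module
simulates the geometry instead: a Voronoi tessellation of minimum-separation
seed points stands in for the confluent monolayer, shared borders are
rasterized into a junction mask, contiguous runs of border pixels are deleted
to a requested global gap fraction (the ground truth for "discontinuity"),
and the surviving junction is rendered as a Gaussian-cross-section ridge on
top of a smooth uneven-illumination field plus pixel noise.

Every quantity a downstream test needs — the tessellation, the pre-gap
junction mask, the gap mask, per-cell gap fractions, border-touching cells —
is recorded in :class:`MonolayerTruth`, and generation is bit-reproducible
from the configuration alone.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .image import ImageChannel, as_uint8, write_channel


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated monolayer image.

    Lengths are in pixels throughout; physical calibration (µm/px) is left to
    the user since it does not affect the discontinuity statistic.

    Attributes
    ----------
    image_size : (height, width), each >= 128.
    n_cells : number of Voronoi seed points (>= 4).
    gap_fraction : requested fraction of junction length removed as gaps,
        in [0, 1).
    junction_width_sigma : Gaussian cross-section sigma of the rendered
        junction ridge, px.
    junction_peak_intensity : ridge peak, 8-bit intensity units.
    noise_sigma : additive Gaussian pixel noise, intensity units.
    illumination_amplitude : peak of the smooth low-frequency background
        field, intensity units. ``peak + amplitude`` must stay <= 255 so the
        render never saturates by construction.
    gap_length_pixels : typical contiguous gap run length, px.
    elongation : anisotropic stretch of the seed geometry along the row axis
        (1.0 = isotropic). Mimics TNF-induced cell elongation; off by default.
    rng_seed : seed for all randomness in the image.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 60
    gap_fraction: float = 0.0
    junction_width_sigma: float = 1.5
    junction_peak_intensity: int = 200
    noise_sigma: float = 5.0
    illumination_amplitude: float = 30.0
    gap_length_pixels: int = 12
    elongation: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 128 or w < 128:
            raise ValueError(f"image_size must be >= 128 in each dimension, got {self.image_size}")
        if self.n_cells < 4:
            raise ValueError(f"n_cells must be >= 4, got {self.n_cells}")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError(f"gap_fraction must lie in [0, 1), got {self.gap_fraction}")
        if self.junction_width_sigma <= 0:
            raise ValueError(f"junction_width_sigma must be positive, got {self.junction_width_sigma}")
        if not 0 <= self.junction_peak_intensity <= 255:
            raise ValueError(
                f"junction_peak_intensity must lie in [0, 255], got {self.junction_peak_intensity}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.illumination_amplitude < 0:
            raise ValueError(f"illumination_amplitude must be >= 0, got {self.illumination_amplitude}")
        if self.junction_peak_intensity + self.illumination_amplitude > 255:
            raise ValueError(
                "junction_peak_intensity + illumination_amplitude must be <= 255 "
                f"(no saturation by construction), got {self.junction_peak_intensity} + "
                f"{self.illumination_amplitude}"
            )
        if self.gap_length_pixels < 1:
            raise ValueError(f"gap_length_pixels must be >= 1, got {self.gap_length_pixels}")
        if self.elongation <= 0:
            raise ValueError(f"elongation must be positive, got {self.elongation}")


@dataclass
class MonolayerTruth:
    """Ground truth of one simulated image.

    ``junction_mask`` is the pre-gap rasterized border network; ``gap_mask``
    is the subset of it deleted before rendering, so the realized global gap
    fraction is ``gap_mask.sum() / junction_mask.sum()``. ``border_cells``
    lists cell IDs whose territory touches the image frame; outline
    extraction downstream excludes those, so truth-based checks should too.
    """

    seed_points: np.ndarray              # (n_cells, 2) float, row/col
    cell_label_map: np.ndarray           # (H, W) int, labels 1..n_cells
    junction_mask: np.ndarray            # (H, W) bool
    gap_mask: np.ndarray                 # (H, W) bool, subset of junction_mask
    per_cell_gap_fraction: dict[int, float]
    border_cells: set[int]
    rng_seed: int

    @property
    def realized_gap_fraction(self) -> float:
        total = int(self.junction_mask.sum())
        return float(self.gap_mask.sum()) / total if total else 0.0

    def interior_cells(self) -> list[int]:
        return sorted(set(int(c) for c in np.unique(self.cell_label_map)) - self.border_cells)

    def scorable_cells(self, guard_band: int = 20, seal_radius: int = 8) -> list[int]:
        """Cells whose *observable* outline is complete and clear of the frame.

        The rendered junction ridge has finite width: two borders closer
        together than roughly twice the ridge's rendered half-width (the
        ``seal_radius``) merge into one. Near the image frame this can seal a
        clipped cell into an apparently closed one, so territory membership
        alone does not predict what outline extraction can see. This method
        reproduces the observable geometry from the truth masks — it dilates
        the junction network by ``seal_radius`` and takes the enclosed faces
        — and keeps cells whose face stays at least ``guard_band`` +
        ``seal_radius`` + 1 pixels from the frame, mirroring the extraction
        side's border policy of excluding outlines within ``guard_band``
        pixels of the frame.
        """
        h, w = self.cell_label_map.shape
        from skimage.morphology import disk

        obs = ndi.binary_dilation(self.junction_mask, structure=disk(seal_radius))
        faces, _ = ndi.label(~obs, structure=ndi.generate_binary_structure(2, 1))
        threshold = guard_band + seal_radius + 1
        kept = []
        for i, seed in enumerate(self.seed_points):
            r, c = int(round(seed[0])), int(round(seed[1]))
            r = min(max(r, 0), h - 1)
            c = min(max(c, 0), w - 1)
            face_id = faces[r, c]
            if face_id == 0:
                continue
            rr, cc = np.nonzero(faces == face_id)
            if min(rr.min(), cc.min(), h - 1 - rr.max(), w - 1 - cc.max()) >= threshold:
                kept.append(i + 1)
        return sorted(set(kept))


def _sample_seed_points(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform seed points with a minimum-separation rejection rule.

    Separation starts at ~0.6 of the mean nearest-neighbor spacing of a
    uniform tessellation and relaxes geometrically if the field is too
    crowded to place all points, keeping generation deterministic and total.
    """
    h, w = config.image_size
    min_sep = 0.6 * np.sqrt(h * w / config.n_cells)
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < config.n_cells:
        cand = rng.uniform([0, 0], [h, w])
        if all(np.hypot(*(cand - p)) >= min_sep for p in points):
            points.append(cand)
        attempts += 1
        if attempts > 200 * config.n_cells:
            min_sep *= 0.9
            attempts = 0
    return np.array(points)


def _label_map(points: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Nearest-seed (Voronoi) labeling of the pixel grid, labels 1-based."""
    h, w = config.image_size
    scale = np.array([1.0, config.elongation])  # stretch column axis distances
    tree = cKDTree(points * scale)
    rr, cc = np.mgrid[0:h, 0:w]
    grid = np.column_stack([rr.ravel(), cc.ravel()]) * scale
    _, idx = tree.query(grid, workers=-1)
    return (idx + 1).reshape(h, w).astype(np.int32)


def _lloyd_relax(points: np.ndarray, config: SimulationConfig, iterations: int = 4) -> np.ndarray:
    """Centroidal-Voronoi (Lloyd) relaxation of the seed points.

    Confluent endothelial monolayers have near-regular polygonal cells whose
    junctions meet close to 120 degrees; raw Poisson/min-separation Voronoi
    still contains near-degenerate vertices with thin wedge corners that no
    real monolayer shows. A few Lloyd steps (seeds moved to their cell
    centroids) regularize the tessellation toward that epithelial geometry.
    """
    pts = points.copy()
    for _ in range(iterations):
        labels = _label_map(pts, config)
        for i in range(len(pts)):
            rr, cc = np.nonzero(labels == i + 1)
            if len(rr):
                pts[i] = [rr.mean(), cc.mean()]
    return pts


def _junction_pixels_by_edge(
    labels: np.ndarray,
) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Group junction pixels by the cell pair whose border they rasterize.

    A pixel is junctional when a 4-neighbor carries a different label. Each
    junction pixel keeps its own cell's label, so a shared border is two
    facing single-pixel chains; the edge key is the unordered label pair. At
    triple points the smallest differing neighbor label wins (deterministic).

    Returns per edge the pixels ordered along the border (by projection onto
    the edge's principal axis) together with the projection values, so gaps
    can later be carved as *spatial* intervals covering both facing chains.
    """
    h, w = labels.shape
    own = labels
    partner = np.full((h, w), 0, dtype=np.int32)
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = np.full((h, w), np.iinfo(np.int32).max, dtype=np.int32)
        sr, sc = shift
        src = own[
            max(0, -sr) : h - max(0, sr),
            max(0, -sc) : w - max(0, sc),
        ]
        neigh[
            max(0, sr) : h - max(0, -sr),
            max(0, sc) : w - max(0, -sc),
        ] = src
        differs = (neigh != own) & (neigh != np.iinfo(np.int32).max)
        update = differs & ((partner == 0) | (neigh < partner))
        partner[update] = neigh[update]
    jr, jc = np.nonzero(partner > 0)
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for r, c in zip(jr.tolist(), jc.tolist()):
        a, b = int(own[r, c]), int(partner[r, c])
        key = (min(a, b), max(a, b))
        edges.setdefault(key, []).append((r, c))
    ordered: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for key in sorted(edges):
        px = np.array(edges[key])
        centered = px - px.mean(axis=0)
        if len(px) > 1:
            cov = centered.T @ centered
            _, vecs = np.linalg.eigh(cov)
            axis = vecs[:, -1]
            proj = centered @ axis
            order = np.lexsort((px[:, 1], px[:, 0], proj))
        else:
            proj = np.zeros(1)
            order = np.array([0])
        ordered[key] = (px[order], proj[order])
    return ordered


def _carve_gaps(
    edges: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Delete contiguous runs of junction pixels until the target fraction.

    A run is a *spatial* interval along a border: all pixels of both facing
    chains whose projection falls within a window of ~``gap_length_pixels``.
    Runs are placed uniformly along total junction length; the final run is
    trimmed so the realized fraction lands on the request (well inside the
    ±0.05 contract). Returns an (n_gap, 2) array of deleted coordinates.
    """
    keys = sorted(edges)
    total = sum(len(edges[k][0]) for k in keys)
    target = int(round(config.gap_fraction * total))
    removed: dict[tuple[int, int], np.ndarray] = {
        k: np.zeros(len(edges[k][0]), dtype=bool) for k in keys
    }
    n_removed = 0
    guard = 0
    while n_removed < target and guard < 100 * len(keys) + 10_000:
        guard += 1
        weights = np.array([(~removed[k]).sum() for k in keys], dtype=float)
        if weights.sum() == 0:
            break
        k = keys[rng.choice(len(keys), p=weights / weights.sum())]
        px, proj = edges[k]
        length = max(
            1.0, rng.normal(config.gap_length_pixels, config.gap_length_pixels / 4)
        )
        anchor = proj[int(rng.integers(0, len(px)))]
        window = (proj >= anchor) & (proj < anchor + length)
        fresh = np.nonzero(window & ~removed[k])[0]
        fresh = fresh[: max(0, target - n_removed)]  # hard-trim to land on target
        removed[k][fresh] = True
        n_removed += len(fresh)
    coords = [edges[k][0][removed[k]] for k in keys if removed[k].any()]
    return np.concatenate(coords) if coords else np.empty((0, 2), dtype=int)


def _illumination_field(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency background: an upsampled random coarse grid."""
    h, w = config.image_size
    if config.illumination_amplitude == 0:
        return np.zeros((h, w))
    coarse = rng.random((6, 6))
    field = ndi.zoom(coarse, (h / 6, w / 6), order=3, grid_mode=True, mode="nearest")
    field -= field.min()
    peak = field.max()
    if peak > 0:
        field /= peak
    return config.illumination_amplitude * field


def generate_monolayer(config: SimulationConfig) -> tuple[ImageChannel, MonolayerTruth]:
    """Render one synthetic cadherin-5 channel with full ground truth.

    The render is ``peak * exp(-d^2 / (2 sigma^2))`` of the distance ``d`` to
    the nearest surviving junction pixel, plus the illumination field and
    noise, clipped and quantized to 8 bits. Identical configurations
    reproduce the image bit-exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    points = _lloyd_relax(_sample_seed_points(config, rng), config)
    labels = _label_map(points, config)
    edges = _junction_pixels_by_edge(labels)

    h, w = config.image_size
    junction_mask = np.zeros((h, w), dtype=bool)
    for px, _ in edges.values():
        junction_mask[px[:, 0], px[:, 1]] = True

    gap_mask = np.zeros((h, w), dtype=bool)
    if config.gap_fraction > 0:
        gap_px = _carve_gaps(edges, config, rng)
        if len(gap_px):
            gap_mask[gap_px[:, 0], gap_px[:, 1]] = True

    kept = junction_mask & ~gap_mask
    if kept.any():
        d = ndi.distance_transform_edt(~kept)
        ridge = config.junction_peak_intensity * np.exp(
            -(d ** 2) / (2 * config.junction_width_sigma ** 2)
        )
    else:
        ridge = np.zeros((h, w))

    raster = ridge + _illumination_field(config, rng)
    if config.noise_sigma > 0:
        raster = raster + rng.normal(0.0, config.noise_sigma, size=(h, w))
    pixels = as_uint8(raster)

    border_cells = set(
        np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        ).tolist()
    )
    per_cell: dict[int, float] = {}
    for cell in np.unique(labels).tolist():
        on_cell = junction_mask & (labels == cell)
        n_border = int(on_cell.sum())
        per_cell[int(cell)] = float((gap_mask & on_cell).sum()) / n_border if n_border else 0.0

    truth = MonolayerTruth(
        seed_points=points,
        cell_label_map=labels,
        junction_mask=junction_mask,
        gap_mask=gap_mask,
        per_cell_gap_fraction=per_cell,
        border_cells=border_cells,
        rng_seed=config.rng_seed,
    )
    img = ImageChannel(pixels, image_id=f"sim_seed{config.rng_seed}", group_label="")
    return img, truth


def derive_seed(base_seed: int, group_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(group_index), int(replicate_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_condition_panel(
    base_config: SimulationConfig,
    group_gap_fractions: dict[str, float],
    images_per_group: int,
) -> list[tuple[str, ImageChannel, MonolayerTruth]]:
    """One independent image per (condition, replicate).

    Mirrors a multi-condition immunofluorescence experiment: each condition
    gets its own true gap fraction, each replicate its own derived seed, and
    the whole panel is deterministic given the base seed.
    """
    if not group_gap_fractions:
        raise ValueError("group_gap_fractions must contain at least one group")
    if images_per_group < 1:
        raise ValueError(f"images_per_group must be >= 1, got {images_per_group}")
    panel = []
    for gi, (label, gap) in enumerate(group_gap_fractions.items()):
        for ri in range(images_per_group):
            seed = derive_seed(base_config.rng_seed, gi, ri)
            cfg = SimulationConfig(
                **{**asdict(base_config), "gap_fraction": float(gap), "rng_seed": seed}
            )
            img, truth = generate_monolayer(cfg)
            img = ImageChannel(
                img.pixels, image_id=f"{label}_rep{ri}_seed{seed}", group_label=label
            )
            panel.append((label, img, truth))
    return panel


# ---------------------------------------------------------------------------
# truth serialization (run-length encoded masks; JSON, text-only)

def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    flat = np.asarray(mask).ravel()
    if flat.size == 0:
        return []
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    return [[int(s), int(e - s)] for s, e, v in zip(starts, ends, flat[starts]) if v]


def _rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


def _labels_encode(labels: np.ndarray) -> list[list[int]]:
    flat = labels.ravel()
    change = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    return [[int(v), int(e - s)] for s, e, v in zip(starts, ends, flat[starts])]


def _labels_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.concatenate([np.full(length, value, dtype=np.int32) for value, length in runs])
    return flat.reshape(shape)


def write_truth(truth: MonolayerTruth, path: str | Path) -> None:
    """One JSON per image: seeds, RLE masks, per-cell gap fractions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    shape = truth.cell_label_map.shape
    payload = {
        "shape": list(shape),
        "rng_seed": truth.rng_seed,
        "seed_points": truth.seed_points.tolist(),
        "cell_label_map_rle": _labels_encode(truth.cell_label_map),
        "junction_mask_rle": _rle_encode(truth.junction_mask),
        "gap_mask_rle": _rle_encode(truth.gap_mask),
        "per_cell_gap_fraction": {str(k): v for k, v in truth.per_cell_gap_fraction.items()},
        "border_cells": sorted(truth.border_cells),
    }
    path.write_text(json.dumps(payload))


def read_truth(path: str | Path) -> MonolayerTruth:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    return MonolayerTruth(
        seed_points=np.array(payload["seed_points"]),
        cell_label_map=_labels_decode(payload["cell_label_map_rle"], shape),
        junction_mask=_rle_decode(payload["junction_mask_rle"], shape),
        gap_mask=_rle_decode(payload["gap_mask_rle"], shape),
        per_cell_gap_fraction={int(k): v for k, v in payload["per_cell_gap_fraction"].items()},
        border_cells=set(payload["border_cells"]),
        rng_seed=int(payload["rng_seed"]),
    )


def write_panel(
    panel: list[tuple[str, ImageChannel, MonolayerTruth]],
    output_dir: str | Path,
) -> Path:
    """Write TIFFs + truth JSONs + a manifest CSV; returns the manifest path.

    The manifest (columns: group, image_path, truth_path, seed) is the direct
    input format of the batch pipeline, so simulated panels feed the analysis
    without edits.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest = output_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "image_path", "truth_path", "seed"])
        for label, img, truth in panel:
            img_path = output_dir / f"{img.image_id}.tif"
            truth_path = output_dir / f"{img.image_id}_truth.json"
            write_channel(img, img_path)
            write_truth(truth, truth_path)
            writer.writerow([label, str(img_path), str(truth_path), truth.rng_seed])
    return manifest
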