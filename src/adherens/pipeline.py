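"""Batch orchestration: manifest in, scored cells and group report out.

One call runs the whole analysis for a panel of grouped micrographs listed in
a manifest CSV (columns ``group,image_path`` plus optional ``truth_path`` and
``seed``): per image, the outline-extraction chain, random cell selection and
discontinuity scoring; pooled, a tidy per-cell CSV, a per-image aggregation,
a Kruskal–Wallis group report with box-plot figure, per-image provenance
JSONs and QC overlays. Reruns with the same configuration reproduce the CSV
byte for byte; every output embeds a hash of the configuration it came from.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import ImageChannel, read_channel
from .junctions import select_outlines, subtract_background, trace_outlines
from .discontinuity import records_to_frame, score_image
from .simulate import SimulationConfig, derive_seed, generate_condition_panel, read_truth, write_panel
from .stats import GroupComparison, kruskal_wallis


class EmptyManifestError(ValueError):
    """Manifest lists no images."""


class OrphanImageError(ValueError):
    """Results and truth files do not describe the same panel."""


@dataclass
class PipelineConfig:
    """All knobs of the batch pipeline.

    The image-processing defaults reproduce the published operator settings:
    rolling-ball radius 20 px, Gaussian sigma 2.0 applied twice, two rounds
    of binary dilation, fixed 21–255 scoring window, 25 cells per image.
    """

    manifest_path: str = ""
    output_dir: str = "adherens_out"
    rolling_radius: int = 20
    blur_sigma: float = 2.0
    blur_passes: int = 2
    dilate_iterations: int = 2
    bridge_max: int = 10
    prune_length: int = 5
    threshold_low: int = 21
    threshold_high: int = 255
    cells_per_image: int = 25
    rng_seed: int = 0
    channel_index: int = 0
    auto_rescale: bool = False
    write_overlays: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O locations excluded)."""
        payload = asdict(self)
        for key in ("manifest_path", "output_dir", "write_overlays"):
            payload.pop(key)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    records: pd.DataFrame
    comparison: GroupComparison | None
    per_image: pd.DataFrame
    log: dict
    output_dir: Path


def _read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = pd.read_csv(path, dtype=str)
    required = {"group", "image_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}, got {list(manifest.columns)}")
    if len(manifest) == 0:
        raise EmptyManifestError(f"manifest {path} lists no images")
    return manifest


def _overlay_figure(img: ImageChannel, outlines, selected, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.pixels, cmap="gray", interpolation="nearest")
    sel_ids = {o.cell_id for o in selected}
    for o in outlines:
        if o.touches_border:
            continue
        color = "lime" if o.cell_id in sel_ids else "orange"
        ax.plot(o.path[:, 1], o.path[:, 0], ".", color=color, markersize=0.5)
    ax.set_title(f"{img.image_id} ({img.group_label}) — selected in green")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _boxplot_figure(comparison: GroupComparison, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(comparison.group_labels) + 2, 4))
    ax.boxplot(
        [comparison.per_group_ratios[g] for g in comparison.group_labels],
        tick_labels=comparison.group_labels,
        whis=(0, 100),
    )
    ax.set_ylabel("ratio of cadherin-5 discontinuity (%)")
    ax.set_title(
        f"Kruskal–Wallis H = {comparison.H_statistic:.3g}, p = {comparison.p_value:.3g}"
    )
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full discontinuity analysis over a manifest of images."""
    t_start = time.time()
    manifest = _read_manifest(config.manifest_path)
    out_dir = Path(config.output_dir)
    (out_dir / "provenance").mkdir(parents=True, exist_ok=True)
    if config.write_overlays:
        (out_dir / "overlays").mkdir(exist_ok=True)
    cfg_hash = config.config_hash()

    all_records = []
    log: dict = {
        "config": asdict(config),
        "config_hash": cfg_hash,
        "package_version": __version__,
        "images": [],
    }
    for idx, row in manifest.iterrows():
        t_img = time.time()
        img = read_channel(
            row["image_path"],
            group_label=row["group"],
            channel_index=config.channel_index,
            auto_rescale=config.auto_rescale,
        )
        background_subtracted = subtract_background(img, radius=config.rolling_radius)
        skeleton, outlines = trace_outlines(
            img,
            rolling_radius=config.rolling_radius,
            blur_sigma=config.blur_sigma,
            blur_passes=config.blur_passes,
            dilate_iterations=config.dilate_iterations,
            bridge_max=config.bridge_max,
            prune_length=config.prune_length,
            background_subtracted=background_subtracted,
        )
        selection_seed = derive_seed(config.rng_seed, int(idx), 1)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            selected = select_outlines(
                outlines, k=config.cells_per_image, rng_seed=selection_seed
            )
        records = score_image(
            img,
            selected,
            threshold_low=config.threshold_low,
            threshold_high=config.threshold_high,
            background_subtracted=background_subtracted,
        )
        all_records.extend(records)

        image_log = {
            "image_id": img.image_id,
            "group": row["group"],
            "outlines_found": sum(1 for o in outlines if not o.touches_border),
            "outlines_selected": len(selected),
            "selection_seed": selection_seed,
            "warnings": [str(w.message) for w in caught],
            "seconds": round(time.time() - t_img, 3),
        }
        log["images"].append(image_log)
        prov = {
            "config_hash": cfg_hash,
            "image_id": img.image_id,
            "operators": skeleton.provenance,
            **image_log,
        }
        (out_dir / "provenance" / f"{img.image_id}.json").write_text(
            json.dumps(prov, indent=1)
        )
        if config.write_overlays:
            _overlay_figure(img, outlines, selected, out_dir / "overlays" / f"{img.image_id}.png")

    records_frame = records_to_frame(all_records)
    csv_path = out_dir / "discontinuity_records.csv"
    with open(csv_path, "w", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        records_frame.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")

    per_image = (
        records_frame.groupby(["group", "image_id"], sort=True)["ratio_percent"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
    with open(out_dir / "per_image_summary.csv", "w", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        fh.write("# note: cells within one image are not independent observations\n")
        per_image.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")

    comparison = None
    groups = {
        g: grp["ratio_percent"].tolist()
        for g, grp in records_frame.groupby("group", sort=True)
    }
    if len(groups) >= 2 and all(len(v) for v in groups.values()):
        comparison = kruskal_wallis(groups)
        report = {
            "config_hash": cfg_hash,
            "H_statistic": comparison.H_statistic,
            "p_value": comparison.p_value,
            "groups": {
                g: asdict(s) for g, s in comparison.group_summaries.items()
            },
        }
        (out_dir / "group_comparison.json").write_text(json.dumps(report, indent=1))
        _boxplot_figure(comparison, out_dir / "group_comparison.png")

    log["total_seconds"] = round(time.time() - t_start, 3)
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return PipelineResult(
        records=records_frame,
        comparison=comparison,
        per_image=per_image,
        log=log,
        output_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# simulate / validate

@dataclass
class PanelSpec:
    """Declarative description of a synthetic condition panel."""

    groups: dict[str, float]            # group label -> true gap fraction
    images_per_group: int = 4
    base: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" not in data or not data["groups"]:
            raise ValueError("panel spec must define a non-empty 'groups' mapping")
        base_keys = set(SimulationConfig.__dataclass_fields__)
        base_kwargs = {k: v for k, v in data.items() if k in base_keys}
        if "image_size" in base_kwargs:
            base_kwargs["image_size"] = tuple(base_kwargs["image_size"])
        unknown = set(data) - base_keys - {"groups", "images_per_group"}
        if unknown:
            raise ValueError(f"unknown panel spec keys: {sorted(unknown)}")
        base = SimulationConfig(**base_kwargs)
        base.validate()
        return cls(
            groups={str(k): float(v) for k, v in data["groups"].items()},
            images_per_group=int(data.get("images_per_group", 4)),
            base=base,
        )


def simulate_panel(spec: PanelSpec, output_dir: str | Path) -> Path:
    """Generate a panel and write it in pipeline-ready form; returns manifest."""
    panel = generate_condition_panel(spec.base, spec.groups, spec.images_per_group)
    return write_panel(panel, output_dir)


def validate_recovery(results_csv: str | Path, manifest_path: str | Path) -> dict:
    """Close the loop: compare pipeline output against simulation ground truth.

    For every image, the true realized gap fraction (from the truth JSON) is
    paired with the mean measured ratio; the report carries the per-image
    table, the Spearman rank correlation between the two (undefined for a
    single image), and a monotonicity verdict over group means ordered by
    true gap fraction.
    """
    results = pd.read_csv(results_csv, comment="#")
    manifest = _read_manifest(manifest_path)
    if "truth_path" not in manifest.columns:
        raise ValueError("manifest has no truth_path column; nothing to validate against")
    truth_by_image = {}
    for _, row in manifest.iterrows():
        image_id = Path(row["image_path"]).stem
        if not Path(row["truth_path"]).exists():
            raise OrphanImageError(f"truth file missing for image {image_id}: {row['truth_path']}")
        truth_by_image[image_id] = read_truth(row["truth_path"])

    orphans = sorted(set(results["image_id"]) - set(truth_by_image))
    if orphans:
        raise OrphanImageError(f"results contain images with no ground truth: {orphans}")

    rows = []
    for (group, image_id), grp in results.groupby(["group", "image_id"]):
        truth = truth_by_image[image_id]
        rows.append(
            {
                "group": group,
                "image_id": image_id,
                "true_gap_fraction": truth.realized_gap_fraction,
                "mean_measured_ratio": float(grp["ratio_percent"].mean()),
                "n_cells": int(len(grp)),
            }
        )
    table = pd.DataFrame(rows).sort_values(["group", "image_id"]).reset_index(drop=True)

    if len(table) >= 2 and table["true_gap_fraction"].nunique() > 1:
        from scipy.stats import spearmanr

        rho = float(
            spearmanr(table["true_gap_fraction"], table["mean_measured_ratio"]).statistic
        )
    else:
        rho = None

    group_means = (
        table.groupby("group")
        .agg(truth=("true_gap_fraction", "mean"), measured=("mean_measured_ratio", "mean"))
        .sort_values("truth")
    )
    monotone = bool(np.all(np.diff(group_means["measured"].to_numpy()) > 0)) if len(
        group_means
    ) > 1 else True

    return {
        "per_image": table.to_dict(orient="records"),
        "spearman_rho": rho,
        "group_means": {
            g: {"truth": float(r["truth"]), "measured": float(r["measured"])}
            for g, r in group_means.iterrows()
        },
        "monotone_in_truth": monotone,
    }
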