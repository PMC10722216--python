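"""Run orchestration: configuration, I/O, blinding, and the full pipeline.

A run executes geometry -> segmentation -> regularity -> morphometry ->
statistics over a set of cells (either a simulated nested dataset or a
sample sheet pointing at two-channel TIFFs and optional mask exports) and
writes ``qc.csv``, ``metrics.csv``, ``contrasts.csv`` and a run log into
the output directory.  Re-running with the same configuration and seed
reproduces ``metrics.csv`` byte for byte.

Interchange formats are deliberately plain: CSV (UTF-8, header row) for
tables, TIFF/PNG for images and masks, YAML for configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .geometry import GeometryParams, prepare_cell, qc_filter
from .morphometry import MorphometryParams, compute_cell_metrics
from .regularity import RegularityParams, r_power, t_power
from .segment import SegmentParams, baseline_segment, load_mask
from .simulate import DesignConfig, SimTruth, generate_dataset, infarct_effects_preset
from .types import CellImage, CellMetrics, TubuleMask

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_sample_sheet",
    "read_cell_tiff",
    "blind_labels",
    "unblind_labels",
]

REQUIRED_SHEET_COLS = ["cell_id", "image", "animal_id", "group", "region"]


@dataclass
class RunConfig:
    """Everything a run needs; every field has a working default.

    ``simulate_preset`` selects a built-in simulated study ("default" or
    "infarct_effects"); alternatively ``sample_sheet`` points at real data.
    ``mask_source`` chooses between the simulator truth masks, the
    baseline segmenter, and external mask files (``mask_dir``).
    """

    out_dir: str = "ttmorph_run"
    seed: int = 0
    pixel_size_nm: float = 85.0
    sample_sheet: str | None = None
    mask_dir: str | None = None
    simulate_preset: str | None = "default"
    mask_source: str = "simulator_truth"
    n_animals_per_group: int = 2
    n_cells_per_region: int = 3
    overlays: int = 0
    geometry: GeometryParams = field(default_factory=GeometryParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    regularity: RegularityParams = field(default_factory=RegularityParams)
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    stats_metrics: tuple = (
        "area_pct", "length_pct", "transverse_pct", "thickness_ratio",
        "t_power_au", "r_power_au",
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for name, sub in (
            ("geometry", GeometryParams),
            ("segment", SegmentParams),
            ("regularity", RegularityParams),
            ("morphometry", MorphometryParams),
        ):
            if name in data and isinstance(data[name], dict):
                block = data[name]
                for key in ("transverse_band_deg", "band_period_um"):
                    if key in block and isinstance(block[key], list):
                        block[key] = tuple(block[key])
                data[name] = sub(**block)
        if isinstance(data.get("stats_metrics"), list):
            data["stats_metrics"] = tuple(data["stats_metrics"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_cell_tiff(
    path: str | Path, pixel_size_nm: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, float]:
    """Read a cell TIFF: (tubule, ryr, cell_mask | None, pixel_size_nm).

    Channel 1 is the WGA/tubule channel, channel 2 the RyR channel; an
    optional third channel carries the binary cell mask.  Pixel size
    comes from the TIFF resolution tags unless an explicit value is
    given (an explicit value always wins).
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        tag_px = None
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is not None and unit is not None:
            num, den = xres.value
            if num > 0:
                per_unit = num / den  # pixels per unit
                unit_nm = {2: 25.4e6, 3: 1e7}.get(int(unit.value))
                if unit_nm:
                    tag_px = unit_nm / per_unit
    if arr.ndim != 3 or arr.shape[0] < 2:
        if arr.ndim == 3 and arr.shape[-1] in (2, 3):
            arr = np.moveaxis(arr, -1, 0)
        else:
            raise ValueError(
                f"{Path(path).name}: expected a 2-channel TIFF, got {arr.shape}"
            )
    cell_mask = arr[2] > 0 if arr.shape[0] >= 3 else None
    px = pixel_size_nm if pixel_size_nm is not None else (tag_px or 85.0)
    return arr[0].astype(float), arr[1].astype(float), cell_mask, float(px)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    missing = [c for c in REQUIRED_SHEET_COLS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet misses required columns {missing}")
    if sheet["cell_id"].duplicated().any():
        dupes = sheet.loc[sheet["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_ids in sample sheet: {dupes}")
    return sheet


def blind_labels(
    sheet: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace group labels by random codes; returns (blinded sheet, key).

    The key maps code -> group and inverts the blinding exactly.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(sheet["group"].unique())
    codes = [f"G{int(x):03d}" for x in rng.choice(1000, len(groups), replace=False)]
    mapping = dict(zip(groups, codes))
    blinded = sheet.copy()
    blinded["group"] = blinded["group"].map(mapping)
    key = pd.DataFrame({"code": codes, "group": groups})
    return blinded, key


def unblind_labels(blinded: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    inverse = dict(zip(key["code"], key["group"]))
    out = blinded.copy()
    out["group"] = out["group"].map(inverse)
    return out


def _simulated_cells(config: RunConfig):
    effects = infarct_effects_preset() if config.simulate_preset == "infarct_effects" else {}
    design = DesignConfig(
        n_animals_per_group=config.n_animals_per_group,
        n_cells_per_region=config.n_cells_per_region,
        base=SimTruth(pixel_size_nm=config.pixel_size_nm),
        effects=effects,
        seed=config.seed,
    )
    ds = generate_dataset(design)
    for cell, tmask, _truth in ds.cells:
        yield cell.labels(), (lambda c=cell, m=tmask: (c, m.mask))


def _sheet_cells(config: RunConfig):
    sheet = read_sample_sheet(config.sample_sheet)
    base = Path(config.sample_sheet).parent

    def loader(row):
        tub, ryr, cell_mask, px = read_cell_tiff(
            base / row["image"], config.pixel_size_nm
        )
        if cell_mask is None:
            cell_mask = tub > 0  # fall back to the intensity support
        cell = CellImage(
            tubule_channel=tub, ryr_channel=ryr, cell_mask=cell_mask,
            pixel_size_nm=px, cell_id=str(row["cell_id"]),
            animal_id=str(row["animal_id"]), group_label=str(row["group"]),
            region_label=str(row["region"]),
        )
        if isinstance(row.get("mask_path"), str):
            mask_path = base / row["mask_path"]
        elif config.mask_dir:
            mask_path = Path(config.mask_dir) / f"{row['cell_id']}.tif"
        else:
            mask_path = None
        mask = None
        if mask_path is not None and mask_path.exists():
            mask = load_mask(mask_path, cell).mask
        return cell, mask

    for _, row in sheet.iterrows():
        labels = {
            "cell_id": str(row["cell_id"]), "animal_id": str(row["animal_id"]),
            "group": str(row["group"]), "region": str(row["region"]),
        }
        yield labels, (lambda r=row: loader(r))


def _write_overlay(path: Path, cell: CellImage, mask: TubuleMask, sk_mask) -> None:
    import imageio.v3 as iio

    img = cell.tubule_channel
    lo, hi = np.percentile(img, [1, 99.5])
    base = np.clip((img - lo) / max(hi - lo, 1e-9), 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[mask.mask] = [0.8, 0.1, 0.1]
    rgb[sk_mask] = [1.0, 1.0, 1.0]
    iio.imwrite(path, (rgb * 255).astype(np.uint8))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all outputs to ``out_dir``.

    Per-cell failures are logged into qc.csv with a reason and skipped;
    the run itself only fails on configuration errors.
    """
    from .morphometry import skeletonize
    from .stats import compare_metrics

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overlays_dir = out / "overlays"
    if config.overlays:
        overlays_dir.mkdir(exist_ok=True)

    if config.sample_sheet:
        source = _sheet_cells(config)
    else:
        source = _simulated_cells(config)

    qc_rows, metric_rows, log_lines = [], [], []
    n_overlays = 0
    for labels, load in source:
        try:
            cell, raw_mask = load()
            if raw_mask is not None and config.mask_source != "baseline_segmenter":
                rcell, rmask, angle = prepare_cell(
                    cell, config.geometry, extra_mask=raw_mask
                )
                provenance = (
                    "simulator_truth"
                    if config.sample_sheet is None
                    else "external_file"
                )
                tmask = TubuleMask.from_cell(rmask, rcell, provenance)
            else:
                rcell, angle = prepare_cell(cell, config.geometry)
                tmask = None

            report = qc_filter(rcell, config.geometry)
            qc_rows.append(
                {**labels, "passed": report.passed,
                 "reasons": ";".join(report.reasons), "axis_angle_deg": angle}
            )
            if not report.passed:
                continue
            if tmask is None:
                tmask = baseline_segment(rcell, config.segment)

            tp = t_power(rcell, tmask, config.regularity)
            rp = r_power(rcell, config.regularity)
            metric_rows.append(
                compute_cell_metrics(
                    rcell, tmask, tp, rp, config.morphometry
                ).as_row()
            )
            if config.overlays and n_overlays < config.overlays:
                sk = skeletonize(tmask, config.morphometry.orientation_window_px)
                _write_overlay(
                    overlays_dir / f"{cell.cell_id}.png", rcell, tmask, sk.mask
                )
                n_overlays += 1
        except Exception as exc:  # per-cell robustness: record and move on
            qc_rows.append(
                {**labels, "passed": False,
                 "reasons": f"failed-io:{exc}", "axis_angle_deg": np.nan}
            )
            log_lines.append(f"cell {labels['cell_id']} failed: {exc}")

    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc.csv", index=False)
    metrics = pd.DataFrame(metric_rows, columns=CellMetrics.columns())
    metrics.to_csv(out / "metrics.csv", index=False)

    contrasts = pd.DataFrame()
    if len(metrics) and metrics.groupby("group")["animal_id"].nunique().min() >= 2:
        try:
            contrasts = compare_metrics(metrics, list(config.stats_metrics))
        except ValueError as exc:
            log_lines.append(f"stats skipped: {exc}")
    else:
        log_lines.append("stats skipped: fewer than 2 animals per group")
    contrasts.to_csv(out / "contrasts.csv", index=False)

    config.to_yaml(out / "config.yaml")
    with open(out / "run.log", "w") as fh:
        fh.write(f"ttmorph {__version__}\n")
        fh.write(f"config sha256: {config.digest()}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"cells analysed: {len(metrics)} / {len(qc)}\n")
        for line in log_lines:
            fh.write(line + "\n")
    return out
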