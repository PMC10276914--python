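"""File formats, configuration, and batch execution.

Images travel as multi-page TIFF (page order: z-major, channel-minor) with a
JSON ImageDescription carrying the channel roles, z depth and pixel scale;
masks as single-channel TIFF/PNG with the 0/nonzero rule; traces as
two-column CSV (time_s, current_pA) with a JSON sidecar for the sample rate
and group metadata. Batch runs emit TSV tables plus a JSON run manifest
(input checksums, config snapshot, per-field status); rerunning with
identical inputs, config and seed reproduces byte-identical tables —
timestamps are confined to the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import defaults, inclusions
from .primitives import BinaryMask, ImageStack

logger = logging.getLogger("tauscope")


class IngestionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All operator parameters of the pipeline, serializable to flat YAML."""

    pixel_size_um: float = defaults.PIXEL_SIZE_UM
    channel_roles: dict = field(default_factory=lambda: {"nuclei": 0, "marker": 1,
                                                         "deposit": 2})
    deposit_threshold: float = defaults.DEPOSIT_THRESHOLD
    marker_threshold: float = defaults.MARKER_THRESHOLD
    yfp_threshold: float = defaults.DEPOSIT_THRESHOLD
    nucleus_threshold: float = defaults.NUCLEUS_THRESHOLD
    ball_radius_px: int = defaults.BALL_RADIUS_PX
    gaussian_sigma_px: float = defaults.GAUSSIAN_SIGMA_PX
    closing_cycles: int = defaults.CLOSING_CYCLES
    connectivity: int = defaults.CONNECTIVITY
    small_min_px: int = defaults.SMALL_BOUNDS_PX[0]
    small_max_px: int = defaults.SMALL_BOUNDS_PX[1]
    medium_max_px: int = defaults.MEDIUM_BOUNDS_PX[1]
    condensed_max_area_px: int = defaults.CONDENSED_MAX_AREA_PX
    condensed_min_intensity: float = defaults.CONDENSED_MIN_INTENSITY
    branch_threshold_8bit: float = 128.0
    mask_threshold_frac: float = 0.10
    criterion_threshold: float = defaults.CRITERION_THRESHOLD
    amp_min_pa: float = defaults.AMP_MIN_PA
    window_s: float = defaults.WINDOW_S
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 6.0
    seed: int = 0

    def cutoffs(self) -> inclusions.SizeClassCutoffs:
        return inclusions.SizeClassCutoffs(
            small=(self.small_min_px, self.small_max_px),
            medium=(self.small_max_px + 1, self.medium_max_px),
            large_min=self.medium_max_px + 1,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise IngestionError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Multi-page TIFF, one page per (z, channel), z-major."""
    pages = stack.data.transpose(1, 0, 2, 3).reshape(-1, *stack.shape)
    meta = {"channels": stack.channels, "n_z": stack.n_z,
            "pixel_size_um": stack.pixel_size_um}
    tifffile.imwrite(path, pages.astype(np.float32),
                     photometric="minisblack", description=json.dumps(meta))


def read_image(path: str | Path,
               *,
               channels: dict[str, int] | None = None,
               n_z: int | None = None,
               pixel_size_um: float | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` or a generic multi-page TIFF.

    Axis interpretation and pixel scale come from the embedded JSON metadata;
    explicit arguments override the metadata (logged when both exist). A
    file without metadata needs ``channels`` (and ``n_z`` when stacked).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    file_channels = meta.get("channels")
    file_nz = meta.get("n_z")
    file_scale = meta.get("pixel_size_um")
    if channels is not None and file_channels is not None and channels != file_channels:
        logger.warning("config channel map overrides file metadata for %s", path)
    if pixel_size_um is not None and file_scale is not None \
            and pixel_size_um != file_scale:
        logger.warning("config pixel size %.4g overrides file metadata %.4g for %s",
                       pixel_size_um, file_scale, path)
    channels = channels if channels is not None else file_channels
    n_z = n_z if n_z is not None else file_nz
    pixel_size_um = pixel_size_um if pixel_size_um is not None else file_scale
    if channels is None:
        raise IngestionError(f"{path}: channel roles unresolvable; pass channels=")
    if pixel_size_um is None:
        raise IngestionError(f"{path}: pixel size unresolvable; pass pixel_size_um=")
    if pages.ndim == 2:
        pages = pages[None]
    n_c = len(channels)
    if n_z is None:
        if pages.shape[0] % n_c:
            raise IngestionError(f"{path}: page count {pages.shape[0]} does not "
                                 f"divide into {n_c} channels; pass n_z=")
        n_z = pages.shape[0] // n_c
    data = pages.reshape(n_z, n_c, *pages.shape[1:]).transpose(1, 0, 2, 3)
    return ImageStack(np.asarray(data, np.float64), float(pixel_size_um),
                      dict(channels))


def read_mask(path: str | Path) -> BinaryMask:
    """Single-plane TIFF/PNG mask via the 0/nonzero rule."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # drop any color/alpha axis
        arr = arr[..., 0]
    return BinaryMask(arr != 0, provenance=f"file:{Path(path).name}")


def write_mask(path: str | Path, mask: BinaryMask | np.ndarray) -> None:
    arr = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    iio.imwrite(path, (arr.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(path: str | Path, samples: np.ndarray, sample_rate_hz: float,
                group: str = "", cell_id: str = "") -> None:
    """Two-column CSV (time_s, current_pA) plus a JSON sidecar."""
    path = Path(path)
    t = np.arange(len(samples)) / sample_rate_hz
    pd.DataFrame({"time_s": t, "current_pA": samples}).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"sample_rate_hz": sample_rate_hz,
                                   "group": group, "cell_id": cell_id}))


def read_trace(path: str | Path):
    """Read a trace CSV and its JSON sidecar into an ephys Trace."""
    from .ephys import Trace
    path = Path(path)
    df = pd.read_csv(path)
    if "current_pA" not in df.columns:
        raise IngestionError(f"{path}: expected a current_pA column")
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["sample_rate_hz"])
        group, cell = meta.get("group", ""), meta.get("cell_id", "")
    else:
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise IngestionError(f"{path}: cannot infer sample rate")
        fs = 1.0 / float(np.median(np.diff(t)))
        group = cell = ""
    return Trace(df["current_pA"].to_numpy(), fs, group=group, cell_id=cell)


# ---------------------------------------------------------------------------
# batch runs
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_batch(field_manifest: list[dict],
              config: PipelineConfig,
              out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the inclusion pipeline over a manifest of fields.

    ``field_manifest`` entries carry ``field_id``, ``path`` (image file) or
    ``stack`` (in-memory ImageStack), and ``group``. Per-field failures are
    logged into the manifest and skipped; they never abort the batch. Emits
    ``per_field.tsv``, ``group_summary.tsv``, ``particles.tsv`` and
    ``manifest.json`` under ``out_dir`` and returns the two tables and the
    manifest dict.
    """
    from . import __version__
    if not field_manifest:
        raise IngestionError("empty field manifest")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, particle_rows, statuses = [], [], []
    warnings: list[str] = []
    for entry in field_manifest:
        fid = entry["field_id"]
        group = entry.get("group", "")
        try:
            if "stack" in entry:
                stack = entry["stack"]
                checksum = None
            else:
                stack = read_image(entry["path"],
                                   channels=entry.get("channels"),
                                   pixel_size_um=config.pixel_size_um)
                checksum = _sha256(Path(entry["path"]))
            records, summary = inclusions.quantify_inclusions(
                stack, config.deposit_threshold,
                ball_radius_px=config.ball_radius_px,
                connectivity=config.connectivity,
                cutoffs=config.cutoffs(),
                marker_threshold=config.marker_threshold,
                closing_cycles=config.closing_cycles,
            )
            warnings.extend(f"{fid}: {w}" for w in summary.flags)
            rows.append({
                "field_id": fid, "group": group,
                "n_particles": summary.n_particles,
                "total_area_px": summary.total_area_px,
                "total_area_um2": summary.total_area_um2,
                "sum_int_den": summary.sum_int_den,
                "n_small": summary.class_counts["small"],
                "n_medium": summary.class_counts["medium"],
                "n_large": summary.class_counts["large"],
                "n_live_nuclei": summary.n_live_nuclei,
                "particles_per_live": summary.particles_per_live,
                "int_den_per_live": summary.int_den_per_live,
            })
            for r in records:
                particle_rows.append({
                    "field_id": fid, "label": r.label, "area_px": r.area_px,
                    "area_um2": r.area_um2, "mean_intensity": r.mean_intensity,
                    "int_den": r.int_den, "centroid_row": r.centroid[0],
                    "centroid_col": r.centroid[1], "size_class": r.size_class,
                })
            statuses.append({"field_id": fid, "status": "ok", "checksum": checksum})
        except Exception as exc:  # noqa: BLE001 - error isolation contract
            logger.error("field %s failed: %s", fid, exc)
            statuses.append({"field_id": fid, "status": f"error: {exc}",
                             "checksum": None})
    per_field = pd.DataFrame(rows)
    if len(per_field):
        agg = per_field.groupby("group").agg(
            n_fields=("field_id", "count"),
            mean_n_particles=("n_particles", "mean"),
            median_n_particles=("n_particles", "median"),
            mean_int_den_per_live=("int_den_per_live", "mean"),
            median_int_den_per_live=("int_den_per_live", "median"),
            min_int_den_per_live=("int_den_per_live", "min"),
            max_int_den_per_live=("int_den_per_live", "max"),
            mean_n_live=("n_live_nuclei", "mean"),
        ).reset_index()
    else:
        agg = pd.DataFrame()
    particles = pd.DataFrame(particle_rows)
    per_field.to_csv(out_dir / "per_field.tsv", sep="\t", index=False)
    agg.to_csv(out_dir / "group_summary.tsv", sep="\t", index=False)
    particles.to_csv(out_dir / "particles.tsv", sep="\t", index=False)
    manifest = {
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        "fields": statuses,
        "warnings": warnings,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return per_field, agg, manifest
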