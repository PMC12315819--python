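"""File formats, run configuration and the end-to-end pipeline.

Fields are stored as paired 16-bit grayscale TIFFs named
``<field>_red.tif`` / ``<field>_blue.tif`` with a JSON metadata sidecar
(``<field>_meta.json``: pixel size, exposures, identifiers) and, for
synthetic fields, a ``<field>_truth.json`` ground-truth sidecar.  Spot
lists, per-field co-localization summaries and well summaries travel as
CSV; run configuration as JSON (round-trippable, hashed into every report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .assay_qc import (DEFAULT_MAX_BLEEDTHROUGH_FRAC, DEFAULT_MIN_RANK_CORR,
                       qc_batch, summarize_well)
from .colocalization import coloc_summary, match_spots
from .detection import detect_field
from .types import (ColocSummary, DetectConfig, DualChannelField,
                    GroundTruthField, Spot, StandardSeries)

logger = logging.getLogger("coagg")

__all__ = [
    "RunConfig",
    "write_field",
    "read_field_pair",
    "find_field_pairs",
    "spots_to_frame",
    "summaries_to_frame",
    "read_standard_series",
    "run_pipeline",
]

SPOT_COLUMNS = ["field_id", "channel", "x_px", "y_px", "radius_px",
                "mean_intensity", "method"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable and hashable."""

    detect: DetectConfig = dc_field(default_factory=DetectConfig)
    d_max_px: float = 3.0
    qc_min_rank_corr: float = DEFAULT_MIN_RANK_CORR
    qc_max_bleedthrough_frac: float = DEFAULT_MAX_BLEEDTHROUGH_FRAC
    n_boot: int = 2000
    alpha: float = 0.05
    equal_var: bool = True
    seed: int = 0
    output_dir: str = "."

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        det = d.pop("detect", {})
        return cls(detect=DetectConfig(**det), **d)

    @property
    def config_hash(self) -> str:
        # output_dir is run bookkeeping, not part of the scientific config
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Field I/O
# ---------------------------------------------------------------------------

def write_field(fld: DualChannelField, out_dir: str | Path,
                truth: GroundTruthField | None = None) -> dict[str, Path]:
    """Write a field as paired TIFFs plus JSON sidecars; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = fld.field_id
    paths = {
        "red": out / f"{stem}_red.tif",
        "blue": out / f"{stem}_blue.tif",
        "meta": out / f"{stem}_meta.json",
    }
    tifffile.imwrite(paths["red"], fld.red_image.astype(np.uint16))
    tifffile.imwrite(paths["blue"], fld.blue_image.astype(np.uint16))
    meta = {"pixel_size_um": fld.pixel_size_um,
            "exposure_red_s": fld.exposure_red_s,
            "exposure_blue_s": fld.exposure_blue_s,
            "field_id": fld.field_id, "well_id": fld.well_id,
            "sample_id": fld.sample_id}
    paths["meta"].write_text(json.dumps(meta, indent=2))
    if truth is not None:
        tp = out / f"{stem}_truth.json"
        tp.write_text(json.dumps({
            "red_centers": truth.red_centers,
            "blue_centers": truth.blue_centers,
            "pair_index": truth.pair_index,
            "coloc_fraction": truth.coloc_fraction}, indent=2))
        paths["truth"] = tp
    return paths


def read_truth(path: str | Path) -> GroundTruthField:
    d = json.loads(Path(path).read_text())
    return GroundTruthField(
        red_centers=[tuple(c) for c in d["red_centers"]],
        blue_centers=[tuple(c) for c in d["blue_centers"]],
        pair_index=[tuple(p) for p in d["pair_index"]])


def _load_gray(path: Path) -> np.ndarray:
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path.name}: expected single-channel grayscale, "
                         f"got shape {img.shape}")
    if img.dtype == np.uint8:
        logger.info("%s: 8-bit input up-scaled to 16-bit range", path.name)
        img = img.astype(np.uint16) * 257
    return img


def read_field_pair(path_red: str | Path, path_blue: str | Path,
                    pixel_size_um: float | None = None,
                    **metadata) -> DualChannelField:
    """Read and validate a red/blue TIFF pair into a DualChannelField.

    Pixel size comes from the ``<field>_meta.json`` sidecar when present,
    else from the ``pixel_size_um`` argument; its absence is an error.
    """
    path_red, path_blue = Path(path_red), Path(path_blue)
    red = _load_gray(path_red)
    blue = _load_gray(path_blue)
    if red.shape != blue.shape:
        raise ValueError(f"channel shape mismatch: {path_red.name} "
                         f"{red.shape} vs {path_blue.name} {blue.shape}")
    meta = dict(metadata)
    sidecar = path_red.with_name(
        path_red.name.replace("_red.tif", "_meta.json"))
    if sidecar.exists():
        meta = {**json.loads(sidecar.read_text()), **meta}
    px = meta.pop("pixel_size_um", pixel_size_um)
    if px is None:
        raise ValueError(f"{path_red.name}: pixel size missing (no sidecar "
                         "and no pixel_size_um given)")
    allowed = {"exposure_red_s", "exposure_blue_s", "field_id", "well_id",
               "sample_id"}
    meta = {k: v for k, v in meta.items() if k in allowed}
    meta.setdefault("field_id", path_red.name.replace("_red.tif", ""))
    return DualChannelField(red_image=red, blue_image=blue,
                            pixel_size_um=float(px), **meta)


def find_field_pairs(image_dir: str | Path,
                     ) -> tuple[list[tuple[Path, Path]], list[str]]:
    """Pair ``*_red.tif`` / ``*_blue.tif`` files by stem.

    Returns (pairs, unpaired_stems); pairing is by the filename suffix
    convention, sorted by stem for determinism.
    """
    d = Path(image_dir)
    reds = {p.name[:-len("_red.tif")]: p for p in d.glob("*_red.tif")}
    blues = {p.name[:-len("_blue.tif")]: p for p in d.glob("*_blue.tif")}
    stems = sorted(set(reds) | set(blues))
    pairs, unpaired = [], []
    for s in stems:
        if s in reds and s in blues:
            pairs.append((reds[s], blues[s]))
        else:
            unpaired.append(s)
    return pairs, unpaired


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def spots_to_frame(spots: list[Spot], field_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        [(field_id, s.channel, s.x_px, s.y_px, s.radius_px,
          s.mean_intensity, s.method) for s in spots],
        columns=SPOT_COLUMNS)


def summaries_to_frame(summaries: list[ColocSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "field_id": s.field_id, "n_red": s.n_red, "n_blue": s.n_blue,
        "n_coloc": s.n_coloc, "expected_chance": s.expected_chance,
        "corrected_count": s.corrected_count, "coloc_rate": s.coloc_rate,
        "field_area_mm2": s.field_area_mm2} for s in summaries])


def read_standard_series(path: str | Path) -> StandardSeries:
    """Read a standard-series CSV (concentration_ug_ml, red_count,
    blue_count; optional rows with concentration 0 are the blanks;
    a standard_type column labels the series)."""
    df = pd.read_csv(path)
    blanks = df[df["concentration_ug_ml"] == 0]
    steps = df[df["concentration_ug_ml"] > 0].sort_values(
        "concentration_ug_ml", ascending=False)
    return StandardSeries(
        concentrations=steps["concentration_ug_ml"].tolist(),
        red_counts=steps["red_count"].tolist(),
        blue_counts=steps["blue_count"].tolist(),
        standard_type=str(df["standard_type"].iloc[0]),
        blank_red=float(blanks["red_count"].mean()) if len(blanks) else None,
        blank_blue=float(blanks["blue_count"].mean()) if len(blanks) else None)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(image_dir: str | Path, config: RunConfig | None = None,
                 standards_csv: str | Path | None = None) -> dict:
    """Detect, match and summarize every paired field in a directory.

    Writes ``spots.csv``, ``field_summaries.csv``, ``well_summaries.csv``
    and ``report.json`` under ``config.output_dir``.  Unpaired or unreadable
    fields are recorded as per-field failures and the run continues.  When a
    standards CSV is given, batch QC runs and ``qc_passed`` reflects it.
    """
    config = config or RunConfig()
    pairs, unpaired = find_field_pairs(image_dir)
    if not pairs:
        raise FileNotFoundError(f"no paired fields found in {image_dir}")
    failures = [{"field": s, "error": "unpaired image"} for s in unpaired]

    spot_frames, summaries, fields = [], [], []
    for pr, pb in pairs:
        try:
            fld = read_field_pair(pr, pb)
            red, blue = detect_field(fld, config.detect)
            match = match_spots(red, blue, config.d_max_px)
            h, w = fld.red_image.shape
            summ = coloc_summary(match, len(red), len(blue), h * w,
                                 fld.pixel_size_um, field_id=fld.field_id)
            spot_frames.append(spots_to_frame(red + blue, fld.field_id))
            summaries.append(summ)
            fields.append(fld)
        except Exception as exc:  # keep going; report the failure
            failures.append({"field": pr.name, "error": str(exc)})
            logger.warning("field %s failed: %s", pr.name, exc)

    by_well: dict[tuple[str, str], list[ColocSummary]] = {}
    for fld, summ in zip(fields, summaries):
        by_well.setdefault((fld.well_id, fld.sample_id), []).append(summ)
    wells = [summarize_well(v, well_id=k[0], sample_id=k[1])
             for k, v in sorted(by_well.items())]

    qc = None
    if standards_csv is not None:
        series = read_standard_series(standards_csv)
        verdict = qc_batch(series, config.qc_min_rank_corr,
                           config.qc_max_bleedthrough_frac)
        qc = {"passed": verdict.passed, "reasons": verdict.reasons}

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spot_frames:
        pd.concat(spot_frames, ignore_index=True).to_csv(
            out / "spots.csv", index=False)
    summaries_to_frame(summaries).to_csv(out / "field_summaries.csv", index=False)
    pd.DataFrame([{
        "well_id": w.well_id, "sample_id": w.sample_id, "n_fields": w.n_fields,
        "total_red": w.total_red, "total_blue": w.total_blue,
        "total_coloc": w.total_coloc, "total_corrected": w.total_corrected,
        "total_area_mm2": w.total_area_mm2,
        "density_red": w.density_red, "density_blue": w.density_blue,
        "density_coloc": w.density_coloc,
        "density_corrected": w.density_corrected,
    } for w in wells]).to_csv(out / "well_summaries.csv", index=False)

    report = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_fields": len(summaries),
        "failures": failures,
        "qc": qc,
        "fields": [{"field_id": s.field_id, "n_red": s.n_red,
                    "n_blue": s.n_blue, "n_coloc": s.n_coloc,
                    "expected_chance": s.expected_chance,
                    "corrected_count": s.corrected_count,
                    "coloc_rate": s.coloc_rate} for s in summaries],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline: %d fields, %d failures, config %s, seed %d",
                len(summaries), len(failures), config.config_hash, config.seed)
    return report
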