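"""Reading and writing the pipeline's external formats.

Images go through 16-bit TIFF (tifffile) or PNG (Pillow); tabular data —
per-point spectra, sampling plans, segment summaries — through CSV
(pandas).  Spectra CSVs follow the convention: first column the
wavenumber axis, subsequent columns one spectrum each, with stage
coordinates and exposure carried in the header rows ``x_um``, ``y_um``
and ``exposure_s`` when present.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .phantom import Spectrum
from .segmentation import SegmentationResult


def save_af_tiff(path, af_image: np.ndarray) -> None:
    """Write an AF image as 16-bit greyscale TIFF."""
    arr = np.clip(np.asarray(af_image, float), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def load_af_image(path) -> np.ndarray:
    """Read a greyscale AF raster (TIFF or PNG)."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        return tifffile.imread(path)
    return np.asarray(Image.open(path))


def save_label_tiff(path, label_image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(label_image).astype(np.int32))


def save_map_png(path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, np.uint8)).save(str(path))


def save_segments_csv(path, segmentation: SegmentationResult) -> None:
    rows = [
        {
            "id": s.id,
            "area_px": s.area_px,
            "centroid_row": s.centroid[0],
            "centroid_col": s.centroid[1],
            "mean_af": s.mean_af,
        }
        for s in segmentation.segments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_spectra_csv(path, spectra: list[Spectrum]) -> None:
    """First column wavenumber, then one intensity column per spectrum."""
    if not spectra:
        raise ValueError("no spectra to write")
    wn = spectra[0].wavenumbers
    data = {"wavenumber_cm1": wn}
    meta_rows = {"x_um": [], "y_um": [], "exposure_s": []}
    for i, s in enumerate(spectra):
        if s.wavenumbers.shape != wn.shape or not np.allclose(s.wavenumbers, wn):
            raise ValueError("spectra must share one wavenumber axis")
        data[f"spectrum_{i}"] = s.intensities
        meta_rows["x_um"].append(s.position[0])
        meta_rows["y_um"].append(s.position[1])
        meta_rows["exposure_s"].append(s.exposure)
    frame = pd.DataFrame(data)
    meta = pd.DataFrame(
        {"wavenumber_cm1": list(meta_rows)}
        | {f"spectrum_{i}": [meta_rows["x_um"][i], meta_rows["y_um"][i], meta_rows["exposure_s"][i]]
           for i in range(len(spectra))}
    )
    pd.concat([meta, frame], ignore_index=True).to_csv(path, index=False)


def load_spectra_csv(path) -> list[Spectrum]:
    raw = pd.read_csv(path)
    meta_names = ("x_um", "y_um", "exposure_s")
    meta = raw[raw["wavenumber_cm1"].isin(meta_names)].set_index("wavenumber_cm1")
    body = raw[~raw["wavenumber_cm1"].isin(meta_names)].astype(float)
    wn = body["wavenumber_cm1"].to_numpy()
    out = []
    for col in body.columns:
        if col == "wavenumber_cm1":
            continue
        pos = (float(meta.loc["x_um", col]), float(meta.loc["y_um", col])) if len(meta) else (0.0, 0.0)
        exp = float(meta.loc["exposure_s", col]) if "exposure_s" in meta.index else 2.0
        out.append(
            Spectrum(wavenumbers=wn, intensities=body[col].to_numpy(), position=pos, exposure=exp)
        )
    return out


def save_report_json(path, report) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def write_layer_outputs(outdir, report, record) -> None:
    """Write every intermediate artefact of one layer run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_af_tiff(out / "af_image.tif", record.phantom.af_image)
    save_label_tiff(out / "labels.tif", record.phantom.label_map)
    save_label_tiff(out / "segments.tif", record.segmentation.label_image)
    save_segments_csv(out / "segments.csv", record.segmentation)
    save_map_png(out / "map.png", report.map_image)
    save_report_json(out / "report.json", report)
    report.segment_table.to_csv(out / "segment_decisions.csv", index=False)
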