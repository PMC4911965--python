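"""File I/O: ROI stacks, channel banks, templates, results tables, DICOM.

ROI datasets are written as multi-page TIFF stacks (or raw little-endian
32-bit float with the same layout) plus a JSON sidecar carrying the category,
noise model, counts, seed and pixel pitch.  Channel banks export one TIFF
page per channel with a JSON parameter block.  Templates serialise to JSON
with vectors and matrices as nested lists.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .channels import ChannelBank, ChannelParams
from .observer import CHOTemplate
from .phantom import Category, NoiseModel, ROIDataset, ROIImage
from .study import StudyConfig, StudyResults

logger = logging.getLogger(__name__)

SIDE_CAR_NAME = "dataset.json"


def _dataset_sidecar(dataset: ROIDataset, fmt: str) -> dict:
    sidecar = {
        "format": fmt,
        "roi_side": dataset.roi_side,
        "pixel_pitch": dataset.pixel_pitch,
        "n_signal": dataset.n_signal,
        "n_noise": dataset.n_noise,
        "seed": dataset.seed,
        "category": {
            "dose_mGy": dataset.category.dose_mGy,
            "recon_strength": dataset.category.recon_strength,
            "contrast_hu": dataset.category.contrast_hu,
            "diameter_mm": dataset.category.diameter_mm,
        },
    }
    if dataset.noise_model is not None:
        sidecar["noise_model"] = {
            "kind": dataset.noise_model.kind,
            "sigma_hu": dataset.noise_model.sigma_hu,
            "nps_exponent": dataset.noise_model.nps_exponent,
        }
    return sidecar


def save_roi_dataset(dataset: ROIDataset, directory: str | Path, fmt: str = "tiff") -> Path:
    """Write a dataset as signal/noise/truth stacks plus a JSON sidecar.

    ``fmt`` is "tiff" (multi-page float32 TIFF) or "raw" (little-endian
    float32, C order, shapes recorded in the sidecar).  Returns the directory.
    """
    if fmt not in ("tiff", "raw"):
        raise ValueError("fmt must be 'tiff' or 'raw'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stacks = {
        "signal_present": dataset.signal_present,
        "signal_absent": dataset.signal_absent,
        "truth_profile": dataset.truth_profile.pixels[None],
    }
    for name, stack in stacks.items():
        data = np.asarray(stack, dtype="<f4")
        if fmt == "tiff":
            tifffile.imwrite(directory / f"{name}.tif", data)
        else:
            data.tofile(directory / f"{name}.raw")
    with open(directory / SIDE_CAR_NAME, "w") as handle:
        json.dump(_dataset_sidecar(dataset, fmt), handle, indent=2)
    return directory


def load_roi_dataset(directory: str | Path) -> ROIDataset:
    """Load a dataset written by :func:`save_roi_dataset`."""
    directory = Path(directory)
    with open(directory / SIDE_CAR_NAME) as handle:
        sidecar = json.load(handle)
    side = sidecar["roi_side"]

    def read(name: str, count: int) -> np.ndarray:
        if sidecar["format"] == "tiff":
            data = tifffile.imread(directory / f"{name}.tif")
            data = np.asarray(data, dtype=float)
            if data.ndim == 2:
                data = data[None]
        else:
            data = np.fromfile(directory / f"{name}.raw", dtype="<f4").astype(float)
            data = data.reshape(count, side, side)
        return data

    category = Category(**sidecar["category"])
    noise_model = (
        NoiseModel(**sidecar["noise_model"]) if "noise_model" in sidecar else None
    )
    return ROIDataset(
        category=category,
        signal_present=read("signal_present", sidecar["n_signal"]),
        signal_absent=read("signal_absent", sidecar["n_noise"]),
        truth_profile=ROIImage(read("truth_profile", 1)[0], sidecar["pixel_pitch"]),
        seed=sidecar["seed"],
        pixel_pitch=sidecar["pixel_pitch"],
        noise_model=noise_model,
    )


def save_channel_bank(bank: ChannelBank, directory: str | Path) -> Path:
    """Export a channel bank as one TIFF page per spatial template plus a
    JSON parameter block, for visual inspection and cross-implementation
    comparison."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pages = np.stack(
        [bank.template_image(j) for j in range(1, bank.n_channels + 1)]
    ).astype("<f4")
    tifffile.imwrite(directory / "channels.tif", pages)
    meta = {
        "roi_side": bank.roi_side,
        "pixel_pitch": bank.pixel_pitch,
        "params": {
            "n_channels": bank.params.n_channels,
            "bandwidth_W": bank.params.bandwidth_W,
            "sigma0": bank.params.sigma0,
            "alpha": bank.params.alpha,
        },
    }
    with open(directory / "channels.json", "w") as handle:
        json.dump(meta, handle, indent=2)
    return directory


def template_to_json(template: CHOTemplate, bank: ChannelBank | None = None) -> dict:
    """Serialise a template (vectors/matrices as nested lists); includes the
    bank's parameter block for provenance when a bank is given."""
    payload = {
        "w_cho": template.w_cho.tolist(),
        "mean_signal_c": template.mean_signal_c.tolist(),
        "mean_noise_c": template.mean_noise_c.tolist(),
        "cov_signal_c": template.cov_signal_c.tolist(),
        "cov_noise_c": template.cov_noise_c.tolist(),
        "n_train_signal": template.n_train_signal,
        "n_train_noise": template.n_train_noise,
    }
    if bank is not None:
        payload["channel_params"] = {
            "n_channels": bank.params.n_channels,
            "bandwidth_W": bank.params.bandwidth_W,
            "sigma0": bank.params.sigma0,
            "alpha": bank.params.alpha,
            "roi_side": bank.roi_side,
            "pixel_pitch": bank.pixel_pitch,
        }
    return payload


def template_from_json(payload: dict) -> CHOTemplate:
    return CHOTemplate(
        w_cho=np.asarray(payload["w_cho"], dtype=float),
        mean_signal_c=np.asarray(payload["mean_signal_c"], dtype=float),
        mean_noise_c=np.asarray(payload["mean_noise_c"], dtype=float),
        cov_signal_c=np.asarray(payload["cov_signal_c"], dtype=float),
        cov_noise_c=np.asarray(payload["cov_noise_c"], dtype=float),
        n_train_signal=payload["n_train_signal"],
        n_train_noise=payload["n_train_noise"],
    )


def save_template(template: CHOTemplate, path: str | Path, bank: ChannelBank | None = None) -> None:
    with open(path, "w") as handle:
        json.dump(template_to_json(template, bank), handle, indent=2)


def load_template(path: str | Path) -> CHOTemplate:
    with open(path) as handle:
        return template_from_json(json.load(handle))


def write_results(results: StudyResults, path: str | Path) -> None:
    """Results CSV; Python's shortest round-trip float repr keeps the table
    lossless through a write/read cycle."""
    results.table.to_csv(path, index=False)


def read_results(path: str | Path, config: StudyConfig | None = None) -> StudyResults:
    table = pd.read_csv(path, keep_default_na=True)
    if "error" in table.columns:
        table["error"] = table["error"].fillna("")
    return StudyResults(table=table, config=config if config is not None else StudyConfig())


def read_human_pcs(path: str | Path) -> pd.DataFrame:
    """Human-reader PC table: one row per observer and category, with an
    ``observer`` column, category columns (e.g. dose_mGy, recon_strength,
    contrast_hu, diameter_mm) and a ``pc`` column."""
    df = pd.read_csv(path)
    for col in ("observer", "pc"):
        if col not in df.columns:
            raise ValueError(f"human PC table must contain an {col!r} column")
    return df


def load_dicom_series(paths: list[str | Path] | str | Path) -> tuple[np.ndarray, float]:
    """Load a DICOM slice series into an HU stack.

    Accepts a directory or a list of files; slices are sorted by
    InstanceNumber when available.  Pixel values are rescaled to HU via
    RescaleSlope/RescaleIntercept when present, otherwise returned raw with a
    logged warning.  Returns (stack, pixel_pitch_mm) with pixel_pitch taken
    from PixelSpacing (NaN if absent).
    """
    import pydicom

    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        files = sorted(Path(paths).glob("*.dcm")) or sorted(
            p for p in Path(paths).iterdir() if p.is_file()
        )
    elif isinstance(paths, (str, Path)):
        files = [Path(paths)]
    else:
        files = [Path(p) for p in paths]
    if not files:
        raise ValueError("no DICOM files found")

    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))

    slices = []
    pitch = float("nan")
    for ds in datasets:
        frame = ds.pixel_array.astype(float)
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is not None and intercept is not None:
            frame = frame * float(slope) + float(intercept)
        else:
            logger.warning(
                "DICOM file %s lacks rescale slope/intercept; returning raw values",
                getattr(ds, "filename", "<memory>"),
            )
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            pitch = float(spacing[0])
        slices.append(frame)
    return np.stack(slices), pitch


def load_tiff_series(path: str | Path) -> np.ndarray:
    """Multi-page TIFF to a float stack of shape (n, height, width)."""
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    return data
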