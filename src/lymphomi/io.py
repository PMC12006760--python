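"""File formats: decay stacks as multi-page TIFF + JSON sidecar, masks as
16-bit label TIFF, tables as CSV, reports as JSON.

A decay stack is stored with one TIFF page per time bin (shape
``(n_bins, rows, cols)`` on disk) and a small JSON sidecar carrying the
time base and channel metadata, so the files stay open and inspectable
with standard tools. All readers raise explicit parse errors on malformed
or truncated input rather than returning partial data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datamodels import InstrumentResponse, TCSPCImage
from .simulate import FieldData

__all__ = [
    "write_decay_stack", "read_decay_stack",
    "write_irf", "read_irf",
    "write_mask", "read_mask",
    "write_field", "read_field",
    "write_fit_maps",
    "write_table", "read_table",
    "write_json", "read_json",
    "sha256_file",
]


def _read_tiff(path: Path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ValueError(f"cannot parse TIFF {path}: {exc}") from exc


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_decay_stack(image: TCSPCImage, path: str | Path, **extra_meta) -> Path:
    """Write a TCSPC stack as multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    data = np.moveaxis(np.asarray(image.counts), 2, 0)  # (bins, rows, cols)
    tifffile.imwrite(path, data)
    meta = {
        "bin_width_ns": image.bin_width_ns,
        "period_ns": image.period_ns,
        "n_bins": image.n_bins,
        "channel": image.channel,
        **extra_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_decay_stack(path: str | Path) -> TCSPCImage:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = _read_tiff(path)
    if data.ndim != 3 or data.shape[0] != meta["n_bins"]:
        raise ValueError(
            f"decay stack {path} has shape {data.shape}, expected {meta['n_bins']} pages"
        )
    return TCSPCImage(
        counts=np.moveaxis(data, 0, 2),
        bin_width_ns=meta["bin_width_ns"],
        period_ns=meta["period_ns"],
        channel=meta.get("channel", ""),
    )


def write_irf(irf: InstrumentResponse, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "bin_width_ns": irf.bin_width_ns,
        "period_ns": irf.period_ns,
        "counts": irf.counts.tolist(),
    }
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def read_irf(path: str | Path) -> InstrumentResponse:
    meta = json.loads(Path(path).read_text())
    return InstrumentResponse(
        counts=np.asarray(meta["counts"], dtype=float),
        bin_width_ns=meta["bin_width_ns"],
        period_ns=meta["period_ns"],
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return _read_tiff(Path(path))


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse CSV {path}: {exc}") from exc


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_field(field: FieldData, out_dir: str | Path) -> Path:
    """Write one simulated acquisition to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"condition": field.condition, "batch_id": field.batch_id, "seed": field.seed}
    write_decay_stack(field.nadh, out / "nadh.tif", **meta)
    write_decay_stack(field.fad, out / "fad.tif", **meta)
    write_irf(field.irf, out / "irf.json")
    write_mask(field.cell_mask, out / "cell_mask.tif")
    write_mask(field.nucleus_mask, out / "nucleus_mask.tif")
    tifffile.imwrite(out / "cd69.tif", field.cd69_image.astype(np.float32))
    write_table(field.ground_truth, out / "ground_truth.csv")
    return out


def read_field(field_dir: str | Path) -> FieldData:
    d = Path(field_dir)
    nadh = read_decay_stack(d / "nadh.tif")
    fad = read_decay_stack(d / "fad.tif")
    meta = json.loads((d / "nadh.json").read_text())
    return FieldData(
        nadh=nadh,
        fad=fad,
        irf=read_irf(d / "irf.json"),
        cell_mask=read_mask(d / "cell_mask.tif"),
        nucleus_mask=read_mask(d / "nucleus_mask.tif"),
        cd69_image=_read_tiff(d / "cd69.tif"),
        ground_truth=read_table(d / "ground_truth.csv"),
        condition=meta.get("condition", ""),
        batch_id=meta.get("batch_id", ""),
        seed=meta.get("seed"),
    )


def write_fit_maps(fit, out_dir: str | Path, prefix: str) -> list[Path]:
    """Write per-pixel variable maps as 32-bit float TIFFs plus a summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in fit.variable_maps().items():
        p = out / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths.append(p)
    fitted = np.isfinite(fit.tau_m)
    summary = {
        "intensity_threshold": fit.intensity_threshold,
        "n_fitted_pixels": int(fitted.sum()),
        "n_converged": int(fit.converged.sum()),
        "median_chi2": float(np.nanmedian(fit.chi2)) if fitted.any() else None,
    }
    paths.append(write_json(summary, out / f"{prefix}_summary.json"))
    return paths
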