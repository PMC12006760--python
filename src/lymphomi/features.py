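"""Single-cell OMI feature extraction.

Turns per-pixel fit maps, intensity images, masks and the CD69 marker
channel into one row per cell carrying the nine optical-metabolic-imaging
variables: NAD(P)H and FAD mean lifetime, short and long lifetimes, and
normalized amplitude fraction (as a percentage), plus the optical redox
ratio normalized to each batch's quiescent control mean. Lifetime variables
are unweighted means over cytoplasm pixels that converged and pass the
pixel-level chi-square cut; quality-control filters then remove dim cells
(< 5,000 NAD(P)H photons) and implausibly small masks (< 250 px whole-cell
area, i.e. 75 um^2 at the default 270 um / 256 px scale).

Activation ground truth follows the CD69 surface marker: quiescent = CD69-
cells in the control condition, activated = CD69+ cells in the stimulated
condition; everything else is retained but unlabeled for the main contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening, remove_small_objects

from .fitting import FitImageResult

__all__ = [
    "OMI_FEATURES",
    "segment_cells",
    "segment_cd69",
    "assign_cd69",
    "assign_cd69_labels",
    "label_activation",
    "redox_ratio",
    "normalize_orr",
    "aggregate_cell_features",
    "apply_qc_filters",
]

log = logging.getLogger(__name__)

#: The nine OMI variables used for clustering, embedding and classification.
OMI_FEATURES = [
    "nadh_tm", "nadh_tau1", "nadh_tau2", "nadh_a1",
    "fad_tm", "fad_tau1", "fad_tau2", "fad_a1",
    "orr_norm",
]

NADH_FEATURES = ["nadh_tm", "nadh_tau1", "nadh_tau2", "nadh_a1"]


def segment_cells(
    intensity: np.ndarray,
    min_cell_px: int = 30,
    nucleus_fraction: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold-based single-cell segmentation of an intensity image.

    Foreground is an Otsu cut on the NAD(P)H intensity image followed by a
    small-object sweep; connected components become cell labels. The
    nucleus is recovered photometrically as the in-cell pixels dimmer than
    ``nucleus_fraction`` times the cell's mean intensity (nuclei carry less
    cytoplasmic fluorophore), cleaned by a morphological opening. Returns
    ``(cells, nuclei, cytoplasm)`` label images; an image with no
    foreground yields empty (all-zero) labels.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2:
        raise ValueError("intensity image must be 2-D")
    if np.ptp(intensity) == 0:
        z = np.zeros(intensity.shape, dtype=np.uint16)
        return z, z.copy(), z.copy()
    # Otsu on log intensity: the raw histogram has three classes
    # (background, nucleus, cytoplasm) and raw Otsu can split within the
    # cell; the log transform separates background from cell cleanly.
    fg = intensity > np.expm1(threshold_otsu(np.log1p(intensity)))
    fg = remove_small_objects(fg, max_size=min_cell_px - 1)
    cells = cc_label(fg).astype(np.uint16)
    if cells.max() == 0:
        z = np.zeros(intensity.shape, dtype=np.uint16)
        return cells, z, z.copy()

    labels = np.arange(1, cells.max() + 1)
    cell_means = ndimage.mean(intensity, labels=cells, index=labels)
    mean_map = np.zeros(intensity.shape)
    mean_map[cells > 0] = cell_means[cells[cells > 0] - 1]
    nuc_bin = (cells > 0) & (intensity < nucleus_fraction * mean_map)
    nuc_bin = opening(nuc_bin, footprint=disk(1))
    nuclei = np.where(nuc_bin, cells, 0).astype(np.uint16)
    cytoplasm = np.where(nuc_bin, 0, cells).astype(np.uint16)
    return cells, nuclei, cytoplasm


def segment_cd69(cd69_image: np.ndarray, min_px: int = 20) -> np.ndarray:
    """Binary CD69 mask from the marker intensity image (Otsu threshold)."""
    cd69_image = np.asarray(cd69_image, dtype=float)
    if np.ptp(cd69_image) == 0:
        return np.zeros(cd69_image.shape, dtype=bool)
    mask = cd69_image > threshold_otsu(cd69_image)
    return remove_small_objects(mask, max_size=min_px - 1)


def assign_cd69(
    cd69_mask: np.ndarray, cell_mask: np.ndarray, threshold: float = 0.75
) -> bool:
    """CD69 status of one cell from mask overlap.

    Positive iff some connected CD69 component has at least ``threshold``
    of its own area inside the cell mask (the marker blob of a stained
    cell should lie mostly within that cell).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    comps = cc_label(np.asarray(cd69_mask, dtype=bool))
    touching = np.unique(comps[cell_mask & (comps > 0)])
    for lab in touching:
        comp = comps == lab
        if (comp & cell_mask).sum() / comp.sum() >= threshold:
            return True
    return False


def assign_cd69_labels(
    cd69_mask: np.ndarray, cell_labels: np.ndarray, threshold: float = 0.75
) -> dict[int, bool]:
    """CD69 status for every labeled cell in a field."""
    out: dict[int, bool] = {}
    for lab in np.unique(cell_labels):
        if lab == 0:
            continue
        out[int(lab)] = assign_cd69(cd69_mask, cell_labels == lab, threshold)
    return out


def label_activation(condition: str, cd69_positive: bool) -> str:
    """Activation label: control/CD69- -> quiescent, stimulated/CD69+ -> activated."""
    if condition not in ("control", "stimulated"):
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "control" and not cd69_positive:
        return "quiescent"
    if condition == "stimulated" and cd69_positive:
        return "activated"
    return "unlabeled"


def redox_ratio(nadh_intensity: float, fad_intensity: float) -> float:
    """Optical redox ratio I_NAD(P)H / (I_NAD(P)H + I_FAD), bounded in [0, 1]."""
    if nadh_intensity < 0 or fad_intensity < 0:
        raise ValueError("intensities must be >= 0")
    total = nadh_intensity + fad_intensity
    if total == 0:
        raise ValueError("both intensities are zero")
    return nadh_intensity / total


def normalize_orr(records: pd.DataFrame, batch_col: str = "batch_id") -> pd.DataFrame:
    """Add ``orr_norm``: ORR divided by the batch's quiescent-control mean.

    Each batch stands for one day/donor; normalization corrects day-to-day
    intensity drift. A batch without quiescent control cells is an error.
    """
    records = records.copy()
    ref = {}
    for batch, grp in records.groupby(batch_col):
        ctrl = grp[(grp["condition"] == "control") & (grp["activation"] == "quiescent")]
        ctrl = ctrl[np.isfinite(ctrl["orr"])]
        if ctrl.empty:
            raise ValueError(f"batch {batch!r} has no quiescent control cells to normalize ORR")
        ref[batch] = ctrl["orr"].mean()
    records["orr_norm"] = records["orr"] / records[batch_col].map(ref)
    return records


def _label_mean(values: np.ndarray, labels: np.ndarray, valid: np.ndarray,
                n_labels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-label mean of `values` over `valid` pixels; returns (means, counts)."""
    lab = labels[valid]
    v = values[valid]
    counts = np.bincount(lab, minlength=n_labels + 1)[1:]
    sums = np.bincount(lab, weights=v, minlength=n_labels + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def aggregate_cell_features(
    nadh_fit: FitImageResult,
    fad_fit: FitImageResult,
    nadh_intensity: np.ndarray,
    fad_intensity: np.ndarray,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    condition: str,
    batch_id: str = "batch0",
    cd69_positive: dict[int, bool] | None = None,
    chi2_max: float = 1.3,
) -> pd.DataFrame:
    """Average pixel fits over each cell's cytoplasm into CellRecord rows.

    Lifetime variables are unweighted means over cytoplasm pixels that
    converged and satisfy the pixel-level chi-square rule (chi2 <= 1.3),
    applied before averaging. Amplitude fractions are reported as
    normalized percentages. ``photons`` is the summed NAD(P)H count over
    the cytoplasm; ``area_px`` is the whole-cell pixel count; the ORR is
    the ratio of cytoplasm mean intensities. Cells whose valid-pixel set
    is empty keep their row with NaN features so QC can count them.
    """
    cell_labels = np.asarray(cell_labels)
    n_labels = int(cell_labels.max())
    cyto = (cell_labels > 0) & (np.asarray(nucleus_labels) == 0)
    cyto_labels = np.where(cyto, cell_labels, 0).astype(np.intp)

    whole_area = np.bincount(cell_labels.ravel().astype(np.intp), minlength=n_labels + 1)[1:]
    out: dict[str, np.ndarray] = {}
    n_valid = {}
    for name, fit in (("nadh", nadh_fit), ("fad", fad_fit)):
        valid = cyto & fit.converged & (fit.chi2 <= chi2_max) & np.isfinite(fit.tau_m)
        for var, col in (("tau_m", "tm"), ("tau1", "tau1"), ("tau2", "tau2"), ("a1", "a1"),
                         ("chi2", "chi2")):
            vals = np.nan_to_num(getattr(fit, var).astype(float), nan=0.0)
            means, counts = _label_mean(vals, cyto_labels, valid, n_labels)
            out[f"{name}_{col}"] = means
        out[f"{name}_a1"] = out[f"{name}_a1"] * 100.0  # normalized fraction -> %
        n_valid[name] = counts

    nadh_int_mean, cyto_counts = _label_mean(
        np.asarray(nadh_intensity, float), cyto_labels, cyto, n_labels
    )
    fad_int_mean, _ = _label_mean(np.asarray(fad_intensity, float), cyto_labels, cyto, n_labels)
    photon_sums = np.bincount(
        cyto_labels[cyto], weights=np.asarray(nadh_intensity, float)[cyto],
        minlength=n_labels + 1,
    )[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        orr = nadh_int_mean / (nadh_int_mean + fad_int_mean)

    ids = np.arange(1, n_labels + 1)
    present = whole_area > 0
    cd69 = np.array(
        [bool(cd69_positive.get(int(i), False)) if cd69_positive else False for i in ids]
    )
    table = pd.DataFrame(
        {
            "cell_id": ids,
            "batch_id": batch_id,
            "condition": condition,
            "cd69_positive": cd69,
            "activation": [label_activation(condition, c) for c in cd69],
            "nadh_tm": out["nadh_tm"], "nadh_tau1": out["nadh_tau1"],
            "nadh_tau2": out["nadh_tau2"], "nadh_a1": out["nadh_a1"],
            "fad_tm": out["fad_tm"], "fad_tau1": out["fad_tau1"],
            "fad_tau2": out["fad_tau2"], "fad_a1": out["fad_a1"],
            "orr": orr,
            "photons": photon_sums,
            "area_px": whole_area,
            "chi2_mean": (out["nadh_chi2"] + out["fad_chi2"]) / 2.0,
            "n_valid_pixels": np.minimum(n_valid["nadh"], n_valid["fad"]),
        }
    )
    table = table[present].reset_index(drop=True)
    n_empty = int((table["n_valid_pixels"] == 0).sum())
    if n_empty:
        log.info("%d cells have no converged chi2-passing cytoplasm pixels", n_empty)
    return table


def apply_qc_filters(
    table: pd.DataFrame,
    min_photons: float = 5000.0,
    min_area_px: int = 250,
    max_chi2: float = 1.3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cell-level quality control.

    Removes cells with fewer than ``min_photons`` NAD(P)H photons or
    whole-cell masks under ``min_area_px`` pixels. The chi-square rule acts
    at pixel level during aggregation; here it removes cells left without
    any valid pixel (``n_valid_pixels == 0`` or NaN features), or — for
    tables built without pixel data — cells whose mean chi2 exceeds
    ``max_chi2``. Returns the retained table and per-rule exclusion counts;
    each excluded cell is counted once, in the order photons, area, chi2.
    """
    photons_bad = table["photons"] < min_photons
    area_bad = table["area_px"] < min_area_px
    if "n_valid_pixels" in table.columns:
        chi2_bad = (table["n_valid_pixels"] == 0) | ~np.isfinite(table["nadh_tm"])
    else:
        chi2_bad = table["chi2_mean"] > max_chi2
    counts = {
        "photons": int(photons_bad.sum()),
        "area": int((area_bad & ~photons_bad).sum()),
        "chi2": int((chi2_bad & ~photons_bad & ~area_bad).sum()),
    }
    keep = ~(photons_bad | area_bad | chi2_bad)
    return table.loc[keep].reset_index(drop=True), counts
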