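"""Nuclear protein-gradient quantification.

Nuclei are segmented from a smoothed reference channel (DAPI or Histone-RFP),
measured in both channels, corrected for depth-dependent signal attenuation
using the nominally uniform Histone-RFP channel, background-subtracted using
posterior (85-95% EL) nuclei, and reduced to binned AP profiles with an
exponential amplitude/decay-length fit per nuclear cycle.

The physical picture: nuclear Bcd-GFP follows A * exp(-(x/L)/lambda) with a
length constant lambda of about 0.15 EL in fixed tissue; the Histone-RFP
signal is position-independent, so any systematic variation of its mean with
imaging depth measures optical attenuation common to both channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .stack import ImageStack


@dataclass
class GradientProfile:
    cycle: int
    bin_centers: np.ndarray
    binned_mean: np.ndarray
    binned_sd: np.ndarray
    binned_n: np.ndarray
    amplitude: float = np.nan  # fitted value at x/L = 0
    decay_length_el: float = np.nan
    fit_valid: bool = False


# ---------------------------------------------------------------------------
# segmentation and measurement
# ---------------------------------------------------------------------------

def segment_nuclei(
    stack: ImageStack,
    stage: int,
    smooth_sigma: float = 1.5,
    min_volume_frac: float = 0.3,
    watershed_min_separation_px: float = 6.0,
) -> np.ndarray:
    """Label nuclei in a single-channel stack.

    Gaussian smoothing, global Otsu threshold, 3D connected-component
    labeling; at blastoderm stages (>= 10) a distance-transform watershed
    splits touching objects. Objects smaller than ``min_volume_frac`` of the
    median object volume are discarded.
    """
    v = ndimage.gaussian_filter(stack.voxels, (smooth_sigma / 2.0, smooth_sigma, smooth_sigma))
    if v.max() <= 0 or np.ptp(v) == 0:
        return np.zeros(stack.shape, dtype=int)
    thr = threshold_otsu(v)
    mask = v > thr
    if not mask.any():
        return np.zeros(stack.shape, dtype=int)

    if stage >= 10:
        dist = ndimage.distance_transform_edt(mask)
        sm = ndimage.gaussian_filter(dist, 1.0)
        maxf = ndimage.maximum_filter(sm, size=int(watershed_min_separation_px) | 1)
        peaks = (sm == maxf) & mask & (sm > 0.5)
        markers, _ = ndimage.label(peaks)
        labels = watershed(-sm, markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)

    # volume screen
    ids, volumes = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        return labels
    min_vol = min_volume_frac * np.median(volumes)
    kill = ids[volumes < min_vol]
    if kill.size:
        labels[np.isin(labels, kill)] = 0
    # relabel consecutively
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def measure_nuclei(
    labels: np.ndarray,
    gfp: ImageStack,
    rfp: ImageStack,
    registration=None,
    depth_per_slice_um: float = 3.5,
    ap_span: tuple[float, float] | None = None,
    erode: bool = True,
) -> pd.DataFrame:
    """Per-nucleus mean channel intensities, centroid, x/L and depth.

    ``registration`` may be an AxisRegistration mapping (x, y) to x/L; for
    synthetic stacks ``ap_span=(x0, x1)`` maps the centroid x linearly onto
    [0, 1]. Depth increases with slice index from the surface at z = 0.
    By default each mask is eroded by one voxel before measuring, so that
    threshold masks extending past the true nuclear boundary do not dilute
    the means with background voxels.
    """
    if gfp.shape != rfp.shape or labels.shape != gfp.shape:
        raise ValueError("channel and label shapes must match")
    if erode:
        core = ndimage.grey_erosion(labels, size=(3, 3, 3))
        eroded = np.where(core == labels, labels, 0)
        # keep the original mask for labels the erosion would destroy
        survivors = np.unique(eroded[eroded > 0])
        labels = np.where(
            np.isin(labels, survivors), eroded, labels
        )
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        return pd.DataFrame(
            columns=["label", "x_px", "y_px", "z_slice", "ap_fraction", "depth_um",
                     "mean_gfp_raw", "mean_rfp_raw", "volume"]
        )
    mean_g = ndimage.mean(gfp.voxels, labels, ids)
    mean_r = ndimage.mean(rfp.voxels, labels, ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    volumes = ndimage.sum(np.ones_like(labels), labels, ids)
    z, y, x = (np.array([c[i] for c in centroids]) for i in range(3))

    if registration is not None:
        ax, ay = registration.anterior_xy
        px, py = registration.posterior_xy
        ux, uy = registration.um_per_px
        a_vec = np.array([(px - ax) * ux, (py - ay) * uy])
        L = np.linalg.norm(a_vec)
        ap = ((x - ax) * ux * a_vec[0] + (y - ay) * uy * a_vec[1]) / L**2
    else:
        nx = labels.shape[2]
        x0, x1 = ap_span if ap_span is not None else (0.0, nx - 1.0)
        ap = (x - x0) / (x1 - x0)
    ap = np.clip(ap, 0.0, 1.0)

    return pd.DataFrame(
        dict(
            label=ids,
            x_px=x, y_px=y, z_slice=z,
            ap_fraction=ap,
            depth_um=z * depth_per_slice_um,
            mean_gfp_raw=mean_g,
            mean_rfp_raw=mean_r,
            volume=volumes,
        )
    )


# ---------------------------------------------------------------------------
# attenuation correction and background subtraction
# ---------------------------------------------------------------------------

def attenuation_correct(records: pd.DataFrame, n_depth_bins: int = 8) -> pd.DataFrame:
    """Undo depth attenuation of GFP using the uniform RFP channel.

    The default smooth monotone curve is an exponential fit (log-linear
    least squares) to mean RFP versus depth; if the exponential describes
    the binned medians poorly (non-exponential but monotone attenuation), a
    monotone-enforced interpolation of the binned medians is used instead,
    with a warning. The correction factor is curve(reference)/curve(depth)
    with the reference depth taken as the mean depth of the shallowest
    decile, so near-surface nuclei are left essentially unchanged.
    """
    if len(records) < 10:
        raise ValueError("need >= 10 nuclei spanning a depth range")
    rec = records.copy()
    depth = rec["depth_um"].to_numpy()
    rfp = rec["mean_rfp_raw"].to_numpy()
    ref_depth = float(depth[depth <= np.quantile(depth, 0.1)].mean())

    edges = np.linspace(depth.min(), depth.max() + 1e-9, n_depth_bins + 1)
    idx = np.clip(np.digitize(depth, edges) - 1, 0, n_depth_bins - 1)
    centers, medians = [], []
    for b in range(n_depth_bins):
        sel = idx == b
        if sel.sum() >= 2:
            centers.append(depth[sel].mean())
            medians.append(np.median(rfp[sel]))
    curve = _exp_curve(depth, rfp)
    if len(centers) >= 4:
        centers = np.array(centers)
        medians = np.array(medians)
        resid = np.abs(curve(centers) - medians) / np.maximum(medians, 1e-12)
        if np.max(resid) > 0.2:
            warnings.warn(
                "RFP-depth relation is not exponential; using monotone binned medians",
                stacklevel=2,
            )
            mono = np.minimum.accumulate(medians)
            curve = lambda d: np.interp(d, centers, mono)

    factor = curve(ref_depth) / np.maximum(curve(depth), 1e-12)
    rec["attenuation_factor"] = factor
    rec["mean_gfp_corrected"] = rec["mean_gfp_raw"] * factor
    rec["mean_rfp_corrected"] = rec["mean_rfp_raw"] * factor
    return rec


def _exp_curve(depth: np.ndarray, rfp: np.ndarray):
    good = rfp > 0
    slope, intercept = np.polyfit(depth[good], np.log(rfp[good]), 1)
    return lambda d: np.exp(intercept + slope * np.asarray(d, dtype=float))


def subtract_background(
    records: pd.DataFrame,
    posterior_window: tuple[float, float] = (0.85, 0.95),
    background: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Subtract the autofluorescence background from corrected GFP means.

    The background is the mean corrected GFP over nuclei at 85-95% EL, where
    the Bcd gradient has decayed to nothing; negatives are clipped to zero.
    """
    rec = records.copy()
    if background is None:
        sel = rec["ap_fraction"].between(*posterior_window)
        if not sel.any():
            raise ValueError(
                "no nuclei in the posterior window; pass an explicit background value"
            )
        background = float(rec.loc[sel, "mean_gfp_corrected"].mean())
    vals = rec["mean_gfp_corrected"] - background
    rec["n_clipped"] = int((vals < 0).sum())
    rec["mean_gfp_corrected"] = vals.clip(lower=0.0)
    return rec, background


# ---------------------------------------------------------------------------
# profile extraction and fitting
# ---------------------------------------------------------------------------

def fit_exponential(
    x: np.ndarray,
    y: np.ndarray,
    window: tuple[float, float] = (0.1, 0.7),
    weights: np.ndarray | None = None,
    min_points: int = 5,
) -> tuple[float, float, bool]:
    """Weighted log-linear fit y ~ A * exp(-x/lambda) over a window.

    Returns (amplitude at x=0, decay length, valid flag). Only strictly
    positive y enter the fit; weights default to y^2 (equalizing relative
    errors on the log scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = (x >= window[0]) & (x <= window[1]) & (y > 0) & np.isfinite(y)
    if sel.sum() < min_points:
        return np.nan, np.nan, False
    w = (y[sel] ** 2) if weights is None else np.asarray(weights, dtype=float)[sel]
    coef = np.polyfit(x[sel], np.log(y[sel]), 1, w=np.sqrt(w))
    slope, intercept = coef
    if slope >= 0:
        return float(np.exp(intercept)), np.inf, False
    return float(np.exp(intercept)), float(-1.0 / slope), True


def extract_profile(
    records: pd.DataFrame,
    n_bins: int = 50,
    cycle: int = 0,
    fit_window: tuple[float, float] = (0.1, 0.7),
) -> GradientProfile:
    """Binned AP profile of corrected nuclear GFP with an exponential fit."""
    if len(records) < 20:
        raise ValueError("need >= 20 nuclei for a profile")
    ap = records["ap_fraction"].to_numpy()
    g = records["mean_gfp_corrected"].to_numpy()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.floor(ap * n_bins).astype(int), 0, n_bins - 1)
    n = np.bincount(idx, minlength=n_bins).astype(float)
    s = np.bincount(idx, weights=g, minlength=n_bins)
    s2 = np.bincount(idx, weights=g**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, s2 / np.maximum(n, 1) - mean**2, 0.0)
    sd = np.sqrt(np.clip(var, 0.0, None))
    centers = (edges[:-1] + edges[1:]) / 2.0

    amp, lam, ok = fit_exponential(centers, np.nan_to_num(mean), window=fit_window)
    return GradientProfile(
        cycle=cycle,
        bin_centers=centers,
        binned_mean=mean,
        binned_sd=sd,
        binned_n=n,
        amplitude=amp,
        decay_length_el=lam,
        fit_valid=ok,
    )


def amplitude_timeseries(profiles: list[GradientProfile]) -> pd.DataFrame:
    """Per-bin normalization by the developmental maximum, plus an amplitude
    trajectory across nuclear cycles."""
    if len(profiles) < 2:
        raise ValueError("need profiles from >= 2 cycles")
    cycles = [p.cycle for p in profiles]
    grid = np.stack([np.nan_to_num(p.binned_mean) for p in profiles])
    per_bin_max = grid.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(per_bin_max > 0, grid / np.maximum(per_bin_max, 1e-300), np.nan)
    rows = []
    for i, p in enumerate(profiles):
        rows.append(
            dict(
                cycle=cycles[i],
                amplitude=p.amplitude,
                decay_length_el=p.decay_length_el,
                mean_normalized=float(np.nanmean(normalized[i][per_bin_max > 0])),
            )
        )
    df = pd.DataFrame(rows)
    df.attrs["normalized_grid"] = normalized
    return df
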