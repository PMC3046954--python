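"""Stack conditioning: z-slice realignment and photon-gain normalization.

Two corrections precede particle detection. First, stage drift in the
xy-plane is undone by shifting successive z-slices so that the pixel-wise
intensity cross-correlation between neighboring slices is maximal
(integer-pixel shifts; detection refits subpixel positions later). Second,
each slice is converted to photon-equivalent units using the mean-variance
relation of small image patches: for Poisson-dominated shot noise the slope
of patch variance against patch mean is the raw-units-per-photon conversion
factor of that slice. After normalization a single detection threshold works
across stacks regardless of acquisition gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stack import ImageStack


@dataclass
class GainFit:
    """Linear mean-variance fit for one slice: variance = slope*mean + intercept."""

    slope: float
    intercept: float
    n_patches: int
    r_squared: float


def realign_stack(stack: ImageStack, max_shift: int = 5) -> ImageStack:
    """Undo xy stage drift by cumulative integer shifts from slice 0 outward.

    Each slice is aligned to its (already aligned) predecessor by exhaustive
    integer search over ±max_shift; content shifted out of frame is padded
    with the slice median. Offsets are recorded on the returned stack.
    """
    v = stack.voxels
    nz = v.shape[0]
    if nz < 2:
        raise ValueError("realignment requires at least 2 slices")
    aligned = np.empty_like(v)
    aligned[0] = v[0]
    offsets = np.zeros((nz, 2), dtype=int)
    for z in range(1, nz):
        # per-step shift between successive raw slices, accumulated outward
        dy, dx = _best_shift(v[z - 1], v[z], max_shift)
        if max(abs(dy), abs(dx)) == max_shift:
            warnings.warn(
                f"slice {z}: best shift at the ±{max_shift} px search-window "
                "boundary; possible unbounded drift",
                stacklevel=2,
            )
        offsets[z] = offsets[z - 1] + (dy, dx)
        aligned[z] = _apply_shift(v[z], *offsets[z])
    out = stack.copy()
    out.voxels = aligned
    out.per_slice_offsets = offsets
    return out


def _best_shift(ref: np.ndarray, img: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (dy, dx) maximizing the cross-correlation of ``img`` shifted
    onto ``ref`` over a fixed interior window.

    Both slices are lightly smoothed and mean-subtracted first so that the
    correlation is driven by shared image structure rather than by pixel
    noise; ties (within numerical noise) prefer the smaller shift.
    """
    from scipy import ndimage

    m = max_shift
    ref_s = ndimage.gaussian_filter(ref, 2.0)
    img_s = ndimage.gaussian_filter(img, 2.0)
    core = ref_s[m:-m, m:-m]
    core = core - core.mean()
    ny, nx = ref.shape
    shifts = sorted(
        ((dy, dx) for dy in range(-m, m + 1) for dx in range(-m, m + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), s),
    )
    best, best_val = (0, 0), -np.inf
    for dy, dx in shifts:  # smaller shifts first: strict improvement required
        win = img_s[m - dy : ny - m - dy, m - dx : nx - m - dx]
        val = float(np.dot(core.ravel(), (win - win.mean()).ravel()))
        margin = 0.0 if not np.isfinite(best_val) else 1e-9 * max(abs(best_val), 1.0)
        if val > best_val + margin:
            best_val, best = val, (dy, dx)
    return best


def _apply_shift(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.full_like(img, np.median(img))
    ny, nx = img.shape
    ys = slice(max(0, dy), min(ny, ny + dy))
    xs = slice(max(0, dx), min(nx, nx + dx))
    ys_src = slice(max(0, -dy), min(ny, ny - dy))
    xs_src = slice(max(0, -dx), min(nx, nx - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def estimate_gain(
    stack: ImageStack,
    n_patches: int = 20_000,
    patch_size: int = 5,
    seed: int = 0,
    per_slice: bool = True,
    x_range: tuple[float, float] = (0.6, 1.0),
) -> list[GainFit] | GainFit:
    """Estimate the raw-to-photon conversion from patch mean-variance slopes.

    Randomly placed patch_size x patch_size patches are drawn from each slice
    (or pooled over the stack when ``per_slice=False``); a least-squares line
    through (patch mean, patch variance) pairs gives the slope, i.e. the gain.
    Patches are restricted to the posterior ``x_range`` (fractions of the
    slice width) so that bright anterior particles, whose spatial structure
    is not shot noise, do not bias the slope; pass (0, 1) to use the whole
    slice.
    """
    if patch_size < 3:
        raise ValueError("patch_size must be >= 3")
    nz, ny, nx = stack.shape
    if patch_size > min(ny, nx):
        raise ValueError("patches must fit inside a slice")
    rng = np.random.default_rng(seed)
    x_lo = int(x_range[0] * nx)
    x_hi = max(x_lo + patch_size, int(x_range[1] * nx))

    def fit_slices(slices: np.ndarray) -> GainFit:
        means, variances = [], []
        for sl in slices:
            n_avail = (ny // patch_size) * ((x_hi - x_lo) // patch_size)
            k = min(n_patches, max(n_avail, 1))
            ys = rng.integers(0, ny - patch_size + 1, k)
            xs = rng.integers(x_lo, x_hi - patch_size + 1, k)
            patches = np.stack(
                [sl[y : y + patch_size, x : x + patch_size].ravel() for y, x in zip(ys, xs)]
            )
            means.append(patches.mean(axis=1))
            variances.append(patches.var(axis=1, ddof=1))
        m = np.concatenate(means)
        var = np.concatenate(variances)
        if np.ptp(m) < 1e-12 or np.all(var < 1e-12):
            raise ValueError("degenerate gain fit: image has no intensity variation")
        # robust line: patches containing particles have structured variance
        # far above the shot-noise line and are rejected iteratively
        keep = np.ones(m.size, dtype=bool)
        for _ in range(3):
            slope, intercept = np.polyfit(m[keep], var[keep], 1)
            resid = var - (slope * m + intercept)
            mad = np.median(np.abs(resid[keep])) + 1e-12
            new_keep = np.abs(resid) < 6.0 * 1.4826 * mad
            if new_keep.sum() < max(10, 0.2 * m.size) or np.array_equal(new_keep, keep):
                break
            keep = new_keep
        pred = slope * m + intercept
        m, var = m[keep], var[keep]
        pred = pred[keep]
        ss_res = float(np.sum((var - pred) ** 2))
        ss_tot = float(np.sum((var - var.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return GainFit(float(slope), float(intercept), int(m.size), r2)

    if per_slice:
        return [fit_slices(stack.voxels[z : z + 1]) for z in range(nz)]
    return fit_slices(stack.voxels)


def gains_from_fits(fits: list[GainFit], smooth: bool = True, window: int = 5) -> np.ndarray:
    """Per-slice gain profile from fits, optionally smoothed with a moving
    median (the conversion factor changes slowly and systematically with z)."""
    g = np.array([f.slope for f in fits], dtype=float)
    if smooth and g.size >= 3:
        half = window // 2
        sm = np.array(
            [np.median(g[max(0, i - half) : min(g.size, i + half + 1)]) for i in range(g.size)]
        )
        g = sm
    return g


def normalize_slices(stack: ImageStack, gains: np.ndarray | float) -> ImageStack:
    """Divide every slice by its gain, yielding photon-equivalent units."""
    nz = stack.n_slices
    g = np.broadcast_to(np.atleast_1d(np.asarray(gains, dtype=float)), (nz,))
    if np.any(g <= 0):
        raise ValueError("all gains must be positive")
    out = stack.copy()
    out.voxels = stack.voxels / g[:, None, None]
    out.per_slice_gain = np.ones(nz)
    return out


def preprocess(stack: ImageStack, max_shift: int = 5, n_patches: int = 5000,
               patch_size: int = 5, seed: int = 0) -> ImageStack:
    """Convenience composition: realign, estimate per-slice gains, normalize."""
    aligned = realign_stack(stack, max_shift=max_shift)
    fits = estimate_gain(aligned, n_patches=n_patches, patch_size=patch_size, seed=seed)
    gains = gains_from_fits(fits)
    return normalize_slices(aligned, gains)
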