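"""Single-particle calling: DoG filtering, shadow linking, Gaussian fitting.

The detection chain mirrors standard practice for diffraction-limited spot
calling in confocal stacks:

1. every z-slice is band-passed with a *balanced* circular
   difference-of-Gaussians (DoG) filter matched to the particle size, so a
   constant background gives exactly zero response;
2. strict local maxima of the filtered slices above a single photon-unit
   threshold become candidate particles;
3. because the axial PSF extends over neighboring slices, a true particle
   appears as a column of candidates at the same xy position ("shadows");
   candidates are linked brightest-first and only the central detection of
   each column survives, carrying its shadow count;
4. each surviving candidate is fit with a 2D elliptical Gaussian plus a
   constant offset on a 9x9 pixel patch; candidates sharing a patch are fit
   jointly (sum of Gaussians, one shared offset) so overlapping particles
   get unbiased radii and amplitudes;
5. acceptance filters reject implausible fits: radii outside [0.7, 2.5] px,
   amplitude below the local offset, or fewer than 1 shadow.

Particle intensity is defined as amplitude * r_x * r_y (proportionality
constant 1); the radii r_x, r_y are Gaussian sigmas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .stack import ImageStack

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


@dataclass
class DoGParams:
    center_radius_px: float = 1.5
    surround_radius_px: float = 2.5
    threshold: float = 150.0  # in photon-normalized units

    def __post_init__(self) -> None:
        if not (0 < self.center_radius_px < self.surround_radius_px):
            raise ValueError("require 0 < center radius < surround radius")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class Candidate:
    x_px: int
    y_px: int
    z_slice: int
    dog_value: float
    processed: bool = False


@dataclass
class FilterCriteria:
    r_min: float = 0.7
    r_max: float = 2.5
    require_amplitude_gt_offset: bool = True
    min_shadows: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError("require 0 < r_min < r_max")


@dataclass
class FittedParticle:
    x_c: float
    y_c: float
    z_slice: int
    r_x: float  # major axis sigma, px
    r_y: float  # minor axis sigma, px
    theta: float  # orientation of r_x axis vs horizontal, radians
    offset: float
    amplitude: float
    n_shadows: int
    dog_value: float = np.nan
    converged: bool = True
    accepted: bool | None = None
    reject_reason: str = ""

    @property
    def intensity(self) -> float:
        return self.amplitude * self.r_x * self.r_y

    @property
    def eccentricity(self) -> float:
        return abs(self.r_x - self.r_y) / (self.r_x + self.r_y)

    @property
    def diameter(self) -> float:
        """Reported size statistic: mean FWHM of the two axes, in px."""
        return FWHM_PER_SIGMA * (self.r_x + self.r_y) / 2.0


# ---------------------------------------------------------------------------
# DoG filtering and candidate finding
# ---------------------------------------------------------------------------

def dog_filter(image: np.ndarray, params: DoGParams | None = None) -> np.ndarray:
    """Balanced circular difference-of-Gaussians band-pass of a 2D slice.

    Both component Gaussians are unit-sum, so the response to any constant
    image is identically zero.
    """
    if params is None:
        params = DoGParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dog_filter expects a 2D slice")
    lo = ndimage.gaussian_filter(img, params.center_radius_px, mode="reflect", truncate=4.0)
    hi = ndimage.gaussian_filter(img, params.surround_radius_px, mode="reflect", truncate=4.0)
    return lo - hi


def dog_filter_stack(stack: ImageStack, params: DoGParams | None = None) -> np.ndarray:
    return np.stack([dog_filter(sl, params) for sl in stack.voxels])


def find_candidates(filtered: np.ndarray, params: DoGParams | None = None) -> list[Candidate]:
    """Per-slice strict local maxima (8-neighborhood) above the threshold.

    Plateaus contribute a single candidate at their lexicographically
    smallest (z, y, x) coordinate. The result is sorted by descending DoG
    value (ties broken by coordinate) as required by shadow linking.
    """
    if params is None:
        params = DoGParams()
    out: list[Candidate] = []
    for z, sl in enumerate(filtered):
        maxf = ndimage.maximum_filter(sl, size=3, mode="nearest")
        mask = (sl >= params.threshold) & (sl == maxf)
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)
        for y, x in ndimage.minimum_position(
            np.broadcast_to(np.arange(sl.shape[1]), sl.shape)
            + np.arange(sl.shape[0])[:, None] * sl.shape[1],
            labels,
            index=range(1, n + 1),
        ) if n else []:
            out.append(Candidate(int(x), int(y), int(z), float(sl[y, x])))
    out.sort(key=lambda c: (-c.dog_value, c.z_slice, c.y_px, c.x_px))
    return out


# ---------------------------------------------------------------------------
# shadow linking
# ---------------------------------------------------------------------------

def link_shadows(
    candidates: list[Candidate],
    xy_radius_px: float = 2.0,
    z_window: int = 2,
) -> list[tuple[Candidate, int]]:
    """Collapse axial candidate columns into central detections.

    Iterating brightest-first, candidates on other slices within z_window
    and within xy_radius are marked as shadows of the current candidate and
    removed from further consideration. Returns (candidate, n_shadows) pairs
    for the surviving central candidates.
    """
    if not candidates:
        return []
    by_slice: dict[int, list[int]] = {}
    for i, c in enumerate(candidates):
        by_slice.setdefault(c.z_slice, []).append(i)
    trees = {
        z: cKDTree(np.array([[candidates[i].x_px, candidates[i].y_px] for i in idx]))
        for z, idx in by_slice.items()
    }
    taken = np.zeros(len(candidates), dtype=bool)
    result = []
    for i, c in enumerate(candidates):  # already sorted brightest-first
        if taken[i]:
            continue
        taken[i] = True
        n_shadows = 0
        for dz in range(-z_window, z_window + 1):
            if dz == 0:
                continue
            z = c.z_slice + dz
            if z not in trees:
                continue
            hits = trees[z].query_ball_point([c.x_px, c.y_px], xy_radius_px)
            for h in hits:
                j = by_slice[z][h]
                if not taken[j]:
                    taken[j] = True
                    candidates[j].processed = True
                    n_shadows += 1
        result.append((c, n_shadows))
    return result


# ---------------------------------------------------------------------------
# Gaussian fitting
# ---------------------------------------------------------------------------

def _gauss2d(params, xx, yy):
    xc, yc, rx, ry, theta, amp = params
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - xc) * ct + (yy - yc) * st
    yr = -(xx - xc) * st + (yy - yc) * ct
    return amp * np.exp(-(xr**2 / (2 * rx**2) + yr**2 / (2 * ry**2)))


def _canonical_axes(rx: float, ry: float, theta: float) -> tuple[float, float, float]:
    """Reorder so r_x >= r_y (major/minor) and wrap theta into [-pi/2, pi/2)."""
    if ry > rx:
        rx, ry = ry, rx
        theta = theta + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    return rx, ry, theta


_R_BOUNDS = (0.3, 5.0)
_INIT_R = 1.3


def fit_particle(
    patch: np.ndarray,
    cx: float,
    cy: float,
    n_shadows: int = 0,
    dog_value: float = np.nan,
    z_slice: int = 0,
) -> FittedParticle:
    """Fit offset + elliptical Gaussian to a patch around one candidate.

    (cx, cy) is the candidate position in patch coordinates; the returned
    center is in the same frame.
    """
    patch = np.asarray(patch, dtype=float)
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    med = float(np.median(patch))
    amp0 = max(float(patch.max()) - med, 1e-6)

    def resid(p):
        offset = p[6]
        return (offset + _gauss2d(p[:6], xx, yy) - patch).ravel()

    p0 = [cx, cy, _INIT_R, _INIT_R, 0.0, amp0, med]
    lb = [cx - 3, cy - 3, _R_BOUNDS[0], _R_BOUNDS[0], -np.pi, 0.0, -np.inf]
    ub = [cx + 3, cy + 3, _R_BOUNDS[1], _R_BOUNDS[1], np.pi, np.inf, np.inf]
    res = least_squares(resid, p0, bounds=(lb, ub), max_nfev=400)
    xc, yc, rx, ry, theta, amp, offset = res.x
    rx, ry, theta = _canonical_axes(rx, ry, theta)
    return FittedParticle(
        x_c=float(xc), y_c=float(yc), z_slice=z_slice,
        r_x=float(rx), r_y=float(ry), theta=float(theta),
        offset=float(offset), amplitude=float(amp),
        n_shadows=n_shadows, dog_value=dog_value,
        converged=bool(res.success),
    )


MAX_JOINT_COMPONENTS = 6
_MERGE_RADIUS_PX = 0.6


def joint_fit(
    patch: np.ndarray,
    centers: list[tuple[float, float]],
    n_shadows: list[int] | None = None,
    dog_values: list[float] | None = None,
    z_slice: int = 0,
) -> list[FittedParticle]:
    """Simultaneously fit several Gaussians plus one shared offset.

    Candidates whose initial centers (or fitted centers) coincide within
    ~0.6 px are merged into one component. Falls back to independent single
    fits if the joint optimization fails to converge.
    """
    patch = np.asarray(patch, dtype=float)
    k = len(centers)
    if n_shadows is None:
        n_shadows = [0] * k
    if dog_values is None:
        dog_values = [np.nan] * k

    # pre-fit dedupe of coincident candidates
    keep: list[int] = []
    for i, (x, y) in enumerate(centers):
        if all(np.hypot(x - centers[j][0], y - centers[j][1]) > _MERGE_RADIUS_PX for j in keep):
            keep.append(i)
    centers = [centers[i] for i in keep]
    n_shadows = [n_shadows[i] for i in keep]
    dog_values = [dog_values[i] for i in keep]
    k = len(centers)
    if k == 1:
        return [fit_particle(patch, *centers[0], n_shadows[0], dog_values[0], z_slice)]

    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    med = float(np.median(patch))

    def model(p):
        total = np.full(patch.shape, p[-1])
        for i in range(k):
            total = total + _gauss2d(p[6 * i : 6 * i + 6], xx, yy)
        return total

    p0, lb, ub = [], [], []
    for cx, cy in centers:
        amp0 = max(float(patch[int(round(cy)), int(round(cx))]) - med, 1e-6)
        p0 += [cx, cy, _INIT_R, _INIT_R, 0.0, amp0]
        lb += [cx - 3, cy - 3, _R_BOUNDS[0], _R_BOUNDS[0], -np.pi, 0.0]
        ub += [cx + 3, cy + 3, _R_BOUNDS[1], _R_BOUNDS[1], np.pi, np.inf]
    p0.append(med)
    lb.append(-np.inf)
    ub.append(np.inf)

    res = least_squares(lambda p: (model(p) - patch).ravel(), p0, bounds=(lb, ub), max_nfev=800)
    if not res.success:
        return [
            fit_particle(patch, cx, cy, ns, dv, z_slice)
            for (cx, cy), ns, dv in zip(centers, n_shadows, dog_values)
        ]
    offset = float(res.x[-1])
    fitted = []
    for i in range(k):
        xc, yc, rx, ry, theta, amp = res.x[6 * i : 6 * i + 6]
        rx, ry, theta = _canonical_axes(rx, ry, theta)
        fitted.append(
            FittedParticle(
                x_c=float(xc), y_c=float(yc), z_slice=z_slice,
                r_x=float(rx), r_y=float(ry), theta=float(theta),
                offset=offset, amplitude=float(amp),
                n_shadows=n_shadows[i], dog_value=dog_values[i],
            )
        )
    # post-fit merge of components that collapsed onto each other
    merged: list[FittedParticle] = []
    for f in sorted(fitted, key=lambda f: -f.amplitude):
        if all(np.hypot(f.x_c - g.x_c, f.y_c - g.y_c) > _MERGE_RADIUS_PX for g in merged):
            merged.append(f)
    return merged


# ---------------------------------------------------------------------------
# acceptance filtering and the end-to-end pipeline
# ---------------------------------------------------------------------------

def apply_filters(
    particles: list[FittedParticle],
    criteria: FilterCriteria | None = None,
) -> tuple[list[FittedParticle], dict]:
    """Apply the acceptance criteria; returns (accepted, rejection counts)."""
    if criteria is None:
        criteria = FilterCriteria()
    counts = {"radius": 0, "amplitude": 0, "shadows": 0, "non_converged": 0, "accepted": 0}
    accepted = []
    for p in particles:
        reason = ""
        if not p.converged:
            reason = "non_converged"
        elif not (criteria.r_min < p.r_x < criteria.r_max and criteria.r_min < p.r_y < criteria.r_max):
            reason = "radius"
        elif criteria.require_amplitude_gt_offset and not (p.amplitude > p.offset):
            reason = "amplitude"
        elif p.n_shadows < criteria.min_shadows:
            reason = "shadows"
        p.reject_reason = reason
        p.accepted = reason == ""
        if p.accepted:
            counts["accepted"] += 1
            accepted.append(p)
        else:
            counts[reason] += 1
    return accepted, counts


_PATCH_HALF = 4  # 9x9 patches
_GROUP_RADIUS = 8.0  # candidates closer than this on a slice share a joint fit
_JOINT_MARGIN = 4


def _extract_patch(sl: np.ndarray, x0: int, x1: int, y0: int, y1: int) -> np.ndarray:
    """Clip [y0:y1, x0:x1] from a slice, reflecting across borders."""
    ny, nx = sl.shape
    pad_y = (max(0, -y0), max(0, y1 - ny))
    pad_x = (max(0, -x0), max(0, x1 - nx))
    if any(pad_y) or any(pad_x):
        sl = np.pad(sl, (pad_y, pad_x), mode="reflect")
        y0, y1 = y0 + pad_y[0], y1 + pad_y[0]
        x0, x1 = x0 + pad_x[0], x1 + pad_x[0]
    return sl[y0:y1, x0:x1]


def _fit_all(stack_voxels: np.ndarray, survivors: list[tuple[Candidate, int]]) -> list[FittedParticle]:
    """Group surviving candidates per slice and run single or joint fits."""
    particles: list[FittedParticle] = []
    by_slice: dict[int, list[tuple[Candidate, int]]] = {}
    for c, ns in survivors:
        by_slice.setdefault(c.z_slice, []).append((c, ns))

    for z, items in sorted(by_slice.items()):
        pts = np.array([[c.x_px, c.y_px] for c, _ in items], dtype=float)
        # union-find grouping of candidates within the same prospective patch
        parent = list(range(len(items)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(pts)
        for i, j in tree.query_pairs(_GROUP_RADIUS):
            parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(items)):
            groups.setdefault(find(i), []).append(i)

        sl = stack_voxels[z]
        for idx in groups.values():
            if len(idx) == 1:
                c, ns = items[idx[0]]
                patch = _extract_patch(
                    sl, c.x_px - _PATCH_HALF, c.x_px + _PATCH_HALF + 1,
                    c.y_px - _PATCH_HALF, c.y_px + _PATCH_HALF + 1,
                )
                f = fit_particle(patch, _PATCH_HALF, _PATCH_HALF, ns, c.dog_value, z)
                f.x_c += c.x_px - _PATCH_HALF
                f.y_c += c.y_px - _PATCH_HALF
                particles.append(f)
            else:
                idx = sorted(idx, key=lambda i: -items[i][0].dog_value)
                joint_idx = idx[:MAX_JOINT_COMPONENTS]
                single_idx = idx[MAX_JOINT_COMPONENTS:]
                xs = [items[i][0].x_px for i in joint_idx]
                ys = [items[i][0].y_px for i in joint_idx]
                x0, x1 = min(xs) - _JOINT_MARGIN, max(xs) + _JOINT_MARGIN + 1
                y0, y1 = min(ys) - _JOINT_MARGIN, max(ys) + _JOINT_MARGIN + 1
                patch = _extract_patch(sl, x0, x1, y0, y1)
                fits = joint_fit(
                    patch,
                    centers=[(x - x0, y - y0) for x, y in zip(xs, ys)],
                    n_shadows=[items[i][1] for i in joint_idx],
                    dog_values=[items[i][0].dog_value for i in joint_idx],
                    z_slice=z,
                )
                for f in fits:
                    f.x_c += x0
                    f.y_c += y0
                particles.extend(fits)
                for i in single_idx:
                    c, ns = items[i]
                    patch = _extract_patch(
                        sl, c.x_px - _PATCH_HALF, c.x_px + _PATCH_HALF + 1,
                        c.y_px - _PATCH_HALF, c.y_px + _PATCH_HALF + 1,
                    )
                    f = fit_particle(patch, _PATCH_HALF, _PATCH_HALF, ns, c.dog_value, z)
                    f.x_c += c.x_px - _PATCH_HALF
                    f.y_c += c.y_px - _PATCH_HALF
                    particles.append(f)
    return particles


def particles_to_table(particles: list[FittedParticle]) -> pd.DataFrame:
    cols = ["x_c", "y_c", "z_slice", "r_x", "r_y", "theta", "offset", "amplitude",
            "n_shadows", "intensity", "eccentricity", "diameter", "dog_value",
            "accepted", "reject_reason"]
    rows = [
        {**{c: getattr(p, c) for c in cols[:9]},
         "intensity": p.intensity, "eccentricity": p.eccentricity, "diameter": p.diameter,
         "dog_value": p.dog_value, "accepted": p.accepted, "reject_reason": p.reject_reason}
        for p in particles
    ]
    return pd.DataFrame(rows, columns=cols)


def detect(
    stack: ImageStack,
    dog_params: DoGParams | None = None,
    criteria: FilterCriteria | None = None,
    xy_radius_px: float = 2.0,
    z_window: int = 2,
    return_log: bool = False,
):
    """End-to-end particle detection on a normalized, realigned stack.

    Returns a particle table (one row per fitted candidate, with an
    ``accepted`` column) or, with ``return_log=True``, the table plus a dict
    of per-stage counts.
    """
    if dog_params is None:
        dog_params = DoGParams()
    filtered = dog_filter_stack(stack, dog_params)
    candidates = find_candidates(filtered, dog_params)
    survivors = link_shadows(candidates, xy_radius_px=xy_radius_px, z_window=z_window)
    fitted = _fit_all(stack.voxels, survivors)
    _, counts = apply_filters(fitted, criteria)
    table = particles_to_table(fitted)
    log = {
        "n_candidates": len(candidates),
        "n_after_shadow_linking": len(survivors),
        "n_fitted": len(fitted),
        "rejections": counts,
    }
    if return_log:
        return table, log
    return table
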