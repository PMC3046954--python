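"""Embryo-coordinate mapping and spatial summaries of particle fields.

Particles detected in stack pixel coordinates are projected onto the
anterior-posterior (AP) axis extracted from a low-magnification overview
(or supplied directly for synthetic data, where the generating transform is
known). The summaries reproduce the standard views of an anterior mRNA
gradient: per-bin counts and intensity along x/L, the cumulative intensity
fraction, particle density versus fractional distance from the cortex d/L,
and per-stage totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure


@dataclass
class AxisRegistration:
    """AP-axis geometry in a common pixel frame.

    ``um_per_px`` holds separate x/y scale factors so that anisotropically
    sampled synthetic stacks (x spanning the egg length, y the width) can be
    mapped into physical units before projecting.
    """

    anterior_xy: tuple[float, float]
    posterior_xy: tuple[float, float]
    L: float
    semi_minor_px: float | None = None
    um_per_px: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("axis length L must be positive")

    @property
    def length_um(self) -> float:
        ax, ay = self.anterior_xy
        px, py = self.posterior_xy
        ux, uy = self.um_per_px
        return float(np.hypot((px - ax) * ux, (py - ay) * uy))

    @classmethod
    def for_synthetic(cls, model, shape) -> "AxisRegistration":
        """Known generator transform for stacks made by synthgen (bypasses
        overview registration)."""
        from .synthgen import _MARGIN_XY  # same frame convention as the generator

        nz, ny, nx = shape
        span_x = nx - 1 - 2 * _MARGIN_XY
        span_y = ny - 1 - 2 * _MARGIN_XY
        yc = _MARGIN_XY + span_y / 2.0
        return cls(
            anterior_xy=(_MARGIN_XY, yc),
            posterior_xy=(_MARGIN_XY + span_x, yc),
            L=span_x,
            semi_minor_px=span_y / 2.0,
            um_per_px=(model.length_um / span_x, model.width_um / span_y),
        )


def extract_axis(overview: np.ndarray, threshold: float | None = None) -> AxisRegistration:
    """Locate the AP axis in a low-magnification overview image or mask.

    The embryo mask (thresholded at half-maximum unless given) must be a
    single solid elongated object; the poles are the extremal mask points
    along its principal axis.
    """
    img = np.asarray(overview, dtype=float)
    if threshold is None:
        threshold = 0.5 * img.max() if img.max() > 1 else 0.5
    mask = img > threshold
    if not mask.any():
        raise ValueError("empty embryo mask")
    labels = measure.label(mask)
    props = max(measure.regionprops(labels), key=lambda r: r.area)
    if props.solidity < 0.8:
        raise ValueError(f"mask not elliptical (solidity {props.solidity:.2f} < 0.8)")

    ys, xs = np.nonzero(labels == props.label)
    cy, cx = props.centroid
    pts = np.column_stack([xs - cx, ys - cy]).astype(float)
    cov = pts.T @ pts / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or np.sqrt(evals[1] / evals[0]) < 1.2:
        raise ValueError("mask has no principal axis (nearly circular)")
    direction = evecs[:, 1]  # (dx, dy) along the major axis
    proj = pts @ direction
    i_min, i_max = int(np.argmin(proj)), int(np.argmax(proj))
    p1 = (float(xs[i_min]), float(ys[i_min]))
    p2 = (float(xs[i_max]), float(ys[i_max]))
    # anterior = leftmost pole by convention (caller may swap)
    anterior, posterior = (p1, p2) if p1[0] <= p2[0] else (p2, p1)
    L = float(np.hypot(posterior[0] - anterior[0], posterior[1] - anterior[1]))
    return AxisRegistration(
        anterior_xy=anterior,
        posterior_xy=posterior,
        L=L,
        semi_minor_px=2.0 * float(np.sqrt(evals[0])),  # sigma of a solid ellipse is b/2
    )


def project_particles(
    table: pd.DataFrame,
    registration: AxisRegistration,
    x_col: str = "x_c",
    y_col: str = "y_c",
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Attach x/L (``ap_fraction``) and cortical distance d/L (``depth_frac``).

    x/L is the normalized projection onto the AP axis, clipped to [0, 1];
    d is the distance to the elliptical embryo outline in the midsagittal
    plane, measured along the ray from the embryo center (exact for circular
    cross-sections, a good approximation near the outline). Particles
    mapping outside the outline by more than ``tolerance`` (in units of L)
    are flagged in an ``outside_mask`` column.
    """
    out = table.copy()
    ux, uy = registration.um_per_px
    ax, ay = registration.anterior_xy
    px, py = registration.posterior_xy
    a_vec = np.array([(px - ax) * ux, (py - ay) * uy])
    L_um = np.linalg.norm(a_vec)
    a_hat = a_vec / L_um

    qx = (out[x_col].to_numpy() - ax) * ux
    qy = (out[y_col].to_numpy() - ay) * uy
    s = qx * a_hat[0] + qy * a_hat[1]
    out["ap_fraction"] = np.clip(s / L_um, 0.0, 1.0)

    if registration.semi_minor_px is not None:
        b_um = registration.semi_minor_px * uy
        a_um = L_um / 2.0
        cx_um = (ax + px) / 2.0 * ux - ax * ux
        cy_um = (ay + py) / 2.0 * uy - ay * uy
        # coordinates relative to embryo center, in the axis frame
        t = -qx * a_hat[1] + qy * a_hat[0]
        sc = s - L_um / 2.0
        rho = np.sqrt((sc / a_um) ** 2 + (t / b_um) ** 2)
        r_abs = np.hypot(sc, t)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_um = np.where(rho > 1e-9, r_abs * (1.0 / rho - 1.0), a_um)
        # signed: negative for points outside the outline
        out["depth_frac"] = d_um / L_um
        out["outside_mask"] = rho > 1.0 + tolerance
        del cx_um, cy_um
    return out


@dataclass
class APDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    intensity: np.ndarray
    mean_intensity: np.ndarray
    cumulative_intensity: np.ndarray
    empty: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def cumulative_at(self, x: float) -> float:
        """Cumulative intensity fraction at x/L = x (interpolated on edges)."""
        cum = np.concatenate([[0.0], self.cumulative_intensity])
        return float(np.interp(x, self.bin_edges, cum))


def ap_distribution(table: pd.DataFrame, n_bins: int = 50) -> APDistribution:
    """Bin particle counts and intensity along x/L; half-open bins with the
    final bin closed at 1."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if len(table) == 0:
        z = np.zeros(n_bins)
        return APDistribution(edges, z, z.copy(), z.copy(), z.copy(), empty=True)
    ap = table["ap_fraction"].to_numpy()
    inten = table["intensity"].to_numpy()
    idx = np.clip(np.floor(ap * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    intensity = np.bincount(idx, weights=inten, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_i = np.where(counts > 0, intensity / np.maximum(counts, 1), 0.0)
    total = intensity.sum()
    cumulative = np.cumsum(intensity) / total if total > 0 else np.zeros(n_bins)
    return APDistribution(edges, counts, intensity, mean_i, cumulative)


@dataclass
class DepthProfile:
    bin_edges: np.ndarray  # d/L
    counts: np.ndarray
    density: np.ndarray  # particles per unit midsagittal area (um^-2)


def depth_density(
    table: pd.DataFrame,
    registration: AxisRegistration,
    n_bins: int = 25,
    d_max_frac: float = 0.2,
) -> DepthProfile:
    """Particle density in thin shells parallel to the embryo surface.

    Counts per d/L bin are normalized by the midsagittal-plane area of each
    shell. The shell metric matches ``project_particles``: d is the distance
    to the outline along the ray from the embryo center, so the area between
    depths d0 and d1 is the exact integral (1/2) * int [(r_b - d0)^2 -
    (r_b - d1)^2] dphi over the boundary radius r_b(phi). Intended for
    particles at or near the midsagittal plane.
    """
    edges = np.linspace(0.0, d_max_frac, n_bins + 1)
    d = table["depth_frac"].to_numpy()
    counts = np.histogram(d, bins=edges)[0].astype(float)
    L_um = registration.length_um
    a = L_um / 2.0
    b = registration.semi_minor_px * registration.um_per_px[1]
    phi = np.linspace(0, 2 * np.pi, 2001)
    r_b = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    areas = np.empty(n_bins)
    for i in range(n_bins):
        r0 = np.clip(r_b - edges[i] * L_um, 0, None)
        r1 = np.clip(r_b - edges[i + 1] * L_um, 0, None)
        areas[i] = max(np.trapezoid(0.5 * (r0**2 - r1**2), phi), 1e-9)
    return DepthProfile(edges, counts, counts / areas)


def stage_summaries(tables: list[tuple[int, pd.DataFrame]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-embryo and per-stage particle totals.

    Each input is (nuclear cycle, accepted-particle table). Counts refer to
    one embryo half; the ``count_full_embryo`` column carries the x2 left-
    right symmetry annotation.
    """
    if not tables:
        raise ValueError("at least one embryo table required")
    rows = []
    for i, (stage, df) in enumerate(tables):
        inten = df["intensity"].to_numpy() if len(df) else np.array([])
        rows.append(
            dict(
                embryo=i,
                stage=stage,
                n_particles=len(df),
                count_full_embryo=2 * len(df),
                total_intensity=float(inten.sum()),
                mean_particle_intensity=float(inten.mean()) if len(df) else np.nan,
            )
        )
    per_embryo = pd.DataFrame(rows)
    per_stage = (
        per_embryo.groupby("stage")
        .agg(
            n_embryos=("embryo", "count"),
            count_mean=("n_particles", "mean"),
            count_sd=("n_particles", "std"),
            total_intensity_mean=("total_intensity", "mean"),
            total_intensity_sd=("total_intensity", "std"),
            mean_intensity_mean=("mean_particle_intensity", "mean"),
        )
        .reset_index()
    )
    return per_embryo, per_stage
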