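"""Extended synthesis-diffusion-degradation (SDD) model on a 3D masked grid.

The Bcd protein concentration c(r, t) obeys

    dc/dt = D lap(c) - c/tau + rho(r)

inside an ellipsoidal embryo volume with no-flux boundaries, where D
(diffusion, um^2/s), tau (protein lifetime, min) and rho (synthesis, per
voxel) may switch values at specified nuclear cycles — the "extended" SDD
model. The source rho is either the measured/synthetic anterior mRNA
distribution or a point source at the anterior pole. Integration is explicit
forward Euler with a masked 6-neighbor Laplacian (no-flux implemented by
dropping out-of-mask neighbor links, which conserves mass exactly).

Developmental time is mapped from nuclear cycles using the interphase
schedule: 8 min each for n.c. 1-9, 9 min for n.c. 10, 10 min for n.c. 11,
12 min for n.c. 12, and 20 min for n.c. 13 and 14; AP-projected snapshots
are taken at the end of each cycle.

The optional GFP-maturation variant adds a second species: immature protein
carries the source and converts to the mature (fluorescent) species at rate
k (default 1/20 min^-1, i.e. a ~20 min maturation delay).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: interphase durations in minutes, indexed by nuclear cycle 1..14
CYCLE_MINUTES = {**{c: 8.0 for c in range(1, 10)}, 10: 9.0, 11: 10.0, 12: 12.0, 13: 20.0, 14: 20.0}


def cycle_end_times() -> dict[int, float]:
    """Cumulative minutes at the end of each nuclear cycle (n.c. 1 starts at 0)."""
    out, t = {}, 0.0
    for c in range(1, 15):
        t += CYCLE_MINUTES[c]
        out[c] = t
    return out


@dataclass
class Geometry3D:
    """Ellipsoidal voxel mask with a 1-voxel empty border."""

    mask: np.ndarray
    spacing_um: float
    length_um: float
    width_um: float

    @property
    def n_ap(self) -> int:
        xs = np.nonzero(self.mask.any(axis=(1, 2)))[0]
        return int(xs.size)

    @property
    def ap_slices(self) -> np.ndarray:
        """x-indices (axis 0 of the mask) occupied by the embryo."""
        return np.nonzero(self.mask.any(axis=(1, 2)))[0]

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.n_ap
        return (np.arange(n) + 0.5) / n


def build_geometry(length_um: float = 500.0, width_um: float = 180.0,
                   spacing_um: float = 10.0) -> Geometry3D:
    """Ellipsoid stand-in for the embryo volume on a regular grid.

    Axis 0 of the mask is the AP axis; axes 1 and 2 are the two minor axes.
    """
    if not (length_um > width_um > 2 * spacing_um):
        raise ValueError("require length_um > width_um > 2 * spacing_um")
    na = int(round(length_um / spacing_um))
    nb = int(round(width_um / spacing_um))
    if na < 5:
        raise ValueError("spacing too coarse: fewer than 5 voxels along the AP axis")
    shape = (na + 2, nb + 2, nb + 2)  # 1-voxel empty border
    x = (np.arange(shape[0]) + 0.5 - shape[0] / 2.0)[:, None, None]
    y = (np.arange(shape[1]) + 0.5 - shape[1] / 2.0)[None, :, None]
    z = (np.arange(shape[2]) + 0.5 - shape[2] / 2.0)[None, None, :]
    a, b = na / 2.0, nb / 2.0
    mask = (x / a) ** 2 + (y / b) ** 2 + (z / b) ** 2 <= 1.0
    mask[0], mask[-1] = False, False
    mask[:, 0], mask[:, -1] = False, False
    mask[:, :, 0], mask[:, :, -1] = False, False
    return Geometry3D(mask=mask, spacing_um=spacing_um, length_um=length_um, width_um=width_um)


@dataclass
class SDDParams:
    """Time-dependent model parameters of the extended SDD model.

    Defaults are the best-fit configuration: D = 3.1 um^2/s with a sharp
    drop to ``D_after`` at n.c. ``t_diff_off``, constant lifetime tau = 100
    min, and translation active only during n.c. ``t_src_on``-``t_src_off``.
    ``t_diff_off=None`` keeps diffusion on throughout (classic SDD when the
    source is also always on).
    """

    D_um2_s: float = 3.1
    tau_min: float = 100.0
    t_src_on: int = 7
    t_src_off: int = 13
    t_diff_off: int | None = 11
    D_after_um2_s: float = 0.0
    k_maturation_per_min: float | None = None
    source_mode: str = "realistic"

    def __post_init__(self) -> None:
        if self.D_um2_s < 0 or self.D_after_um2_s < 0:
            raise ValueError("diffusion constants must be >= 0")
        if not self.tau_min > 0:
            raise ValueError("tau must be positive (use np.inf for no degradation)")
        if self.t_src_on > self.t_src_off:
            raise ValueError("t_src_on must be <= t_src_off")
        if self.k_maturation_per_min is not None and self.k_maturation_per_min < 0:
            raise ValueError("maturation rate must be >= 0")
        if self.source_mode not in ("realistic", "point"):
            raise ValueError("source_mode must be 'realistic' or 'point'")

    def D_at(self, cycle: int) -> float:
        if self.t_diff_off is not None and cycle >= self.t_diff_off:
            return self.D_after_um2_s
        return self.D_um2_s

    def source_active(self, cycle: int) -> bool:
        return self.t_src_on <= cycle <= self.t_src_off


def classic_params(D_um2_s: float = 3.1, tau_min: float = 100.0) -> SDDParams:
    """Classic SDD: constant D and tau, source always on."""
    return SDDParams(D_um2_s=D_um2_s, tau_min=tau_min, t_src_on=1, t_src_off=14, t_diff_off=None)


@dataclass
class SourceField:
    """Volumetric production-rate density (concentration per minute).

    The total source strength — sum(rho) times the voxel volume — equals
    ``s_tot`` regardless of grid resolution.
    """

    rho: np.ndarray
    s_tot: float
    voxel_volume_um3: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.rho < 0):
            raise ValueError("source rates must be >= 0")
        total = float(self.rho.sum()) * self.voxel_volume_um3
        if total > 0 and abs(total - self.s_tot) > 1e-9 * max(self.s_tot, 1.0):
            raise ValueError("source normalization violated")


def build_source(
    geometry: Geometry3D,
    mode: str = "realistic",
    table: pd.DataFrame | None = None,
    s_tot: float = 1.0,
    weight_col: str | None = None,
) -> SourceField:
    """Discretize an mRNA particle table (or a point source) onto the grid.

    Realistic mode bins particle intensities into AP slabs by their
    ``ap_fraction`` and spreads each slab's weight uniformly over the mask
    voxels of that slab; weight landing in empty slabs is reassigned to the
    nearest occupied slab. Point mode places all of ``s_tot`` in the
    anterior-pole voxel. The field is normalized so its sum is exactly
    ``s_tot`` (constant total source strength across cycles).
    """
    rho = np.zeros(geometry.mask.shape)
    xs = geometry.ap_slices
    vox = geometry.spacing_um**3
    if mode == "point":
        x0 = xs[0]
        sub = np.argwhere(geometry.mask[x0])
        cy, cz = sub.mean(axis=0)
        j = np.argmin(((sub - [cy, cz]) ** 2).sum(axis=1))
        rho[x0, sub[j, 0], sub[j, 1]] = s_tot / vox
        return SourceField(rho=rho, s_tot=s_tot, voxel_volume_um3=vox)
    if mode != "realistic":
        raise ValueError(f"unknown source mode {mode!r}")
    if table is None or len(table) == 0:
        raise ValueError("realistic mode requires a particle table")

    if weight_col is None:
        for cand in ("intensity", "photon_amplitude", "amplitude", "n_mrna"):
            if cand in table.columns:
                weight_col = cand
                break
        else:
            raise ValueError("no intensity-like column found in particle table")
    ap = table["ap_fraction"].to_numpy()
    w = table[weight_col].to_numpy().astype(float)

    n = xs.size
    idx = np.clip(np.floor(ap * n).astype(int), 0, n - 1)
    slab_w = np.bincount(idx, weights=w, minlength=n)

    slab_nvox = np.array([int(geometry.mask[x].sum()) for x in xs])
    occupied = np.nonzero(slab_nvox > 0)[0]
    for i in np.nonzero((slab_w > 0) & (slab_nvox == 0))[0]:
        j = occupied[np.argmin(np.abs(occupied - i))]
        warnings.warn(f"source weight in empty AP slab {i} reassigned to slab {j}", stacklevel=2)
        slab_w[j] += slab_w[i]
        slab_w[i] = 0.0
    for i, x in enumerate(xs):
        if slab_w[i] > 0:
            rho[x][geometry.mask[x]] = slab_w[i] / slab_nvox[i]
    total = rho.sum()
    if total <= 0:
        raise ValueError("source field is empty")
    rho *= s_tot / (total * vox)
    return SourceField(rho=rho, s_tot=s_tot, voxel_volume_um3=vox)


@dataclass
class ScheduleSnapshot:
    cycle: int
    t_min: float
    bin_centers: np.ndarray
    profile: np.ndarray  # AP-projected mean concentration (mature species)
    profile_immature: np.ndarray | None = None
    total_mass: float = 0.0


def _neighbor_shifts(mask: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    """Precompute, per direction, the mask of voxels whose neighbor in that
    direction is also inside the embryo."""
    out = []
    for axis in range(3):
        for shift in (1, -1):
            valid = mask & np.roll(mask, shift, axis=axis)
            out.append((axis, shift, valid))
    return out


def _masked_laplacian(c: np.ndarray, shifts, dx2: float) -> np.ndarray:
    lap = np.zeros_like(c)
    for axis, shift, valid in shifts:
        lap += np.where(valid, np.roll(c, shift, axis=axis) - c, 0.0)
    return lap / dx2


def stable_dt_s(D_um2_s: float, spacing_um: float, safety: float = 0.8) -> float:
    if D_um2_s <= 0:
        return np.inf
    return safety * spacing_um**2 / (6.0 * D_um2_s)


def solve(
    geometry: Geometry3D,
    sources: dict[int, SourceField] | SourceField,
    params: SDDParams,
    dt_s: float | None = None,
    snapshot_cycles=range(1, 15),
) -> list[ScheduleSnapshot]:
    """Integrate the extended SDD model over the nuclear-cycle schedule.

    ``sources`` maps nuclear cycles to source fields (the nearest available
    cycle's geometry is reused for cycles without an entry); a single
    SourceField applies to all cycles. Snapshots are taken at the end of each
    requested cycle and carry the AP-projected mean-concentration profile.
    """
    if isinstance(sources, SourceField):
        sources = {1: sources}
    src_cycles = np.array(sorted(sources))
    mask = geometry.mask
    dx2 = geometry.spacing_um**2
    shifts = _neighbor_shifts(mask)
    mask_per_slab = np.array([mask[x].sum() for x in geometry.ap_slices])

    D_max = max(params.D_um2_s, params.D_after_um2_s)
    dt_cap = stable_dt_s(D_max, geometry.spacing_um)
    if dt_s is not None and dt_s > stable_dt_s(D_max, geometry.spacing_um, safety=0.9):
        raise ValueError(
            f"dt={dt_s:.3g}s violates the explicit stability bound; "
            f"use dt <= {dt_cap:.3g}s"
        )
    tau_s = params.tau_min * 60.0
    base_dt = dt_s if dt_s is not None else min(dt_cap, tau_s / 20.0, 30.0)
    if params.k_maturation_per_min:
        base_dt = min(base_dt, 0.2 * 60.0 / params.k_maturation_per_min)

    c = np.zeros(mask.shape)
    m = np.zeros(mask.shape) if params.k_maturation_per_min is not None else None
    k_s = (params.k_maturation_per_min or 0.0) / 60.0

    snapshots = []
    t = 0.0
    for cycle in range(1, 15):
        dur_s = CYCLE_MINUTES[cycle] * 60.0
        D = params.D_at(cycle)
        j = src_cycles[np.argmin(np.abs(src_cycles - cycle))]
        rho_min = sources[j].rho  # per minute
        rho_s = rho_min / 60.0 if params.source_active(cycle) else None

        n_steps = max(1, int(np.ceil(dur_s / base_dt)))
        dt = dur_s / n_steps
        decay = 0.0 if np.isinf(tau_s) else 1.0 / tau_s
        for _ in range(n_steps):
            lap = _masked_laplacian(c, shifts, dx2) if D > 0 else 0.0
            dc = D * lap - decay * c
            if rho_s is not None:
                dc = dc + rho_s
            if m is not None:
                dc = dc - k_s * c
                lap_m = _masked_laplacian(m, shifts, dx2) if D > 0 else 0.0
                m = m + dt * (D * lap_m - decay * m + k_s * c)
            c = c + dt * dc
        t += dur_s
        if np.any(~np.isfinite(c)) or np.any(c < -1e-9):
            raise RuntimeError(
                f"solver instability at n.c. {cycle}; retry with dt <= {0.5 * base_dt:.3g}s"
            )
        if cycle in snapshot_cycles:
            primary = m if m is not None else c
            prof = np.array(
                [primary[x][mask[x]].mean() for x in geometry.ap_slices]
            )
            prof_im = (
                np.array([c[x][mask[x]].mean() for x in geometry.ap_slices])
                if m is not None
                else None
            )
            snapshots.append(
                ScheduleSnapshot(
                    cycle=cycle,
                    t_min=t / 60.0,
                    bin_centers=geometry.bin_centers,
                    profile=prof,
                    profile_immature=prof_im,
                    total_mass=float(primary[mask].sum()) * geometry.spacing_um**3,
                )
            )
    return snapshots


def integrate_constant(
    geometry: Geometry3D,
    rho_per_min: np.ndarray,
    D_um2_s: float,
    tau_min: float,
    duration_min: float,
    dt_s: float | None = None,
    c0: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate dc/dt = D lap(c) - c/tau + rho for a fixed duration.

    A low-level companion to :func:`solve` for analyses outside the
    nuclear-cycle schedule (steady-state relaxation, convergence checks).
    Returns the concentration field.
    """
    mask = geometry.mask
    shifts = _neighbor_shifts(mask)
    dx2 = geometry.spacing_um**2
    dt = dt_s if dt_s is not None else min(stable_dt_s(D_um2_s, geometry.spacing_um),
                                           tau_min * 60.0 / 20.0, 30.0)
    dur_s = duration_min * 60.0
    n_steps = max(1, int(np.ceil(dur_s / dt)))
    dt = dur_s / n_steps
    decay = 0.0 if np.isinf(tau_min) else 1.0 / (tau_min * 60.0)
    rho_s = rho_per_min / 60.0
    c = np.zeros(mask.shape) if c0 is None else c0.copy()
    for _ in range(n_steps):
        lap = _masked_laplacian(c, shifts, dx2) if D_um2_s > 0 else 0.0
        c = c + dt * (D_um2_s * lap - decay * c + rho_s)
    return c


def run_developmental_scenario(
    tables: dict[int, pd.DataFrame] | pd.DataFrame,
    params: SDDParams | None = None,
    geometry: Geometry3D | None = None,
    s_tot: float = 1.0,
) -> list[ScheduleSnapshot]:
    """Full developmental simulation with the published schedule.

    ``tables`` maps nuclear cycles to particle tables (realistic mode) —
    the nearest measured cycle's source geometry is reused in between — or a
    single table used throughout. Point mode ignores the tables' spatial
    detail beyond requiring a valid geometry.
    """
    if params is None:
        params = SDDParams()
    if geometry is None:
        geometry = build_geometry()
    if isinstance(tables, pd.DataFrame):
        tables = {1: tables}
    if params.source_mode == "point":
        sources = {1: build_source(geometry, mode="point", s_tot=s_tot)}
    else:
        sources = {
            cyc: build_source(geometry, mode="realistic", table=tab, s_tot=s_tot)
            for cyc, tab in tables.items()
        }
    return solve(geometry, sources, params)
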