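"""SDD solver tests: geometry, sources, conservation, analytic limits."""

import numpy as np
import pandas as pd
import pytest

from bcdquant import sddsim, synthgen
from bcdquant.nucgrad import fit_exponential
from bcdquant.sddsim import (
    CYCLE_MINUTES,
    Geometry3D,
    SDDParams,
    SourceField,
    build_geometry,
    build_source,
    classic_params,
    cycle_end_times,
    integrate_constant,
    solve,
)


@pytest.fixture(scope="module")
def small_geometry():
    return build_geometry(length_um=200.0, width_um=90.0, spacing_um=10.0)


@pytest.fixture(scope="module")
def wedge_table():
    parts = synthgen.sample_particles(synthgen.early_model(), 3000, seed=10)
    return synthgen.particles_to_frame(parts)


class TestGeometry:
    def test_ap_voxel_count(self):
        geom = build_geometry(500.0, 180.0, 10.0)
        assert geom.n_ap == 50

    def test_ellipsoid_volume(self):
        geom = build_geometry(500.0, 180.0, 10.0)
        vol = geom.mask.sum() * geom.spacing_um**3
        expected = 4.0 / 3.0 * np.pi * 250 * 90 * 90
        assert vol == pytest.approx(expected, rel=0.05)

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(500.0, 450.0, 200.0)

    def test_schedule_cumulative_times(self):
        ends = cycle_end_times()
        assert ends[9] == 72.0
        assert ends[14] == sum(CYCLE_MINUTES.values()) == 143.0


class TestBuildSource:
    def test_point_source_single_voxel(self, small_geometry):
        src = build_source(small_geometry, mode="point", s_tot=2.5)
        assert np.count_nonzero(src.rho) == 1
        assert src.rho.max() * src.voxel_volume_um3 == pytest.approx(2.5)
        # at the anterior pole: smallest occupied x index
        x_nz = np.nonzero(src.rho.any(axis=(1, 2)))[0]
        assert x_nz[0] == small_geometry.ap_slices[0]

    def test_normalization_constant_across_cycles(self, small_geometry, wedge_table):
        cup = synthgen.particles_to_frame(
            synthgen.sample_particles(synthgen.blastoderm_model(), 3000, seed=11)
        )
        s1 = build_source(small_geometry, table=wedge_table, s_tot=3.0)
        s2 = build_source(small_geometry, table=cup, s_tot=3.0)
        assert s1.rho.sum() * s1.voxel_volume_um3 == pytest.approx(3.0, abs=1e-9)
        assert s2.rho.sum() * s2.voxel_volume_um3 == pytest.approx(3.0, abs=1e-9)

    def test_realistic_source_anterior(self, small_geometry, wedge_table):
        src = build_source(small_geometry, table=wedge_table)
        xs = small_geometry.ap_slices
        ap = (np.arange(xs.size) + 0.5) / xs.size
        per_slab = np.array([src.rho[x].sum() for x in xs])
        assert per_slab[ap <= 0.2].sum() / per_slab.sum() > 0.9

    def test_empty_table_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            build_source(small_geometry, table=pd.DataFrame())


class TestSolve:
    def test_zero_source_stays_zero(self, small_geometry):
        src = SourceField(np.zeros(small_geometry.mask.shape), 0.0)
        snaps = solve(small_geometry, src, SDDParams())
        assert all(np.allclose(s.profile, 0.0) for s in snaps)

    def test_mass_balance_no_degradation(self, small_geometry):
        """tau -> inf, constant source: mass = S_tot x active minutes."""
        src = build_source(small_geometry, mode="point", s_tot=1.0)
        params = SDDParams(tau_min=np.inf, t_src_on=1, t_src_off=14, t_diff_off=None)
        snaps = solve(small_geometry, src, params)
        for s in snaps:
            assert s.total_mass == pytest.approx(s.t_min, rel=1e-6)

    def test_snapshot_times_increasing_profiles_nonnegative(self, small_geometry):
        src = build_source(small_geometry, mode="point")
        snaps = solve(small_geometry, src, SDDParams())
        times = [s.t_min for s in snaps]
        assert times == sorted(times) and len(set(times)) == len(times)
        assert all((s.profile >= 0).all() for s in snaps)

    def test_1d_steady_state_closed_form(self):
        """Steady SDD decay length sqrt(D*tau): D=4, tau=2500 s -> 100 um."""
        mask = np.zeros((62, 5, 5), dtype=bool)
        mask[1:-1, 1:-1, 1:-1] = True  # 600 um bar, 3x3 voxel cross-section
        geom = Geometry3D(mask=mask, spacing_um=10.0, length_um=600.0, width_um=30.0)
        rho = np.zeros(mask.shape)
        rho[1, 1:-1, 1:-1] = 1.0
        tau_min = 2500.0 / 60.0
        c = integrate_constant(geom, rho, D_um2_s=4.0, tau_min=tau_min,
                               duration_min=8 * tau_min)
        profile = np.array([c[x][mask[x]].mean() for x in geom.ap_slices])
        x_um = (np.arange(profile.size) + 0.5) * 10.0
        sel = (x_um > 100) & (x_um < 450)  # away from source and far boundary
        slope = np.polyfit(x_um[sel], np.log(profile[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(100.0, rel=0.05)

    def test_linearity_in_source_strength(self, small_geometry, wedge_table):
        s1 = build_source(small_geometry, table=wedge_table, s_tot=1.0)
        s2 = build_source(small_geometry, table=wedge_table, s_tot=2.0)
        p = SDDParams()
        a = solve(small_geometry, s1, p)
        b = solve(small_geometry, s2, p)
        for sa, sb in zip(a, b):
            assert np.allclose(sb.profile, 2.0 * sa.profile, rtol=1e-9)

    def test_no_diffusion_confines_to_source(self, small_geometry, wedge_table):
        src = build_source(small_geometry, table=wedge_table)
        params = SDDParams(D_um2_s=0.0, t_diff_off=None, t_src_on=1, t_src_off=14)
        snaps = solve(small_geometry, src, params)
        final = snaps[-1]
        xs = small_geometry.ap_slices
        support = np.array([src.rho[x].sum() > 0 for x in xs])
        assert np.all(final.profile[~support] == 0.0)

    def test_unstable_dt_rejected(self, small_geometry):
        src = build_source(small_geometry, mode="point")
        with pytest.raises(ValueError, match="stability"):
            solve(small_geometry, src, SDDParams(D_um2_s=10.0), dt_s=60.0)

    def test_grid_refinement_consistency(self):
        """Halving the spacing changes the nc8 profile by < 5% (L2).

        The source is a smooth analytic density evaluated on each grid so
        that the comparison isolates solver convergence from source-binning
        resolution effects.
        """
        profiles = []
        for spacing in (10.0, 5.0):
            geom = build_geometry(200.0, 90.0, spacing)
            xs = geom.ap_slices
            rho = np.zeros(geom.mask.shape)
            for i, x in enumerate(xs):
                ap_um = (i + 0.5) * spacing
                rho[x][geom.mask[x]] = np.exp(-ap_um / 30.0)
            vox = spacing**3
            rho /= rho.sum() * vox
            src = SourceField(rho=rho, s_tot=1.0, voxel_volume_um3=vox)
            snaps = solve(geom, src, SDDParams(), snapshot_cycles=[8])
            s = snaps[0]
            x = np.linspace(0.02, 0.98, 40)
            profiles.append(np.interp(x, s.bin_centers, s.profile))
        a, b = profiles
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.05

    def test_maturation_fast_limit_matches_single_species(self, small_geometry, wedge_table):
        """k -> fast reproduces the one-species solution for the mature pool."""
        src = build_source(small_geometry, table=wedge_table)
        single = solve(small_geometry, src, SDDParams())
        fast = solve(small_geometry, src, SDDParams(k_maturation_per_min=50.0))
        for ss, sf in zip(single, fast):
            if ss.profile.max() == 0:
                continue
            num = np.linalg.norm(sf.profile - ss.profile)
            assert num / np.linalg.norm(ss.profile) < 0.01

    def test_maturation_delays_visible_signal(self, small_geometry, wedge_table):
        """With a ~20 min maturation delay the visible (mature) profile lags
        the immature pool early on."""
        src = build_source(small_geometry, table=wedge_table)
        snaps = solve(small_geometry, src, SDDParams(k_maturation_per_min=1 / 20.0))
        first_active = next(s for s in snaps if s.profile_immature.max() > 0)
        assert first_active.profile.sum() < first_active.profile_immature.sum()


@pytest.fixture(scope="module")
def scenario(wedge_table):
    cup = synthgen.particles_to_frame(
        synthgen.sample_particles(synthgen.blastoderm_model(), 3000, seed=11)
    )
    geom = sddsim.build_geometry()
    return geom, {6: wedge_table, 10: cup}


class TestScenario:
    def test_best_fit_amplitude_peaks_then_declines(self, scenario):
        geom, tables = scenario
        snaps = sddsim.run_developmental_scenario(tables, SDDParams(), geometry=geom)
        amps = {}
        for s in snaps:
            if s.cycle >= 7:
                amps[s.cycle] = fit_exponential(s.bin_centers, s.profile)[0]
        peak_cycle = max(amps, key=amps.get)
        assert 11 <= peak_cycle <= 13
        assert amps[14] < amps[peak_cycle]

    def test_classic_sdd_monotone_no_late_decline(self, scenario):
        geom, tables = scenario
        snaps = sddsim.run_developmental_scenario(
            tables, classic_params(D_um2_s=3.1, tau_min=30.0), geometry=geom
        )
        mass = [s.total_mass for s in snaps]
        assert all(b >= a * 0.999 for a, b in zip(mass, mass[1:]))
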