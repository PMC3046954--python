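"""End-to-end convenience workflows composing the pipeline stages.

These are the runs a user performs to reproduce the headline numbers:
detection statistics on default synthetic embryo halves, and the per-cycle
amplitude/decay-length dynamics of the best-fit extended SDD simulation.
"""

from __future__ import annotations

import numpy as np

from . import nucgrad, preprocess, sddsim, spatialstats, spotdetect, synthgen


def detection_run(
    geometry_mode: str = "cup",
    seed: int = 0,
    n_particles: int | None = None,
    shape: tuple[int, int, int] = synthgen.DEFAULT_STACK_SHAPE,
) -> dict:
    """Generate one synthetic half-embryo stack, detect, project, summarize.

    Returns the truth and detected intensity fractions along the AP axis
    plus the projected particle table.
    """
    if geometry_mode == "cup":
        model = synthgen.blastoderm_model()
        n = n_particles if n_particles is not None else synthgen.DESK_N_BLASTODERM
    else:
        model = synthgen.early_model()
        n = n_particles if n_particles is not None else synthgen.DESK_N_EARLY

    particles = synthgen.sample_particles(model, n, seed=seed, shape=shape)
    stack = synthgen.render_stack(particles, model, synthgen.RenderSpec(seed=seed), shape=shape)
    pre = preprocess.preprocess(stack, seed=seed)
    table = spotdetect.detect(pre)
    accepted = table[table.accepted].copy()
    registration = spatialstats.AxisRegistration.for_synthetic(model, shape)
    projected = spatialstats.project_particles(accepted, registration)
    dist = spatialstats.ap_distribution(projected)

    truth = synthgen.particles_to_frame(particles)
    w = truth.photon_amplitude
    return dict(
        model=model,
        particles=projected,
        truth=truth,
        n_truth=n,
        n_accepted=len(accepted),
        detected_cum_02=dist.cumulative_at(0.2),
        detected_posterior_share=1.0 - dist.cumulative_at(0.4),
        truth_cum_02=float(w[truth.ap_fraction <= 0.2].sum() / w.sum()),
        distribution=dist,
    )


def default_source_tables(seed: int = 0, n: int = 4000) -> dict:
    """Wedge (early) and cup (blastoderm) particle tables for SDD sources."""
    early = synthgen.particles_to_frame(
        synthgen.sample_particles(synthgen.early_model(), n, seed=seed + 1)
    )
    late = synthgen.particles_to_frame(
        synthgen.sample_particles(synthgen.blastoderm_model(), n, seed=seed + 2)
    )
    return {6: early, 10: late}


def best_fit_dynamics(
    params: sddsim.SDDParams | None = None,
    seed: int = 0,
    geometry: sddsim.Geometry3D | None = None,
    fit_window: tuple[float, float] = (0.1, 0.7),
) -> dict:
    """Run the best-fit extended SDD scenario and fit per-cycle exponentials.

    Returns per-cycle fitted amplitudes and decay lengths plus the summary
    statistics of gradient formation: the n.c. 8 -> 12 amplitude rise, the
    late decline relative to peak, and the maximal relative decay-length
    drift from n.c. 8.
    """
    if params is None:
        params = sddsim.SDDParams()
    if geometry is None:
        geometry = sddsim.build_geometry()
    tables = default_source_tables(seed=seed)
    snaps = sddsim.run_developmental_scenario(tables, params, geometry=geometry)
    amplitude, decay_length = {}, {}
    for s in snaps:
        if s.cycle < 7:
            continue
        a, lam, ok = nucgrad.fit_exponential(s.bin_centers, s.profile, window=fit_window)
        if ok:
            amplitude[s.cycle], decay_length[s.cycle] = a, lam
    peak = max(amplitude.values())
    lam8 = decay_length[8]
    drift = max(
        abs(decay_length[c] - lam8) / lam8 for c in range(8, 15) if c in decay_length
    )
    return dict(
        params=params,
        amplitude=amplitude,
        decay_length=decay_length,
        amp_ratio_12_8=amplitude[12] / amplitude[8],
        amp_14_over_peak=amplitude[14] / peak,
        decay_drift_frac=drift,
        snapshots=snaps,
    )
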