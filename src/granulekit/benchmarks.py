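"""Parameter-recovery protocols: published summary statistics as
generative ground truth, re-estimated by the package's own pipeline.

Each protocol takes a printed mean/SEM (or a diffusion coefficient) as
the generative input, simulates granule motion at the stated imaging
conditions (10 frames/s), runs the corresponding estimator — optionally
through rendering, detection, linking and filtering — and returns the
recovered summary.  Agreement validates the whole estimation chain, not
the simulator alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import diffusion_coefficient, max_distance, msd, track_velocity
from .synthetic import (AcquisitionSpec, MotionModel, matched_truncnorm_loc,
                        render_movie, simulate_tracks)
from .tracking import track_movie
from .tracks import TrackSet


def _recenter(track_data: pd.DataFrame, acq: AcquisitionSpec) -> pd.DataFrame:
    """Translate one track so its bounding box sits mid-field."""
    wx, wy = acq.field_um
    out = track_data.copy()
    for col, w in (("x_um", wx), ("y_um", wy)):
        mid = (out[col].min() + out[col].max()) / 2.0
        out[col] += w / 2.0 - mid
    return out


def recover_velocity(mean_um_s: float, sem_um_s: float, n_tracks: int,
                     seed: int, through_imaging: bool = True,
                     n_frames: int = 24) -> dict:
    """Per-track-speed recovery at the granule-imaging frame rate.

    Per-track constant speeds are drawn from a zero-truncated normal
    whose mean equals ``mean_um_s`` and whose SD is ``sem_um_s·√n`` (the
    population SD implied by the published SEM).  With
    ``through_imaging`` each track is rendered noise-free into its own
    field and re-measured by the detection → linking → filtering
    pipeline before :func:`track_velocity` is applied.
    """
    sd = sem_um_s * np.sqrt(n_tracks)
    loc = matched_truncnorm_loc(mean_um_s, sd)
    model = MotionModel("directed", v=loc, v_sd=sd)
    sim_acq = AcquisitionSpec(nx=160, ny=160, n_frames=n_frames, noise="none")
    truth = simulate_tracks(model, sim_acq, n_tracks, seed=seed, boundary="none",
                            speed_sampling="stratified")

    if not through_imaging:
        velocities = [track_velocity(tr) for tr in truth]
        return {"mean_velocity_um_s": float(np.mean(velocities)),
                "n": n_tracks}

    velocities = []
    for tid in truth.track_ids:
        one = TrackSet(_recenter(truth.data[truth.data["track_id"] == tid],
                                 sim_acq), truth.frame_interval)
        movie = render_movie(one, sim_acq)
        recovered = track_movie(movie, min_frames=min(21, n_frames - 2))
        velocities.extend(track_velocity(tr) for tr in recovered)
    return {"mean_velocity_um_s": float(np.mean(velocities)),
            "n": len(velocities)}


def recover_distance(mean_um: float, sem_um: float, n_tracks: int,
                     seed: int, n_frames: int = 600) -> dict:
    """Maximum-excursion recovery for straight processive runs.

    Per-track total excursions are drawn from a zero-truncated normal
    with mean ``mean_um`` and SD ``sem_um·√n``, realized as straight
    directed runs over the full 60 s acquisition; the farthest-point
    statistic is computed per track.
    """
    duration = (n_frames - 1) * 0.1
    sd = sem_um * np.sqrt(n_tracks)
    loc = matched_truncnorm_loc(mean_um, sd) / duration
    model = MotionModel("directed", v=loc, v_sd=sd / duration)
    acq = AcquisitionSpec(nx=160, ny=160, n_frames=n_frames, noise="none")
    tracks = simulate_tracks(model, acq, n_tracks, seed=seed, boundary="none",
                             speed_sampling="stratified")
    distances = [max_distance(tr) for tr in tracks]
    return {"mean_max_distance_um": float(np.mean(distances)), "n": n_tracks}


def recover_diffusion(d_um2_s: float, n_tracks: int, seed: int,
                      n_frames: int = 600, max_lag: int = 7) -> dict:
    """Median MSD-slope/4 estimate for Brownian granules at a given D."""
    model = MotionModel("brownian", D=d_um2_s)
    acq = AcquisitionSpec(n_frames=n_frames, noise="none")
    tracks = simulate_tracks(model, acq, n_tracks, seed=seed, boundary="none")
    estimates = [diffusion_coefficient(msd(tr, max_lag)).D for tr in tracks]
    return {"median_D_um2_s": float(np.median(estimates)), "n": n_tracks}
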