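import numpy as np
import pytest

import shoalwatch as sw
from shoalwatch.background import fit_background, segment_foreground


@pytest.fixture(scope="session")
def rendered_clip():
    """One simulated, rendered and segmented 30 s clip shared across tests.

    Moderate dispersion, no stimulus, enrichment structure present; the
    returned dict carries every intermediate plus the ground truth.
    """
    scene = sw.TankScene(image_size_px=(256, 256), enrichment_center_cm=(0.0, 12.0))
    school = sw.SchoolParams(n_fish=20, seed=7, dispersion=3.0, enrichment_affinity=0.2)
    traj, gt = sw.simulate_school(scene, school, duration_s=30.0, fps=10.0)
    seq = sw.render_frames(traj, scene, noise_sd=2.0, noise_seed=8)
    model = fit_background(seq)
    masks = segment_foreground(seq, model)
    dets = sw.label_objects(masks, seq.px_per_cm)
    size = sw.estimate_fish_size(dets, school.n_fish, min_frames=100)
    dets = sw.assign_groups(dets, size)
    links = sw.link_clip(dets, size)
    return {
        "scene": scene,
        "school": school,
        "traj": traj,
        "gt": gt,
        "seq": seq,
        "model": model,
        "masks": masks,
        "dets": dets,
        "size": size,
        "links": links,
    }


@pytest.fixture(scope="session")
def stimulus_recovery():
    """A novel-object trial clip: dispersed school with decaying darting
    bursts, run through detection and dart scoring, with ground-truth events."""
    from shoalwatch.detect import build_tracklets
    from shoalwatch.latency import events_from_darting_flags

    scene = sw.TankScene(
        image_size_px=(256, 256), monitored_fraction=1.0, enrichment_center_cm=None
    )
    school = sw.SchoolParams(n_fish=20, seed=12, dispersion=6.0)
    stim = sw.StimulusParams(
        onset_s=0.0,
        initial_dart_rate_per_fish_per_s=0.1,
        decay_timescale_s=15.0,
        dart_speed_multiplier=4.0,
        dart_duration_s=0.5,
    )
    traj, gt = sw.simulate_school(scene, school, stimulus=stim, duration_s=60.0, fps=10.0)
    seq = sw.render_frames(traj, scene, noise_sd=2.0, noise_seed=13)
    model = fit_background(seq)
    masks = segment_foreground(seq, model)
    dets = sw.label_objects(masks, seq.px_per_cm)
    size = sw.estimate_fish_size(dets, school.n_fish, min_frames=100)
    dets = sw.assign_groups(dets, size)
    links = sw.link_clip(dets, size)
    tracks = build_tracklets(dets, links, seq.fps)
    events = sw.detect_darts(tracks, size, seq.fps)
    gt_events = events_from_darting_flags(gt.darting, gt.fps)
    return {
        "scene": scene,
        "gt": gt,
        "size": size,
        "events": events,
        "gt_events": gt_events,
    }


@pytest.fixture(scope="session")
def single_fish_clip():
    """A lone, slow fish in a fully monitored small tank: the workhorse for
    exact detection checks."""
    scene = sw.TankScene(
        image_size_px=(192, 192), monitored_fraction=1.0, enrichment_center_cm=None
    )
    school = sw.SchoolParams(n_fish=1, seed=3, dispersion=0.0, mean_speed_cmps=3.0)
    traj, gt = sw.simulate_school(scene, school, duration_s=15.0, fps=10.0)
    seq = sw.render_frames(traj, scene, noise_sd=0.0)
    model = fit_background(seq)
    masks = segment_foreground(seq, model)
    return {
        "scene": scene,
        "school": school,
        "traj": traj,
        "gt": gt,
        "seq": seq,
        "model": model,
        "masks": masks,
    }
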