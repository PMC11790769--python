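import numpy as np
import pytest

import arenatrack as at


@pytest.fixture(scope="session")
def single_arena_scene():
    """Noiseless one-arena recording with a rectangular scripted sweep."""
    scene = at.SceneSpec(
        frame_size=(160, 120), arenas=((10.0, 10.0, 150.0, 110.0),), noise_sigma=0.0, seed=1
    )
    path = at.ScriptedPath(
        waypoints=((30, 30), (120, 30), (120, 90), (30, 90), (30, 30)),
        duration_s=6.0,
        fps=10.0,
    )
    frames, truth = at.render_video(scene, {0: path})
    return scene, {0: path}, frames, truth


@pytest.fixture(scope="session")
def four_arena_scene():
    """Noiseless four-arena recording, one distinct scripted path per arena."""
    scene = at.SceneSpec(
        frame_size=(320, 240),
        arenas=(
            (10.0, 10.0, 150.0, 110.0),
            (170.0, 10.0, 310.0, 110.0),
            (10.0, 130.0, 150.0, 230.0),
            (170.0, 130.0, 310.0, 230.0),
        ),
        noise_sigma=0.0,
        seed=2,
    )
    paths = {
        0: at.ScriptedPath(waypoints=((30, 30), (130, 90)), duration_s=5.0, fps=10.0),
        1: at.ScriptedPath(waypoints=((290, 30), (190, 90)), duration_s=5.0, fps=10.0),
        2: at.ScriptedPath(waypoints=((30, 210), (130, 150), (30, 150)), duration_s=5.0, fps=10.0),
        3: at.ScriptedPath(waypoints=((240, 180), (240, 180)), duration_s=5.0, fps=10.0),
    }
    frames, truth = at.render_video(scene, paths)
    return scene, paths, frames, truth


def track_scene(scene, frames, truth, settings=None):
    """Run the standard leader-background tracking over the blob frames."""
    settings = settings or at.DetectionSettings()
    bg = at.estimate_background(frames, (0, truth.first_frame), "leader_frame")
    arenas = {i: scene.arenas[i] for i in truth.positions}
    return at.track_video(
        frames, arenas, settings, bg, truth.first_frame, len(frames), fps=truth.fps
    )


@pytest.fixture(scope="session")
def tracked_single(single_arena_scene):
    scene, paths, frames, truth = single_arena_scene
    return single_arena_scene + (track_scene(scene, frames, truth),)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
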