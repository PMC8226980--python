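"""Shared fixtures: solved flow fields are expensive, so they are built once
per session and reused across test modules."""

import numpy as np
import pytest

import vesselchip as vc


@pytest.fixture(scope="session")
def straight_geom():
    return vc.build_serpentine(segment_length_mm=2.0, n_segments=1)


@pytest.fixture(scope="session")
def straight_grid(straight_geom):
    return vc.rasterize(straight_geom, 5.0)


@pytest.fixture(scope="session")
def straight_flow(straight_grid):
    """Newtonian (PBS) flow through a single 2 mm straight limb at 0.5 uL/min."""
    return vc.solve_planform(straight_grid, vc.get_fluid("pbs"), 0.5)


@pytest.fixture(scope="session")
def thrombus_scene():
    """Clot-bearing limb solved with Carreau blood; no frames rendered yet."""
    return vc.make_scene("thrombus", render=False, fluid_name="blood",
                         n_particles=20, n_frames=6, seed=2)


@pytest.fixture(scope="session")
def thrombus_frames(thrombus_scene):
    scene = thrombus_scene
    crop = scene.crop_um
    return vc.render_frames(scene.trajectories, scene.flow, scene.spec,
                            crop_um=crop), crop


@pytest.fixture(scope="session")
def bend_flow_blood():
    """Two serpentine limbs joined by a 180-degree bend, Carreau blood."""
    geom = vc.build_serpentine(segment_length_mm=0.8, n_segments=2,
                               bend_radius_mm=0.3)
    grid = vc.rasterize(geom, 5.0)
    return vc.solve_planform(grid, vc.get_fluid("blood"), 0.5)


@pytest.fixture(scope="session")
def hemorrhage_flow():
    """Wall-gap (bleed) scene solved with PBS."""
    geom = vc.build_serpentine(segment_length_mm=0.6, n_segments=2,
                               bend_radius_mm=0.25)
    geom = vc.add_defect(geom, vc.Defect(kind="wall_gap", path_position_mm=0.3,
                                         gap_length_um=20.0, wall_side="left"))
    grid = vc.rasterize(geom, 4.0)
    return vc.solve_planform(grid, vc.get_fluid("pbs"), 0.5)


@pytest.fixture(scope="session")
def speckle_texture():
    """Band-limited random texture used as PIV ground-truth pattern."""
    from scipy import ndimage

    rng = np.random.default_rng(11)
    tex = ndimage.gaussian_filter(rng.standard_normal((200, 300)), 3.0)
    return 1000.0 + 500.0 * tex / tex.std()
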