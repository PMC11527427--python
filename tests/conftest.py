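import numpy as np
import pytest

from filoquant import quantify, synthetic


@pytest.fixture(scope="session")
def default_camera() -> synthetic.CameraModel:
    return synthetic.CameraModel()


@pytest.fixture(scope="session")
def scene(default_camera):
    """One rendered synthetic cell (myo10 image, phalloidin image, truth)."""
    return synthetic.make_cell_scene(rng_seed=3, camera=default_camera)


@pytest.fixture(scope="session")
def quantified_scene(scene):
    """Pipeline output for the shared scene, with an exact-mean scale."""
    myo10, phalloidin, truth = scene
    first = quantify.quantify_scene(myo10, phalloidin)
    scale = quantify.FluorescenceScale(
        n_cells=1,
        mean_molecules=truth.total_molecules,
        total_signal=first.cell_total_intensity,
    )
    return quantify.quantify_scene(myo10, phalloidin, scale=scale)


def flood_fill_components(mask: np.ndarray) -> int:
    """Brute-force component count under the two-orthogonal-hop rule.

    Independent oracle: breadth-first flood fill where two pixels are
    neighbors if reachable through at most two orthogonal hops (i.e. the
    8-neighborhood including diagonals).
    """
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    count = 0
    neighbors = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in neighbors:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count
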