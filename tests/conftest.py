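import numpy as np
import pytest
from scipy.spatial import cKDTree

from meioquant import SimulationConfig, render_image_stack
from meioquant.foci import detect_foci, segment_nuclei


def match_foci(detected_um: np.ndarray, truth_um: np.ndarray, radius_um: float = 0.3):
    """Greedy one-to-one matching of detected vs true foci.

    Returns the number of true positives; recall = tp / n_truth,
    precision = tp / n_detected.
    """
    if len(detected_um) == 0 or len(truth_um) == 0:
        return 0
    tree = cKDTree(detected_um)
    used = set()
    tp = 0
    for t in truth_um:
        for j in sorted(
            tree.query_ball_point(t, radius_um),
            key=lambda j: np.linalg.norm(t - detected_um[j]),
        ):
            if j not in used:
                used.add(j)
                tp += 1
                break
    return tp


@pytest.fixture(scope="session")
def rendered_field():
    """One rendered 50-nucleus two-channel field with truth tables."""
    config = SimulationConfig(seed=3)
    stacks, nucleus_truth, focus_truth = render_image_stack(
        config, n_nuclei=50, mean_foci_per_nucleus=5.0
    )
    voxel_um = tuple(v / 1000.0 for v in config.voxel_size)
    return config, stacks, nucleus_truth, focus_truth, voxel_um


@pytest.fixture(scope="session")
def detection_result(rendered_field):
    """Segmentation + detection run once on the rendered field."""
    _, stacks, _, _, voxel_um = rendered_field
    _, nuclei, flagged = segment_nuclei(stacks["dapi"], voxel_um)
    result = detect_foci(stacks["signal"], nuclei, voxel_um, flagged=flagged)
    return nuclei, result
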