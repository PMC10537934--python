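import numpy as np
import pytest

from sonodense import pipeline, syndata


def brute_force_max_rectangle_area(mask: np.ndarray) -> int:
    """Exhaustive search over all axis-aligned rectangles via an integral image."""
    mask = np.asarray(mask, dtype=np.int64)
    n_rows, n_cols = mask.shape
    ii = np.zeros((n_rows + 1, n_cols + 1), dtype=np.int64)
    ii[1:, 1:] = mask.cumsum(0).cumsum(1)
    best = 0
    for r1 in range(n_rows):
        for r2 in range(r1 + 1, n_rows + 1):
            for c1 in range(n_cols):
                for c2 in range(c1 + 1, n_cols + 1):
                    area = (r2 - r1) * (c2 - c1)
                    if area <= best:
                        continue
                    filled = ii[r2, c2] - ii[r1, c2] - ii[r2, c1] + ii[r1, c1]
                    if filled == area:
                        best = area
    return best


@pytest.fixture(scope="session")
def small_cohort_table():
    """Feature table of a small synthetic cohort (shared across tests)."""
    cfg = syndata.GeneratorConfig(n_patients=40, image_height=150,
                                  image_width=150, seed=7)
    table, truths = pipeline.cohort_feature_table(cfg)
    return table, truths
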