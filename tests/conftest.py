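import numpy as np
import pytest

from nucseg.synth import Scene, SceneSpec, generate_scene


SMALL_SCENE = dict(height=64, width=64, n_nuclei=5, radius_range=(4.0, 8.0),
                   noise_sd=0.0)


@pytest.fixture(scope="session")
def small_scene() -> Scene:
    return generate_scene(SceneSpec(**SMALL_SCENE, seed=11))


@pytest.fixture(scope="session")
def overlap_scene() -> Scene:
    return generate_scene(SceneSpec(height=96, width=96, n_nuclei=8,
                                    overlap_fraction=0.5, radius_range=(5.0, 9.0),
                                    noise_sd=0.0, seed=21))


def brute_force_touching(mask: np.ndarray) -> list[tuple[int, int]]:
    """Independent oracle: exhaustive per-pixel 8-adjacency scan."""
    h, w = mask.shape
    pairs = set()
    for y in range(h):
        for x in range(w):
            a = mask[y, x]
            if a == 0:
                continue
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        b = mask[yy, xx]
                        if b != 0 and b != a:
                            pairs.add((min(int(a), int(b)),
                                       max(int(a), int(b))))
    return sorted(pairs)
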