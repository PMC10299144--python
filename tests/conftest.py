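import numpy as np
import pytest

import octadme as od


def random_skeleton(seed: int, shape=(32, 32), density: float = 0.15) -> np.ndarray:
    """Sparse random binary pattern used as a stand-in skeleton."""
    rng = np.random.default_rng(seed)
    return rng.random(shape) < density


def brute_force_otsu(img: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer over t = 0..254."""
    arr = img.ravel().astype(float)
    n = arr.size
    best_t, best_v = 0, -1.0
    for t in range(255):
        lo = arr[arr <= t]
        hi = arr[arr > t]
        v = 0.0
        if lo.size and hi.size:
            v = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def brute_force_box_masses(arr: np.ndarray, box: int, dy: int, dx: int) -> list[int]:
    """Double-loop pixel count over complete boxes anchored at (dy, dx)."""
    h, w = arr.shape
    masses = []
    y = dy
    while y + box <= h:
        x = dx
        while x + box <= w:
            m = 0
            for i in range(y, y + box):
                for j in range(x, x + box):
                    m += int(arr[i, j])
            masses.append(m)
            x += box
        y += box
    return masses


def brute_force_lacunarity(arr: np.ndarray, box_sizes, stride: int = 1) -> float:
    """Explicit-loop multi-origin lacunarity, averaged over scales."""
    per_scale = []
    for b in box_sizes:
        vals = []
        for dy in range(0, b, stride):
            for dx in range(0, b, stride):
                m = np.array(brute_force_box_masses(arr, b, dy, dx), dtype=float)
                mean = m.mean()
                if mean == 0:
                    continue
                vals.append(m.var() / mean**2)
        per_scale.append(float(np.mean(vals)))
    return float(np.mean(per_scale))


@pytest.fixture(scope="session")
def reference_cohort():
    return od.load_reference_cohort()
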