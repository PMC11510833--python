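import numpy as np
import pytest

from yoloev.data import SceneParams, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scene_items():
    """Eight small synthetic scenes shared by the training-related tests."""
    params = SceneParams(image_size=64, n_classes=3, objects_min=1,
                         objects_max=3, scale_min=0.25, scale_max=0.6,
                         occlusion_rate=0.0)
    return [(s.image, s.boxes, str(i))
            for i, s in ((i, generate_scene(params, seed=i))
                         for i in range(8))]


def finite_diff(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite-difference gradient of scalar f at x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
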