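import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def naive_haar_subbands(x: np.ndarray, norm: float = 0.5) -> dict[str, np.ndarray]:
    """Nested-loop 2x2 block-arithmetic oracle for the Haar decomposition.

    Works on a single-channel [H, W] array; deliberately independent of the
    package implementation (explicit sliding-window sums, no einsum).
    """
    h, w = x.shape
    assert h % 2 == 0 and w % 2 == 0
    out = {k: np.zeros((h // 2, w // 2)) for k in ("ll", "lh", "hl", "hh")}
    for i in range(0, h, 2):
        for j in range(0, w, 2):
            a, b = x[i, j], x[i, j + 1]
            c, d = x[i + 1, j], x[i + 1, j + 1]
            out["ll"][i // 2, j // 2] = norm * (a + b + c + d)
            out["lh"][i // 2, j // 2] = norm * (-a - b + c + d)
            out["hl"][i // 2, j // 2] = norm * (-a + b - c + d)
            out["hh"][i // 2, j // 2] = norm * (a - b - c + d)
    return out


def naive_confusion(pred: np.ndarray, ref: np.ndarray, nc: int = 2) -> np.ndarray:
    """Per-pixel counting oracle for the confusion matrix."""
    n = np.zeros((nc, nc), dtype=np.int64)
    for r, p in zip(ref.ravel(), pred.ravel()):
        n[int(r), int(p)] += 1
    return n
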