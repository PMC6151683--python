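import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gray(rng):
    """Seeded 32×32 pseudo-random gray-level image."""
    return rng.integers(0, 256, size=(32, 32), dtype=np.uint8)


@pytest.fixture
def random_rgb(rng):
    return rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)


def entropy_bruteforce(img: np.ndarray, n: int, bins: int = 256) -> np.ndarray:
    """Independent oracle: explicit symmetric padding, per-window histogram,
    -sum p log2 p.  Deliberately naive; no shared code with the package."""
    before, after = n // 2, (n - 1) // 2
    padded = np.pad(img, ((before, after), (before, after)), mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            window = padded[i:i + n, j:j + n].ravel()
            hist = np.bincount(window, minlength=bins)
            p = hist[hist > 0] / window.size
            out[i, j] = float(-(p * np.log2(p)).sum())
    return out


def auc_bruteforce(scores, truth) -> float:
    """Mann-Whitney pairwise concordance with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
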