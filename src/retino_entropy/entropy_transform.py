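"""Local-entropy transformation of fundus photographs.

The central representation of the package: every pixel of the luminance image
is replaced by the Shannon entropy (base 2) of the gray-level histogram over
the n×n window centred on it,

    E_local = - sum_i P(i) * log2 P(i),

where P(i) is the relative frequency of gray level i within the window.  Flat
retinal areas give entropy near zero; lesions and vessel edges raise the local
gray-level diversity and hence the entropy.  The entropy image is computed at
the native resolution and only then downsized to the 100×100 network input.

Conventions (the method itself fixes none of these, so they are explicit
package choices, see docs/methods.md):

* sliding per-pixel window, not disjoint tiles;
* symmetric (mirror) boundary padding;
* 256 histogram bins, one per 8-bit gray level;
* even n: the window covers offsets [-n/2, n/2-1] in each axis;
* luminance = ITU-R BT.601 luma, rounded to the nearest integer;
* downsizing by bilinear interpolation with anti-aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

#: block sizes used in the original block-size sweep
SWEEP_BLOCK_SIZES = (2, 3, 5, 9, 11)
#: block size that maximised detection accuracy in the sweep
DEFAULT_BLOCK_N = 9

STANDARD_SIZE = 100

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the local-entropy filter.

    block_n : side length n of the square window (>= 2).
    bins    : number of gray levels in the histogram (256 for 8-bit input).
    padding : boundary rule; only "symmetric" is implemented.
    """

    block_n: int = DEFAULT_BLOCK_N
    bins: int = 256
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.block_n < 2:
            raise ValueError(f"block_n must be >= 2, got {self.block_n}")
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        if self.padding != "symmetric":
            raise ValueError(f"unsupported padding {self.padding!r}")

    @property
    def max_entropy(self) -> float:
        """Upper bound of the filter output, log2(bins) bits."""
        return float(np.log2(self.bins))


def to_luminance(img: np.ndarray) -> np.ndarray:
    """BT.601 luma of an H×W×3 uint8 image, rounded, as H×W uint8."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 image, got shape {arr.shape}")
    lum = arr.astype(np.float64) @ _LUMA_WEIGHTS
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


def _window_pads(n: int) -> tuple[int, int]:
    # odd n: centred window; even n: offsets [-n/2, n/2-1] per axis
    return n // 2, (n - 1) // 2


def local_entropy(lum: np.ndarray, cfg: EntropyConfig | None = None) -> np.ndarray:
    """Per-pixel local Shannon entropy (bits) of a gray-level image.

    Returns a float64 H×W array in [0, log2(bins)].  Implemented as one
    summed-area pass per gray level present in the image: window counts
    c_i give the entropy via  E = log2(N) - (1/N) * sum_i c_i log2 c_i
    with N = n*n, which avoids materialising per-window histograms.
    """
    cfg = cfg or EntropyConfig()
    arr = np.asarray(lum)
    if arr.ndim != 2:
        raise ValueError(f"expected H×W luminance image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError("luminance must be integer gray levels")
    if arr.min() < 0 or arr.max() >= cfg.bins:
        raise ValueError(f"gray levels outside [0, {cfg.bins - 1}]")

    n = cfg.block_n
    before, after = _window_pads(n)
    padded = np.pad(arr, ((before, after), (before, after)), mode="symmetric")
    H, W = arr.shape
    N = n * n

    # summed-area table per present gray level; accumulate c*log2(c)
    acc = np.zeros((H, W), dtype=np.float64)
    ph, pw = padded.shape
    for level in np.unique(padded):
        mask = (padded == level)
        sat = np.zeros((ph + 1, pw + 1), dtype=np.int64)
        np.cumsum(mask, axis=0, out=sat[1:, 1:])
        np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
        counts = (sat[n:n + H, n:n + W] - sat[n:n + H, 0:W]
                  - sat[0:H, n:n + W] + sat[0:H, 0:W])
        c = counts.astype(np.float64)
        nz = c > 0
        acc[nz] += c[nz] * np.log2(c[nz])

    ent = np.log2(N) - acc / N
    # clip tiny negative round-off on constant windows
    return np.clip(ent, 0.0, cfg.max_entropy)


def standardize(img: np.ndarray, representation: str,
                bins: int = 256, size: int = STANDARD_SIZE) -> np.ndarray:
    """Scale to [0,1] and resize to the standard network input.

    representation="original": H×W×3 uint8 → size×size×3, divided by 255.
    representation="entropy":  H×W float entropy → size×size×1, divided by
    log2(bins) (the filter's maximum), the analogous affine map to [0,1].
    Resizing is bilinear with anti-aliasing when downsizing; output clamped
    to [0,1].
    """
    arr = np.asarray(img)
    if representation == "original":
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"original representation needs H×W×3, got {arr.shape}")
        scaled = arr.astype(np.float64) / 255.0
    elif representation == "entropy":
        if arr.ndim != 2:
            raise ValueError(f"entropy representation needs H×W, got {arr.shape}")
        scaled = arr.astype(np.float64) / float(np.log2(bins))
        scaled = scaled[..., None]
    else:
        raise ValueError(f"unknown representation {representation!r}")

    if scaled.shape[:2] != (size, size):
        aa = scaled.shape[0] > size or scaled.shape[1] > size
        scaled = _sk_resize(scaled, (size, size), order=1, mode="reflect",
                            anti_aliasing=aa, preserve_range=True)
    return np.clip(scaled, 0.0, 1.0)


def transform_fundus(img: np.ndarray, cfg: EntropyConfig | None = None,
                     representation: str = "entropy",
                     size: int = STANDARD_SIZE,
                     entropy_after_resize: bool = False) -> np.ndarray:
    """Full preprocessing of one RGB fundus photograph.

    "entropy": luminance → local entropy at native resolution → standardize
    (set ``entropy_after_resize`` to compute the filter on the downsized
    luminance instead, an ablation of the default order).
    "original": standardize the RGB image directly.
    """
    cfg = cfg or EntropyConfig()
    if representation == "original":
        return standardize(img, "original", size=size)
    lum = to_luminance(img)
    if entropy_after_resize:
        small = _sk_resize(lum.astype(np.float64), (size, size), order=1,
                           mode="reflect", anti_aliasing=lum.shape[0] > size,
                           preserve_range=True)
        lum = np.clip(np.rint(small), 0, 255).astype(np.uint8)
    ent = local_entropy(lum, cfg)
    return standardize(ent, "entropy", bins=cfg.bins, size=size)
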