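import numpy as np
import pytest

from chemolipid.chemogram import Chemogram
from chemolipid.synthetic import (
    ArtifactBand,
    LipidBlob,
    SceneSpec,
    generate_chemogram,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_red_chemogram():
    """Noise-free pure-red chemogram: no lipid, no artifacts."""
    px = np.zeros((90, 60, 3), dtype=np.uint8)
    px[:, :, 0] = 255
    return Chemogram(px, mm_per_column=0.25)


@pytest.fixture
def shadowed_blob_scene():
    """One lipid pool partially covered by a calcification shadow, plus a
    guide-wire band; noise-free so truth is unambiguous."""
    spec = SceneSpec(
        H=180,
        W=120,
        mm_per_column=0.25,
        blobs=[LipidBlob(90, 60, 18, 22)],
        artifact_bands=[
            ArtifactBand(0, 10, 0, 120, darkness=10),
            ArtifactBand(45, 135, 45, 58, darkness=10),
        ],
        noise_sd=0.0,
        seed=11,
    )
    return generate_chemogram(spec)


def brute_force_otsu(values):
    """Exhaustive-search oracle: threshold t in 0..254 maximizing
    between-class variance of the split (<= t) vs (> t); first maximizer.

    The variance w0*w1*(mu0 - mu1)^2 is proportional to
    (s0*n1 - s1*n0)^2 / (n0*n1) with per-class pixel counts n and intensity
    sums s, so candidate scores are compared as exact integer fractions --
    no floating-point near-ties."""
    v = np.asarray(values).ravel().astype(np.int64)
    best_t, best_num, best_den = 0, -1, 1
    for t in range(255):
        lo = v[v <= t]
        hi = v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        a = int(lo.sum()) * hi.size - int(hi.sum()) * lo.size
        num, den = a * a, lo.size * hi.size
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    return best_t
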