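import numpy as np
import pytest

from tsrquant import synthetic
from tsrquant.stain import build_stain_matrix


@pytest.fixture(scope="session")
def hdab():
    return build_stain_matrix()


@pytest.fixture(scope="session")
def noiseless_render(hdab):
    """A deterministic layout/image pair with zero rendering noise."""
    layout = synthetic.make_layout(128, 128, target_ratio=1.0, seed=7)
    image = synthetic.render_ihc(
        layout, synthetic.RenderParams(noise_sd=0.0, seed=7), hdab
    )
    return layout, image


def random_histograms(n, seed):
    """Mixed spiky/smooth random 256-bin histograms for threshold oracles."""
    rng = np.random.default_rng(seed)
    hists = []
    for _ in range(n):
        hist = np.zeros(256, dtype=np.int64)
        kind = rng.integers(3)
        if kind == 0:  # a few spikes
            bins = rng.choice(256, size=rng.integers(2, 6), replace=False)
            hist[bins] = rng.integers(1, 1000, size=bins.size)
        elif kind == 1:  # smooth noise floor
            hist += rng.integers(0, 50, size=256)
        else:  # bimodal gaussians, the typical stain histogram
            for mu, amp in ((rng.integers(10, 100), 3000), (rng.integers(150, 250), 3000)):
                x = np.arange(256)
                hist += rng.poisson(amp * np.exp(-((x - mu) ** 2) / 200.0))
        if hist.sum() == 0:
            hist[rng.integers(256)] = 1
        hists.append(hist)
    return hists


def brute_force_otsu(hist):
    """Exhaustive between-class-variance maximizer (first maximizer wins)."""
    hist = np.asarray(hist, dtype=float)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0])
    total = hist.sum()
    levels = np.arange(256.0)
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * hist[: t + 1]).sum() / (w0 * total)
        mu1 = (levels[t + 1 :] * hist[t + 1 :]).sum() / (w1 * total)
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def reference_moments_threshold(hist):
    """Independent moment-preserving threshold.

    Derives the binary-distribution coefficients by solving the moment
    linear system with numpy and the representative levels as roots of
    the resulting quadratic, then walks the cumulative histogram.
    """
    hist = np.asarray(hist, dtype=float)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0])
    p = hist / hist.sum()
    x = np.arange(256.0)
    m = [float((x**k * p).sum()) for k in range(4)]
    try:
        c0, c1 = np.linalg.solve(
            np.array([[m[0], m[1]], [m[1], m[2]]]), np.array([-m[2], -m[3]])
        )
    except np.linalg.LinAlgError:
        return int(nonzero[0])
    roots = np.roots([1.0, c1, c0])
    roots = np.sort(np.real(roots))
    z0, z1 = roots
    if z1 == z0:
        return int(nonzero[0])
    p0 = min(max((z1 - m[1]) / (z1 - z0), 0.0), 1.0)
    cum = 0.0
    for t in range(256):
        cum += p[t]
        if cum >= p0 - 1e-7:  # exact ties belong to the lower level
            return t
    return 255
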