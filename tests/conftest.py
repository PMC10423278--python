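import numpy as np
import pytest

from dcip.simulate import SimulationConfig, generate_leaf_stack


def clean_config(**overrides):
    """A noise-free, blur-free, unquantized simulation configuration with
    well-separated nuclei — the regime where measured ratios must equal the
    assigned truths to machine precision."""
    defaults = dict(
        volume_shape=(16, 192, 192),
        voxel_size=(3.0, 0.5, 0.5),
        n_nuclei=20,
        nucleus_radii=(2.0, 3.0),
        red_intensity=(8.0, 0.0),  # uniformly bright: the identity regime
        n_chloroplasts=0,
        psf_sigma=(0.0, 0.0, 0.0),
        poisson_gain=None,
        read_noise_sd=0.0,
        bit_depth=None,
        min_separation=14.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def clean_stack():
    """One noiseless stack of 20 separated nuclei plus its ground truth."""
    return generate_leaf_stack(clean_config())


@pytest.fixture(scope="session")
def noisy_stack():
    """A default-condition stack (blur, noise, chloroplasts, quantization)."""
    cfg = SimulationConfig(n_nuclei=40, min_separation=14.0, seed=7)
    return generate_leaf_stack(cfg)


def flood_fill_labels(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent connected-component oracle: iterative BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 6:
        offsets = [
            (dz, dy, dx)
            for dz, dy, dx in [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        ]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    labels = np.zeros(binary.shape, dtype=np.int32)
    current = 0
    nz, ny, nx = binary.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not binary[z, y, x] or labels[z, y, x]:
                    continue
                current += 1
                stack = [(z, y, x)]
                labels[z, y, x] = current
                while stack:
                    cz, cy, cx = stack.pop()
                    for dz, dy, dx in offsets:
                        pz, py, px = cz + dz, cy + dy, cx + dx
                        if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                            if binary[pz, py, px] and not labels[pz, py, px]:
                                labels[pz, py, px] = current
                                stack.append((pz, py, px))
    return labels


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label volumes agree up to a bijective relabeling."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def brute_force_otsu(hist: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over all cut points."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    bins = np.arange(hist.size)
    best_t, best_v = 0, -np.inf
    for t in range(hist.size - 1):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[: t + 1] * bins[: t + 1]).sum() / w0
        m1 = (hist[t + 1 :] * bins[t + 1 :]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t
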