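"""Synthetic manifold benchmarks with known intrinsic dimension.

The flagship dataset mixes three shapes in 3-D — a torus, a conical
spiral and a sphere — perturbs the three coordinates with Gaussian noise
and pads the matrix with pure-noise coordinates up to an ambient dimension
of 20 (5100 points total by default).  Because the 3-D noise thickens each
surface into a locally 3-dimensional cloud, the de-noised intrinsic
dimension of the benchmark is 3 by construction, which makes it a clean
probe for the dimension estimator and the adaptive embedders.

Uniform hypercube and hypersphere samplers are also provided as fixtures
for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ManifoldSpec",
    "generate_manifold_dataset",
    "sample_torus",
    "sample_sphere",
    "sample_spiral",
    "sample_hypercube",
    "sample_hypersphere_surface",
]


def sample_torus(
    n: int,
    rng: np.random.Generator,
    R: float = 2.0,
    r: float = 0.5,
    center: tuple = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Uniform (by surface area) sample on a torus of radii ``R > r``.

    Naive uniform sampling of the two angles over-represents the inner rim;
    the poloidal angle is rejection-corrected with acceptance probability
    ``(R + r cos(theta)) / (R + r)``.
    """
    if r >= R:
        raise ValueError(f"torus inner radius must be below outer radius ({r} >= {R})")
    theta = np.empty(n)
    got = 0
    while got < n:
        cand = rng.uniform(0.0, 2.0 * np.pi, size=2 * (n - got))
        keep = rng.uniform(size=cand.size) < (R + r * np.cos(cand)) / (R + r)
        take = cand[keep][: n - got]
        theta[got : got + take.size] = take
        got += take.size
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.asarray(center) + np.column_stack(
        [
            (R + r * np.cos(theta)) * np.cos(phi),
            (R + r * np.cos(theta)) * np.sin(phi),
            r * np.sin(theta),
        ]
    )


def sample_sphere(
    n: int,
    rng: np.random.Generator,
    radius: float = 1.0,
    center: tuple = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Uniform sample on a sphere surface in 3-D (Gaussian projection)."""
    g = rng.normal(size=(n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return np.asarray(center) + radius * g


def sample_spiral(
    n: int,
    rng: np.random.Generator,
    turns: float = 2.0,
    scale: float = 0.25,
    center: tuple = (0.0, 0.0, 1.5),
) -> np.ndarray:
    """Conical spiral ``scale * (t cos t, t sin t, t)``, ``t in [0, 2*pi*turns]``.

    Offset above the torus/sphere pair by default so the three shapes are
    adjacent but non-intersecting.
    """
    t = rng.uniform(0.0, 2.0 * np.pi * turns, size=n)
    return np.asarray(center) + scale * np.column_stack(
        [t * np.cos(t), t * np.sin(t), t]
    )


@dataclass(frozen=True)
class ManifoldSpec:
    """Configuration of the mixed-manifold benchmark.

    ``noise_sd`` perturbs the three manifold coordinates; ``extra_noise_sd``
    is the scale of the ``ambient_D - 3`` pure-noise coordinates.
    """

    shapes: tuple = ("torus", "spiral", "sphere")
    n_per_shape: tuple = (1700, 1700, 1700)
    ambient_D: int = 20
    noise_sd: float = 0.1
    extra_noise_sd: float = 0.02
    shape_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if len(self.shapes) != len(self.n_per_shape):
            raise ValueError("shapes and n_per_shape must align")
        if self.ambient_D < 3:
            raise ValueError("ambient dimension must be at least 3")
        if self.noise_sd < 0 or self.extra_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")


_SAMPLERS = {
    "torus": sample_torus,
    "spiral": sample_spiral,
    "sphere": sample_sphere,
}


def generate_manifold_dataset(
    spec: ManifoldSpec = ManifoldSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate the mixed-manifold benchmark.

    Returns
    -------
    X : (n, ambient_D) array
        Noisy coordinates: shapes + Gaussian noise in the first three
        columns, pure Gaussian noise in the remaining ones.
    labels : (n,) int array
        Shape membership, in the order listed in ``spec.shapes``.
    clean : (n, 3) array
        Noise-free manifold coordinates, for oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    parts, labels = [], []
    for lab, (shape, m) in enumerate(zip(spec.shapes, spec.n_per_shape)):
        if shape not in _SAMPLERS:
            raise ValueError(f"unknown shape {shape!r}")
        kwargs = spec.shape_params.get(shape, {})
        parts.append(_SAMPLERS[shape](m, rng, **kwargs))
        labels.append(np.full(m, lab, dtype=np.int64))
    clean = np.vstack(parts)
    labels = np.concatenate(labels)
    n = clean.shape[0]
    X = np.empty((n, spec.ambient_D))
    X[:, :3] = clean + rng.normal(0.0, spec.noise_sd, size=(n, 3))
    X[:, 3:] = rng.normal(0.0, spec.extra_noise_sd, size=(n, spec.ambient_D - 3))
    return X, labels, clean


def sample_hypercube(
    n: int, d: int, ambient_D: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample on the unit ``d``-cube, zero-padded to ``ambient_D``."""
    if ambient_D < d:
        raise ValueError("ambient dimension below intrinsic dimension")
    X = np.zeros((n, ambient_D))
    X[:, :d] = rng.uniform(size=(n, d))
    return X


def sample_hypersphere_surface(
    n: int, d: int, ambient_D: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample on the ``d``-sphere surface in ``R**(d+1)``, zero-padded."""
    if ambient_D < d + 1:
        raise ValueError("ambient dimension too small for the sphere surface")
    g = rng.normal(size=(n, d + 1))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    X = np.zeros((n, ambient_D))
    X[:, : d + 1] = g
    return X
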