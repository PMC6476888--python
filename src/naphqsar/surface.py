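"""CoMSA descriptors: surface sampling and Kohonen-map projection.

The molecular surface of each aligned molecule is sampled quasi-uniformly
(Fibonacci spirals on per-atom vdW spheres, interior points culled) and
annotated with the molecular electrostatic potential.  A self-organizing
map is trained on the xyz coordinates of the template molecule's surface
(the most active analog, 8c, in the original workflow); every molecule is
then projected through the frozen map into a fixed-length side^2 vector of
mean surface potentials, the CoMSA descriptor block fed to PLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from naphqsar.fields import COULOMB_KCAL, LJ_PARAMS
from naphqsar.structures import Conformer


@dataclass(frozen=True)
class SurfaceSample:
    """Surface points [A] of one molecule with the potential at each point."""

    compound_id: str
    points: np.ndarray  # (n, 3)
    potentials: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if len(self.points) != len(self.potentials):
            raise ValueError("points and potentials must have equal length")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sample_surface(conformer: Conformer, density: float = 5.0) -> SurfaceSample:
    """Quasi-uniform vdW-surface points with Coulomb potential values.

    ``density`` is in points per square angstrom of sphere area before
    interior culling.  Potential at point p: sum_i 332.06 q_i / |p - r_i|
    [kcal/(mol*e)].
    """
    if density <= 0:
        raise ValueError("density must be positive")
    xyz = conformer.coords
    radii = np.array([LJ_PARAMS.get(s, LJ_PARAMS["C"])[0] for s in conformer.symbols])
    pts = []
    for i, (center, r) in enumerate(zip(xyz, radii)):
        n = max(int(np.ceil(density * 4.0 * np.pi * r * r)), 8)
        sphere = center + r * _fibonacci_sphere(n)
        d = np.linalg.norm(sphere[:, None, :] - xyz[None, :, :], axis=2)
        d[:, i] = np.inf  # own sphere never culls its points
        keep = (d >= radii[None, :] - 1e-9).all(axis=1)
        pts.append(sphere[keep])
    points = np.vstack(pts)
    dist = np.linalg.norm(points[:, None, :] - xyz[None, :, :], axis=2)
    potentials = COULOMB_KCAL * (conformer.charges[None, :] / np.maximum(dist, 1e-12)).sum(axis=1)
    return SurfaceSample(conformer.compound_id, points, potentials)


class KohonenMap(BaseEstimator, TransformerMixin):
    """Square self-organizing map over 3D surface coordinates.

    Parameters
    ----------
    side : int
        Map edge; 20 or 30 in the reference workflow (400/900 neurons).
        Other values need ``allow_any_side=True``.
    md : float
        Winning distance [A]; during projection a surface point is accepted
        by its best-matching neuron only if it lies within ``md``.
    n_epochs : int
        Full passes over the training sample; learning rate and Gaussian
        neighborhood radius decay exponentially across epochs.
    fill_value : float
        Descriptor entry for neurons no accepted point maps to.
    random_state : int
        Seed; training is deterministic for a fixed seed.
    """

    def __init__(
        self,
        side: int = 30,
        md: float = 2.0,
        n_epochs: int = 10,
        learning_rate: float = 0.5,
        fill_value: float = 0.0,
        aggregate: str = "mean",
        allow_any_side: bool = False,
        random_state: int = 0,
    ):
        self.side = side
        self.md = md
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.fill_value = fill_value
        self.aggregate = aggregate
        self.allow_any_side = allow_any_side
        self.random_state = random_state

    def _validate(self) -> None:
        if self.side not in (20, 30) and not self.allow_any_side:
            raise ValueError("side must be 20 or 30 (set allow_any_side=True to override)")
        if not 0.2 <= self.md <= 2.0:
            raise ValueError("winning distance md must lie in [0.2, 2.0]")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")

    def fit(self, X, y=None) -> "KohonenMap":
        """Train the codebook on surface coordinates X of shape (n, 3)."""
        self._validate()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3 or len(X) == 0:
            raise ValueError("X must be a nonempty (n, 3) coordinate array")
        rng = np.random.default_rng(self.random_state)
        n_neurons = self.side * self.side
        lo, hi = X.min(axis=0), X.max(axis=0)
        codebook = rng.uniform(lo, hi, size=(n_neurons, 3))
        gi, gj = np.divmod(np.arange(n_neurons), self.side)
        grid = np.column_stack([gi, gj]).astype(float)

        r0, r_end = self.side / 2.0, 0.5
        lr0, lr_end = self.learning_rate, 0.01
        qe = []
        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            radius = r0 * (r_end / r0) ** frac
            lr = lr0 * (lr_end / lr0) ** frac
            for idx in rng.permutation(len(X)):
                x = X[idx]
                bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
                g2 = ((grid - grid[bmu]) ** 2).sum(axis=1)
                h = lr * np.exp(-g2 / (2.0 * radius * radius))
                codebook += h[:, None] * (x - codebook)
            d = np.linalg.norm(X[:, None, :] - codebook[None, :, :], axis=2)
            qe.append(float(d.min(axis=1).mean()))
        self.codebook_ = codebook
        self.quantization_errors_ = np.array(qe)
        self.n_features_in_ = 3
        return self

    def project(self, sample: SurfaceSample) -> np.ndarray:
        """Length-side^2 descriptor: per-neuron mean potential of points
        whose best-matching neuron lies within the winning distance."""
        check_is_fitted(self, "codebook_")
        d = np.linalg.norm(sample.points[:, None, :] - self.codebook_[None, :, :], axis=2)
        bmu = d.argmin(axis=1)
        ok = d[np.arange(len(bmu)), bmu] <= self.md
        vec = np.full(self.side * self.side, float(self.fill_value))
        if not ok.any():
            warnings.warn(
                f"no surface point of {sample.compound_id!r} within md={self.md}; "
                "returning all-fill vector",
                stacklevel=2,
            )
            return vec
        agg = np.mean if self.aggregate == "mean" else np.median
        for neuron in np.unique(bmu[ok]):
            vec[neuron] = agg(sample.potentials[ok & (bmu == neuron)])
        return vec

    def transform(self, samples) -> np.ndarray:
        """Stack projections of an iterable of SurfaceSamples, (m, side^2)."""
        return np.vstack([self.project(s) for s in samples])


def train_som(
    template: SurfaceSample,
    side: int = 30,
    md: float = 2.0,
    seed: int = 0,
    **kwargs,
) -> KohonenMap:
    """Fit a map on the template molecule's surface coordinates."""
    if len(template.points) == 0:
        raise ValueError("template sample is empty")
    som = KohonenMap(side=side, md=md, random_state=seed, **kwargs)
    return som.fit(template.points)


def project_molecule(som: KohonenMap, sample: SurfaceSample) -> np.ndarray:
    """Functional alias for :meth:`KohonenMap.project`."""
    return som.project(sample)


def build_comsa_matrix(som: KohonenMap, samples: dict[str, SurfaceSample]):
    """Compounds x side^2 CoMSA descriptor DataFrame."""
    import pandas as pd

    rows = {cid: som.project(s) for cid, s in samples.items()}
    columns = pd.MultiIndex.from_tuples(
        [("som", i) for i in range(som.side * som.side)], names=["field", "point"]
    )
    return pd.DataFrame.from_dict(rows, orient="index").set_axis(columns, axis=1)
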