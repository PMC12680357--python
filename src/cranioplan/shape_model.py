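"""Statistical shape modelling of corresponding surface meshes.

Shapes sharing one topology are vectorised as ``[x1, y1, z1, ...,
xN, yN, zN]`` and modelled as mean plus a linear combination of
orthonormal modes of variation:

    m  =  m_bar + Phi b

where ``Phi``'s columns are the eigenvectors of the sample covariance of
the mean-centred shape vectors, the eigenvalues quantify the variance
each mode explains, and the coefficient vector ``b`` is the
low-dimensional encoding the surrogate regressor consumes.  The number
of retained modes is the smallest count whose cumulative explained
variance reaches the configured threshold (default 94%).

With n shapes of dimension 3N (3N >> n here), the eigenpairs are
computed by thin SVD of the deviation matrix rather than by
eigendecomposition of the explicit 3N x 3N covariance — mathematically
identical and tested against the dense route.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["StatisticalShapeModel"]


def _procrustes_align(X: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Generalised Procrustes: rigidly align each shape to the evolving mean."""
    shapes = X.reshape(X.shape[0], -1, 3).copy()
    mean = shapes[0]
    for _ in range(iterations):
        for i, s in enumerate(shapes):
            mu_s, mu_m = s.mean(axis=0), mean.mean(axis=0)
            H = (s - mu_s).T @ (mean - mu_m)
            U, _, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
            shapes[i] = (s - mu_s) @ R.T + mu_m
        mean = shapes.mean(axis=0)
    return shapes.reshape(X.shape[0], -1)


class StatisticalShapeModel(BaseEstimator, TransformerMixin):
    """PCA-based shape model over corresponding shape vectors.

    Parameters
    ----------
    variance_threshold : float in (0, 1]
        Retain the smallest number of modes whose cumulative explained
        variance reaches this fraction.
    procrustes : bool
        Rigidly align shapes to the mean before modelling.  Off by
        default: the synthetic pipeline produces construction-aligned
        shapes.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (3N,) mean shape vector
    components_ : (r, 3N) all non-degenerate modes, orthonormal rows,
        sorted by decreasing eigenvalue
    eigenvalues_ : (r,) sample variances along each mode (divisor n - 1)
    explained_variance_ratio_ : (r,) eigenvalue fractions, summing to 1
    n_modes_ : retained mode count for the variance threshold
    """

    def __init__(self, variance_threshold: float = 0.94, procrustes: bool = False):
        self.variance_threshold = variance_threshold
        self.procrustes = procrustes

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be (n_shapes, 3N)")
        n = X.shape[0]
        if n < 2:
            raise ValueError("at least two shapes are required")
        if X.shape[1] % 3 != 0:
            raise ValueError("shape vectors must have length 3N")
        if not (0.0 < self.variance_threshold <= 1.0):
            raise ValueError("variance_threshold must lie in (0, 1]")

        if self.procrustes:
            X = _procrustes_align(X)

        self.mean_ = X.mean(axis=0)
        D = X - self.mean_
        # thin SVD of the (n, 3N) deviation matrix: eigenvalues of the
        # covariance are s^2 / (n - 1); eigenvectors are the right singular
        # vectors
        _, s, Vt = np.linalg.svd(D, full_matrices=False)
        eig = s ** 2 / (n - 1)
        # drop numerically-zero modes (rank <= n - 1 after centring)
        keep = eig > max(eig[0], 1e-300) * 1e-12
        eig, Vt = eig[keep], Vt[keep]

        # reproducible sign: largest-magnitude entry of each mode positive
        flip = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
        Vt = Vt * flip[:, None]

        ratio = eig / eig.sum()
        cumulative = np.cumsum(ratio)
        self.components_ = Vt
        self.eigenvalues_ = eig
        self.explained_variance_ratio_ = ratio
        idx = np.searchsorted(cumulative, self.variance_threshold - 1e-12)
        self.n_modes_ = int(min(idx, len(eig) - 1) + 1)
        self.n_samples_ = n
        self.n_features_in_ = X.shape[1]
        return self

    # -- projection / reconstruction -------------------------------------

    def transform(self, X) -> np.ndarray:
        """Mode coefficients b = Phi^T (m - m_bar) for each row of ``X``."""
        check_is_fitted(self, "mean_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected shape vectors of length {self.n_features_in_}, "
                             f"got {X.shape[1]}")
        return (X - self.mean_) @ self.components_[: self.n_modes_].T

    def inverse_transform(self, B) -> np.ndarray:
        """Reconstruct shapes m_bar + Phi b; ``B`` may use fewer than n_modes_ columns."""
        check_is_fitted(self, "mean_")
        B = np.atleast_2d(np.asarray(B, dtype=np.float64))
        k = B.shape[1]
        if k > len(self.components_):
            raise ValueError(f"got {k} coefficients but the model has only "
                             f"{len(self.components_)} modes")
        return self.mean_ + B @ self.components_[:k]

    def project(self, shape_vector: np.ndarray) -> np.ndarray:
        """Single-shape convenience wrapper around :meth:`transform`."""
        return self.transform(shape_vector.reshape(1, -1))[0]

    def reconstruct(self, b: np.ndarray) -> np.ndarray:
        """Single-shape convenience wrapper around :meth:`inverse_transform`."""
        return self.inverse_transform(np.asarray(b).reshape(1, -1))[0]

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path, faces: np.ndarray | None = None) -> None:
        """Serialise to a directory: modes/eigenvalues as CSV, metadata as JSON,
        and the mean shape as STL when the template faces are provided."""
        check_is_fitted(self, "mean_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "mean.csv", self.mean_[None], delimiter=",")
        np.savetxt(directory / "modes.csv", self.components_, delimiter=",")
        np.savetxt(directory / "eigenvalues.csv", self.eigenvalues_[None], delimiter=",")
        meta = {
            "variance_threshold": self.variance_threshold,
            "n_modes": self.n_modes_,
            "n_samples": self.n_samples_,
            "n_features": self.n_features_in_,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))
        if faces is not None:
            from cranioplan.mesh import save_stl, unflatten_shape

            save_stl(unflatten_shape(self.mean_, faces), directory / "mean.stl")

    @classmethod
    def load(cls, directory: str | Path) -> "StatisticalShapeModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        model = cls(variance_threshold=meta["variance_threshold"])
        model.mean_ = np.loadtxt(directory / "mean.csv", delimiter=",")
        model.components_ = np.atleast_2d(np.loadtxt(directory / "modes.csv", delimiter=","))
        model.eigenvalues_ = np.atleast_1d(np.loadtxt(directory / "eigenvalues.csv", delimiter=","))
        model.explained_variance_ratio_ = model.eigenvalues_ / model.eigenvalues_.sum()
        model.n_modes_ = meta["n_modes"]
        model.n_samples_ = meta["n_samples"]
        model.n_features_in_ = meta["n_features"]
        return model
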