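"""Superimposition and ordination: centroid size, generalized Procrustes
analysis in shape and form (size-and-shape) space, single-case alignment,
object-symmetry symmetrization, floating-rib removal, and shape-space PCA.

Shape space removes translation, rotation and scale (every aligned
configuration has centroid size 1); form space removes translation and
rotation only, so absolute size in mm is retained — the reconstruction
stage relies on this to predict rib lengths in mm.  Superimposition
rotations are proper (determinant +1); reflection enters only through
:func:`symmetrize`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration
from .template import MIRROR_MATRIX, Template

GPA_TOL = 1e-12
# similar shapes converge in a handful of iterations; the cap only matters
# for pathologically dissimilar inputs, where the consensus moves slowly
GPA_MAX_ITER = 1000


def centroid_size(config) -> float:
    """Square root of the summed squared deviations of the coordinates from
    their centroid.

    Accepts a complete :class:`LandmarkConfiguration` or a (k, 3) array.
    """
    X = _as_array(config)
    if X.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 points")
    dev = X - X.mean(axis=0)
    cs = float(np.sqrt((dev ** 2).sum()))
    if cs <= 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


def _as_array(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        if not config.is_complete:
            raise ValueError(
                f"{config.specimen_id!r} has masked points; complete or "
                "reconstruct the configuration first")
        return config.coords
    X = np.asarray(config, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected a (k, 3) coordinate array")
    return X


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||A @ R - B|| for centered A, B."""
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes analysis.

    ``aligned`` has shape (n, k, 3); every aligned configuration is centered
    at the origin and, in shape space, scaled to centroid size 1.
    ``consensus`` is the coordinate-wise mean of the aligned configurations.
    """

    space: str
    labels: tuple[str, ...]
    consensus: np.ndarray
    aligned: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: tuple[str, ...]
    n_iterations: int

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def aligned_config(self, i: int) -> LandmarkConfiguration:
        return LandmarkConfiguration(
            self.specimen_ids[i], self.labels, self.aligned[i],
            np.ones(len(self.labels), dtype=bool))


def _prepare(configs, space: str):
    if space not in ("shape", "form"):
        raise ValueError("space must be 'shape' or 'form'")
    if len(configs) == 0:
        raise ValueError("need at least one configuration")
    labels = configs[0].labels
    for cfg in configs:
        if cfg.labels != labels:
            raise ValueError(
                f"inconsistent label sets: {cfg.specimen_id!r} does not "
                "match the first configuration")
    sizes = np.array([centroid_size(cfg) for cfg in configs])
    X = np.stack([_as_array(cfg) for cfg in configs])
    X = X - X.mean(axis=1, keepdims=True)
    if space == "shape":
        X = X / sizes[:, None, None]
    return labels, X, sizes


def gpa(configs, space: str = "shape") -> ProcrustesFit:
    """Generalized Procrustes analysis.

    Iterates rotation-to-consensus until the consensus root-mean-square
    change falls below 1e-12 (max 1000 iterations).
    """
    labels, X, sizes = _prepare(configs, space)
    n = X.shape[0]
    consensus = X[0].copy()
    n_iter = 0
    for n_iter in range(1, GPA_MAX_ITER + 1):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < GPA_TOL:
            break
    return ProcrustesFit(
        space=space, labels=labels, consensus=consensus, aligned=X,
        centroid_sizes=sizes,
        specimen_ids=tuple(c.specimen_id for c in configs),
        n_iterations=n_iter)


def align_case(case: LandmarkConfiguration, fit: ProcrustesFit
               ) -> LandmarkConfiguration:
    """Superimpose a single case onto a frozen fit's consensus.

    Uses the fit's space convention (form space preserves the case's
    centroid size exactly); the fit itself is not re-run.
    """
    if case.labels != fit.labels:
        raise ValueError("case labels do not match the fit's labels")
    X = _as_array(case)
    X = X - X.mean(axis=0)
    if fit.space == "shape":
        X = X / centroid_size(X)
    R = optimal_rotation(X, fit.consensus)
    return case.with_coords(X @ R)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root summed squared distance between two aligned configurations."""
    return float(np.sqrt(((a - b) ** 2).sum()))


def _mirror_relabel(X: np.ndarray, template: Template) -> np.ndarray:
    """Reflect about the midsagittal plane and swap paired labels."""
    return (X @ MIRROR_MATRIX.T)[template.mirror_permutation()]


def symmetrize(config: LandmarkConfiguration, template: Template
               ) -> LandmarkConfiguration:
    """Average a configuration with its relabeled mirror image.

    The configuration is first oriented so its best-fit midsagittal plane
    (through the midline points) is x = 0; the mirrored, relabeled copy is
    superimposed onto the original and the two are averaged.  A final
    averaging with the in-place mirror makes the output exactly
    mirror-symmetric under the template pairing.
    """
    if config.labels != template.labels:
        raise ValueError("configuration labels do not match template")
    X = _as_array(config).copy()
    mid = template.midline_mask()
    if not mid.any():
        raise ValueError("template has no midline points to orient by")

    # orient: rotate the fitted midline-plane normal onto +x, then shift the
    # plane to x = 0
    M = X[mid]
    c = M.mean(axis=0)
    _, _, Vt = np.linalg.svd(M - c)
    normal = Vt[-1]
    if normal[0] < 0:
        normal = -normal
    axis = np.cross(normal, [1.0, 0.0, 0.0])
    s = np.linalg.norm(axis)
    if s > 1e-12:
        axis = axis / s
        ang = np.arctan2(s, normal[0])
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        X = (X - c) @ R.T + c
    X[:, 0] -= X[mid, 0].mean()

    Xm = _mirror_relabel(X, template)
    # superimpose the mirror onto the original (rigid, no scaling)
    cX, cM = X.mean(axis=0), Xm.mean(axis=0)
    R = optimal_rotation(Xm - cM, X - cX)
    avg = (X + ((Xm - cM) @ R + cX)) / 2.0
    # exact projection onto the mirror-symmetric subspace
    out = (avg + _mirror_relabel(avg, template)) / 2.0
    return config.with_coords(out)


def drop_floating_ribs(obj):
    """Remove ribs 11 and 12 (both sides) from a template or configuration.

    Under the default 526-point template this leaves the 450-point analysis
    subset.  Already-reduced inputs pass through unchanged.
    """
    if isinstance(obj, Template):
        return obj.drop_ribs((11, 12))
    if isinstance(obj, LandmarkConfiguration):
        drop = {f"rib{n}_{side}" for n in (11, 12) for side in ("L", "R")}
        keep = [lab for lab in obj.labels
                if _element_of(lab) not in drop]
        return obj.restrict(keep)
    raise TypeError("expected a Template or LandmarkConfiguration")


def _element_of(label: str) -> str:
    if label.startswith("rib"):
        return "_".join(label.split("_")[:2])
    if label.startswith("sternum"):
        return "sternum"
    return label.split("_")[0]


@dataclass
class PCAResult:
    """Covariance PCA of aligned coordinates.

    ``directions`` rows are orthonormal component vectors in flattened
    (k*3) coordinate space; ``variance_fractions`` sum to 1 over the nonzero
    components; ``scores`` columns have zero mean.  ``degenerate`` flags a
    sample with no variation.
    """

    scores: np.ndarray
    directions: np.ndarray
    variance_fractions: np.ndarray
    degenerate: bool = False


def pca_shape(fit: ProcrustesFit) -> PCAResult:
    """PCA of the aligned coordinates of a Procrustes fit.

    Sign convention: the largest-magnitude loading of each direction is
    positive, making component orientation deterministic.
    """
    if fit.n_specimens < 2:
        raise ValueError("PCA needs at least 2 specimens")
    n = fit.n_specimens
    data = fit.aligned.reshape(n, -1)
    centered = data - data.mean(axis=0)
    total = float((centered ** 2).sum())
    if total <= 1e-24:
        k = centered.shape[1]
        return PCAResult(np.zeros((n, 0)), np.zeros((0, k)),
                         np.zeros(0), degenerate=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    nonzero = S > S[0] * 1e-12
    S, Vt = S[nonzero], Vt[nonzero]
    # deterministic sign: largest-|loading| entry of each direction positive
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    Vt = Vt * flip[:, None]
    scores = centered @ Vt.T
    fractions = S ** 2 / (S ** 2).sum()
    return PCAResult(scores=scores, directions=Vt,
                     variance_fractions=fractions)
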