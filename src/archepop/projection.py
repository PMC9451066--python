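"""Centering + thin SVD of the dosage matrix and the score-space maps.

N centered genotype vectors span at most N-1 dimensions, so projecting
them onto their right singular vectors is a rotation plus pruning of
unused axes: Euclidean geometry (distances, residual sums of squares) is
preserved exactly while the working dimensionality drops from M SNPs to
at most N-1 scores.  Archetypal analysis therefore runs on the scores
X' = U.Sigma and its archetypes are mapped back to SNP space with V.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from archepop.genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionModel",
    "fit_projection",
    "transform",
    "back_project",
    "truncate",
    "save_projection",
    "load_projection",
]

# singular values below this fraction of the largest are numerical noise
_NULL_RTOL = 1e-12


@dataclass
class ProjectionModel:
    """Centered thin-SVD model of an N x M dosage matrix.

    mu      : length-M column means used for centering
    V       : M x d orthonormal right singular vectors
    sigma   : length-d singular values, non-increasing
    scores  : N x d score matrix X' = U.Sigma
    """

    mu: np.ndarray
    V: np.ndarray
    sigma: np.ndarray
    scores: np.ndarray

    @property
    def n_components(self) -> int:
        return self.V.shape[1]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_variants(self) -> int:
        return self.mu.shape[0]


def fit_projection(g: GenotypeMatrix) -> ProjectionModel:
    """Center the dosage columns and compute the thin SVD X_c = U.Sigma.V^T.

    At most N-1 components are retained (centering removes one dimension);
    components whose singular value is numerically zero relative to the
    largest are dropped as well.  Only the thin factors are formed, never
    an M x M matrix.  Singular-vector signs are fixed (largest-magnitude
    entry of each V column made non-negative) so repeated runs agree.
    """
    x = np.asarray(g.dosages, dtype=float)
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean(axis=0)
    xc = x - mu
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    d = min(n - 1, m)
    u, s, vt = u[:, :d], s[:d], vt[:d]
    if s[0] <= 0:
        logger.warning("fit_projection: all rows identical; projection is degenerate (rank 0)")
        keep = np.zeros(d, dtype=bool)
        keep[0] = True  # keep one null axis so shapes stay sane
    else:
        keep = s > _NULL_RTOL * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    v = vt.T
    # deterministic sign: largest-|.| element of each V column non-negative
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v *= flip
    u *= flip
    return ProjectionModel(mu=mu, V=v, sigma=s, scores=u * s)


def transform(pm: ProjectionModel, g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Project dosage rows into score space: (X - mu) @ V.

    ``g`` may be a GenotypeMatrix over the same M variants in the same
    order as the fitted model, or a bare array of matching width.
    """
    if isinstance(g, GenotypeMatrix):
        if g.n_variants != pm.n_variants:
            raise ValueError(f"variant count mismatch: model has {pm.n_variants}, input has {g.n_variants}")
        x = g.dosages
    else:
        x = np.asarray(g, dtype=float)
        if x.shape[-1] != pm.n_variants:
            raise ValueError(f"variant count mismatch: model has {pm.n_variants}, input has {x.shape[-1]}")
    return (x - pm.mu) @ pm.V


def back_project(pm: ProjectionModel, z: np.ndarray) -> np.ndarray:
    """Map fit-space vectors back to SNP space: z @ V^T + mu.

    Re-adding mu makes back-projected archetypes dosage-like, directly
    comparable to the rows of the genotype matrix.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != pm.n_components:
        raise ValueError(f"expected {pm.n_components} components, got {z.shape[1]}")
    return z @ pm.V.T + pm.mu


def truncate(pm: ProjectionModel, d: int) -> ProjectionModel:
    """Keep only the top-d singular triplets (lossy dimensionality reduction)."""
    if not 1 <= d <= pm.n_components:
        raise ValueError(f"d must be in [1, {pm.n_components}], got {d}")
    return ProjectionModel(mu=pm.mu, V=pm.V[:, :d].copy(), sigma=pm.sigma[:d].copy(), scores=pm.scores[:, :d].copy())


def save_projection(pm: ProjectionModel, path: str | os.PathLike) -> None:
    """Save the model as a compressed archive of named arrays plus a JSON header."""
    header = json.dumps(
        {"n_samples": pm.n_samples, "n_variants": pm.n_variants, "n_components": pm.n_components}
    )
    np.savez_compressed(path, mu=pm.mu, V=pm.V, sigma=pm.sigma, scores=pm.scores, header=np.array(header))


def load_projection(path: str | os.PathLike) -> ProjectionModel:
    with np.load(path, allow_pickle=False) as arc:
        pm = ProjectionModel(mu=arc["mu"], V=arc["V"], sigma=arc["sigma"], scores=arc["scores"])
        header = json.loads(str(arc["header"]))
    if header["n_components"] != pm.n_components:
        raise ValueError("archive header inconsistent with array shapes")
    return pm
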