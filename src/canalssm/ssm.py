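"""Per-segment statistical shape model: iterative mean, PCA modes, mode
reconstruction, projection and a subject-count convergence analysis.

The model represents a corresponded shape M_p as a deformation of the mean
shape M̄ by a linear combination of orthonormal principal components with
per-subject weights. The main anatomical variations are visualized by walking
each component to ±2 standard deviations:

    M_{i,±2σ} = M̄ ± m_{i,PC} · 2·sqrt(λ_i)

Shapes are never scale-normalized: size (canal length above all) is a real
anatomical feature and is deliberately kept inside the model, so the mean is
computed with a rigid-only generalized Procrustes iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import kabsch
from .correspondence import CorrespondedMesh
from .errors import CanalSSMError, ParameterError, TopologyError
from .mesh import TriMesh

log = logging.getLogger(__name__)

#: Number of principal components reported in variation tables.
DEFAULT_N_PCS = 4


@dataclass
class SSMModel:
    """Mean shape + orthonormal modes of variation of one canal segment."""

    mean_shape: np.ndarray          # (Nn, 3)
    components: np.ndarray          # (k, 3*Nn), rows orthonormal, by descending λ
    eigenvalues: np.ndarray         # (k,), variances in mm^2
    weights: np.ndarray             # (Nt, k) per-subject scores
    faces: np.ndarray               # template topology
    n_subjects: int
    fraction: float | None = None
    aligned: np.ndarray = field(default=None, repr=False)  # (Nt, Nn, 3) GPA-aligned data

    @property
    def n_vertices(self) -> int:
        return len(self.mean_shape)

    def mean_mesh(self) -> TriMesh:
        return TriMesh(self.mean_shape.copy(), self.faces.copy())


def _stack(meshes) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (Nt, Nn, 3) + shared faces from CorrespondedMesh/TriMesh inputs."""
    verts, faces = [], None
    for m in meshes:
        v = m.vertices
        f = m.faces
        if faces is None:
            faces = np.asarray(f)
        elif not np.array_equal(faces, f):
            raise TopologyError("inputs do not share the template topology")
        verts.append(np.asarray(v, dtype=float))
    shapes = {v.shape for v in verts}
    if len(shapes) != 1:
        raise TopologyError("inputs do not share the template vertex count")
    return np.stack(verts), faces


def build_ssm(corresponded: list, fraction: float | None = None,
              mean_tol_mm: float = 1e-6, max_mean_iter: int = 100,
              align: bool = True) -> SSMModel:
    """Build the shape model from iso-topological corresponded meshes.

    The mean is the coordinate-wise average after rigidly re-aligning each
    subject to the evolving mean (generalized Procrustes, rotation +
    translation only), iterated until the mean moves less than `mean_tol_mm`.
    PCA is an SVD of the centered stacked coordinate matrix with sample
    normalization 1/(Nt-1); component signs are fixed so each component's
    largest-magnitude coordinate is positive. `align=False` skips the rigid
    re-alignment and decomposes the coordinates exactly as given.
    """
    if len(corresponded) < 3:
        raise ParameterError("build_ssm needs at least 3 subjects")
    X, faces = _stack(corresponded)
    nt, nn, _ = X.shape

    aligned = X.copy()
    mean = aligned.mean(axis=0)
    if align:
        for _ in range(max_mean_iter):
            for i in range(nt):
                T = kabsch(X[i], mean)
                aligned[i] = T.apply(X[i])
            new_mean = aligned.mean(axis=0)
            if np.abs(new_mean - mean).max() < mean_tol_mm:
                mean = new_mean
                break
            mean = new_mean

    D = aligned.reshape(nt, 3 * nn) - mean.reshape(1, 3 * nn)
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    eigenvalues = s ** 2 / (nt - 1)
    keep = min(nt - 1, len(eigenvalues))
    eigenvalues = eigenvalues[:keep]
    components = Vt[:keep]
    # deterministic sign: largest-magnitude coordinate of each component positive
    for r in range(keep):
        j = np.argmax(np.abs(components[r]))
        if components[r, j] < 0:
            components[r] = -components[r]
    weights = D @ components.T
    return SSMModel(mean_shape=mean, components=components,
                    eigenvalues=eigenvalues, weights=weights, faces=faces,
                    n_subjects=nt, fraction=fraction, aligned=aligned)


def reconstruct_mode(model: SSMModel, i: int, s: float) -> TriMesh:
    """Shape at `s` standard deviations along principal component `i` (1-based).

    vertices = mean + s * sqrt(λ_i) * m_{i,PC}; s = ±2 gives the ±2σ shapes.
    """
    if not 1 <= i <= len(model.eigenvalues):
        raise ParameterError(f"PC index {i} out of range 1..{len(model.eigenvalues)}")
    lam = model.eigenvalues[i - 1]
    if lam < 1e-18:     # mm^2; zero up to SVD roundoff
        if s != 0:
            log.warning("PC %d has zero variance; returning the mean shape", i)
        return model.mean_mesh()
    disp = s * np.sqrt(lam) * model.components[i - 1]
    v = model.mean_shape + disp.reshape(-1, 3)
    return TriMesh(v, model.faces.copy())


def explained_variance(model: SSMModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-PC explained-variance fractions and the cumulative curve."""
    total = model.eigenvalues.sum()
    if total < 1e-15:   # mm^2; below numerical noise of an exact-zero cohort
        raise CanalSSMError("all eigenvalues are zero: variance fractions undefined")
    fr = model.eigenvalues / total
    return fr, np.cumsum(fr)


def n_modes_for(model: SSMModel, threshold: float = 0.90) -> int:
    """Smallest number of modes whose cumulative explained variance >= threshold."""
    _, cum = explained_variance(model)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def project(model: SSMModel, mesh) -> np.ndarray:
    """Weights w_i = m_{i,PC} · (x - M̄) of a corresponded shape in model space."""
    v = mesh.vertices if hasattr(mesh, "vertices") else np.asarray(mesh)
    v = np.asarray(v, dtype=float)
    if v.shape != model.mean_shape.shape:
        raise TopologyError("shape does not match the model's vertex layout")
    d = (v - model.mean_shape).reshape(-1)
    return model.components @ d


def reconstruct_from_weights(model: SSMModel, weights: np.ndarray) -> TriMesh:
    """Inverse of `project` over the retained components."""
    d = np.asarray(weights, dtype=float) @ model.components
    return TriMesh(model.mean_shape + d.reshape(-1, 3), model.faces.copy())


def convergence_analysis(corresponded: list, sizes, reps: int = 20,
                         seed: int = 0) -> pd.DataFrame:
    """Stability of the model against cohort size, by random subsampling.

    For each subset size, `reps` random subsets are drawn and a sub-model is
    built; reported are (a) the RMS vertex distance of the rigidly re-aligned
    sub-mean to the full-cohort mean and (b) the ratio of total variance,
    sub/full — both flatten as the size approaches the full cohort.
    """
    full = build_ssm(corresponded)
    full_var = float(full.eigenvalues.sum())
    rng = np.random.default_rng(seed)
    nt = full.n_subjects
    rows = []
    for size in sizes:
        if size < 3:
            log.warning("skipping subset size %d (< 3 subjects)", size)
            continue
        if size > nt:
            raise ParameterError(f"subset size {size} exceeds cohort size {nt}")
        rms_vals, var_vals = [], []
        for _ in range(reps):
            idx = rng.choice(nt, size=size, replace=False)
            sub = build_ssm([corresponded[j] for j in idx])
            T = kabsch(sub.mean_shape, full.mean_shape)
            d = T.apply(sub.mean_shape) - full.mean_shape
            rms_vals.append(float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
            var_vals.append(float(sub.eigenvalues.sum()) / full_var
                            if full_var > 0 else np.nan)
        rows.append({"size": int(size),
                     "mean_rms_mm": float(np.mean(rms_vals)),
                     "sd_rms_mm": float(np.std(rms_vals)),
                     "mean_var_ratio": float(np.mean(var_vals)),
                     "sd_var_ratio": float(np.std(var_vals))})
    return pd.DataFrame(rows)
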