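"""Essential dynamics: covariance analysis of a pooled coordinate ensemble.

Frames from one or several simulations are least-squares fitted to a common
reference, the covariance matrix of the fitted (mass-unweighted) coordinates
of a selected bead subset is diagonalized, and frames are projected onto the
leading eigenvectors.  The first eigenvector of a two-state ensemble
captures the interstate transition; by convention its sign is fixed so that
a chosen "orient" structure (e.g. the outward-occluded state) projects
negative, which makes the transition run left-to-right in projection plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .order_params import Frameset


class FitError(ValueError):
    """Raised for degenerate superposition or ED inputs."""


def superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimal least-squares rigid-body superposition (Kabsch).

    Returns the fitted mobile coordinates and the minimized RMSD.  A proper
    rotation (det = +1) is enforced, so mirror images keep a nonzero
    residual.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError("superpose needs matching (n, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise FitError("superpose needs at least 3 beads")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    x = mobile - mc
    y = target - tc
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    if np.count_nonzero(s > 1e-12 * max(s[0], 1e-300)) < 2:
        raise FitError("rank-deficient configuration: superposition is ambiguous")
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    fitted = x @ rot + tc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return fitted, rmsd


def rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition."""
    return superpose(mobile, target)[1]


@dataclass
class EDModel:
    """Result of an essential-dynamics fit."""

    reference: np.ndarray  # (n_sel, 3) coordinates used for fitting, nm
    mean: np.ndarray  # (3 n_sel,) mean fitted coordinates
    eigenvectors: np.ndarray  # (n_modes, 3 n_sel), orthonormal rows
    eigenvalues: np.ndarray  # (n_modes,) nm^2, descending
    selection: np.ndarray  # bead indices analyzed

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise FitError("eigenvalues must be in descending order")

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def _fitted_selection(frames: Frameset, selection: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Fit each frame's selected beads to the reference; returns (F, 3n) rows."""
    out = np.empty((frames.n_frames, selection.size * 3))
    for f in range(frames.n_frames):
        fitted, _ = superpose(frames.coords[f, selection], reference)
        out[f] = fitted.ravel()
    return out


def fit_ed(
    framesets: Frameset | Sequence[Frameset],
    selection: np.ndarray | None = None,
    reference: np.ndarray | None = None,
    orient: np.ndarray | None = None,
) -> EDModel:
    """Covariance/eigenvector analysis of a pooled ensemble.

    Parameters
    ----------
    framesets:
        One or several framesets over the same bead table (e.g. the two
        wild-type state simulations, pooled).
    selection:
        Bead indices to analyze (default: all).  For homolog comparisons
        this is the structurally conserved segment set.
    reference:
        (n_sel, 3) coordinates to fit against; default: the selected beads
        of the first frame of the first frameset.
    orient:
        Optional (n_sel, 3) structure whose projection on the first
        eigenvector is forced negative, fixing the sign convention (e.g.
        pass the outward-occluded state so the transition reads left to
        right).
    """
    if isinstance(framesets, Frameset):
        framesets = [framesets]
    n_beads = framesets[0].structure.n_beads
    selection = (
        np.arange(n_beads) if selection is None else np.asarray(selection, int)
    )
    if selection.size == 0:
        raise FitError("empty selection")
    if reference is None:
        reference = framesets[0].coords[0, selection]
    reference = np.asarray(reference, dtype=float)

    rows = np.vstack([_fitted_selection(fs, selection, reference) for fs in framesets])
    if rows.shape[0] < 2:
        raise FitError("essential dynamics needs >= 2 pooled frames")
    mean = rows.mean(axis=0)
    centered = rows - mean
    cov = centered.T @ centered / rows.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes

    # deterministic sign: largest-magnitude component positive
    for v in evecs:
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v *= -1.0
    model = EDModel(
        reference=reference, mean=mean,
        eigenvectors=evecs, eigenvalues=evals, selection=selection,
    )
    if orient is not None:
        fitted, _ = superpose(np.asarray(orient, float), reference)
        if (fitted.ravel() - mean) @ model.eigenvectors[0] > 0:
            model.eigenvectors[0] *= -1.0
    return model


def project(
    frames: Frameset, model: EDModel, n_vec: int = 2
) -> np.ndarray:
    """Project frames onto the leading eigenvectors.

    Each frame is fitted to the model reference, centered by the model mean
    and dotted with the first ``n_vec`` eigenvectors; returns an
    (n_frames, n_vec) array in nm.
    """
    if frames.structure.n_beads <= model.selection.max():
        raise FitError("frameset incompatible with model selection")
    rows = _fitted_selection(frames, model.selection, model.reference)
    return (rows - model.mean) @ model.eigenvectors[:n_vec].T


def project_structure(coords: np.ndarray, model: EDModel, n_vec: int = 2) -> np.ndarray:
    """Project a single full-structure coordinate array (n_beads, 3)."""
    fitted, _ = superpose(np.asarray(coords, float)[model.selection], model.reference)
    return (fitted.ravel() - model.mean) @ model.eigenvectors[:n_vec].T
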