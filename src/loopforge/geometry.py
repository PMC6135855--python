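"""Coordinate kernels and RMSD machinery.

The fragment search rests on two frame-invariant shape comparisons between
equal-length C-alpha point sets:

* the Binet-Cauchy kernel, ``det(X'Y) / sqrt(det(X'X) det(Y'Y))`` on
  centered coordinate matrices — 1 for identical shapes, sign-sensitive to
  chirality;
* the Rigidity score — the largest discrepancy between center-relative
  distances of paired points, combined with the end-to-end distance
  discrepancy, in angstroms.

Model assessment uses three RMSD variants over main-chain atoms that
differ only in which atoms define the superposition: the loop itself
(local), the flanks (flanked) or everything but the loop (global).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DegenerateFragmentError", "SuperpositionResult", "bc_kernel",
    "rigidity", "superimpose", "rmsd", "local_rmsd", "flanked_rmsd",
    "global_rmsd",
]


class DegenerateFragmentError(ValueError):
    """Point set is rank-deficient after centering; the kernel is undefined."""


@dataclasses.dataclass
class SuperpositionResult:
    """Optimal rigid map ``y -> rotation @ y + translation`` onto X."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _as_points(x, min_n: int = 3) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an N x 3 coordinate array")
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.shape[0]}")
    return x


def bc_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Binet-Cauchy kernel between two equal-length point sets.

    Both sets are centered at their geometric centers internally.  The
    score is invariant to translation and proper rotation of either
    argument, lies in [-1, 1], equals 1 for a perfect shape match and
    flips sign under reflection.
    """
    x = _as_points(x)
    y = _as_points(y)
    if x.shape != y.shape:
        raise ValueError("point sets must have equal length")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    gx = xc.T @ xc
    gy = yc.T @ yc
    gxx = np.linalg.det(gx)
    gyy = np.linalg.det(gy)
    # det(G) <= (tr G / 3)^3; a det far below that bound means the set is
    # collinear or coplanar and the kernel denominator vanishes
    tol_x = 1e-12 * max((np.trace(gx) / 3) ** 3, 1e-30)
    tol_y = 1e-12 * max((np.trace(gy) / 3) ** 3, 1e-30)
    if gxx <= tol_x or gyy <= tol_y:
        raise DegenerateFragmentError(
            "rank-deficient (collinear/coplanar) point set")
    return float(np.linalg.det(xc.T @ yc) / np.sqrt(gxx * gyy))


def rigidity(x: np.ndarray, y: np.ndarray, mode: str = "text") -> float:
    """Rigidity score between two equal-length C-alpha sets, in angstroms.

    ``mode="text"`` (default): the maximum over positions of the absolute
    difference between each point's distance to its own geometric center,
    combined with the end-to-end (first-to-last) distance difference.
    This reading is invariant to rigid motion of either argument.

    ``mode="printed"``: the first term is instead the maximum norm of the
    paired coordinate difference, evaluated in the lab frame (not
    rotation-invariant; provided for comparison).
    """
    x = _as_points(x, min_n=2)
    y = _as_points(y, min_n=2)
    if x.shape != y.shape:
        raise ValueError("point sets must have equal length")
    if mode == "text":
        dx = np.linalg.norm(x - x.mean(axis=0), axis=1)
        dy = np.linalg.norm(y - y.mean(axis=0), axis=1)
        r1 = float(np.max(np.abs(dx - dy)))
    elif mode == "printed":
        r1 = float(np.max(np.linalg.norm(x - y, axis=1)))
    else:
        raise ValueError("mode must be 'text' or 'printed'")
    end_x = float(np.linalg.norm(x[-1] - x[0]))
    end_y = float(np.linalg.norm(y[-1] - y[0]))
    return max(r1, abs(end_x - end_y))


def superimpose(x: np.ndarray, y: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of Y onto X."""
    x = _as_points(x)
    y = _as_points(y)
    if x.shape != y.shape:
        raise ValueError("point sets must have equal length")
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(x - cx, y - cy)
    matrix = rot.as_matrix()
    return SuperpositionResult(
        rotation=matrix,
        translation=cx - matrix @ cy,
        rmsd=float(rssd / np.sqrt(x.shape[0])),
    )


def rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Plain coordinate RMSD with no superposition."""
    x = np.asarray(x, dtype=float).reshape(-1, 3)
    y = np.asarray(y, dtype=float).reshape(-1, 3)
    if x.shape != y.shape:
        raise ValueError("coordinate arrays must have equal shape")
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def _flatten_atoms(coords: np.ndarray) -> np.ndarray:
    # (L, A, 3) residue-major main-chain blocks -> (L*A, 3)
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def _check_range(n: int, loop_range: tuple[int, int]) -> tuple[int, int]:
    start, stop = loop_range
    if not (0 <= start < stop <= n):
        raise ValueError(f"loop range {loop_range} outside structure of "
                         f"length {n}")
    return start, stop


def local_rmsd(model_loop: np.ndarray, native_loop: np.ndarray) -> float:
    """Best-fit RMSD of the loop atoms alone."""
    a = _flatten_atoms(model_loop)
    b = _flatten_atoms(native_loop)
    return superimpose(b, a).rmsd


def flanked_rmsd(model: np.ndarray, native: np.ndarray,
                 loop_range: tuple[int, int], flank_size: int = 4) -> float:
    """Superpose flank atoms only, then measure loop RMSD without refit.

    ``model`` and ``native`` are (L, A, 3) residue-major main-chain arrays
    over the same residue range; ``loop_range`` is a 0-based half-open
    residue index range.  ``flank_size`` residues each side of the loop
    define the fit (clipped to what the structures contain).
    """
    model = np.asarray(model, dtype=float)
    native = np.asarray(native, dtype=float)
    if model.shape != native.shape:
        raise ValueError("model and native must share residue range")
    start, stop = _check_range(model.shape[0], loop_range)
    lo = max(0, start - flank_size)
    hi = min(model.shape[0], stop + flank_size)
    flank_idx = list(range(lo, start)) + list(range(stop, hi))
    if not flank_idx:
        raise ValueError("no flank residues available for superposition")
    fit = superimpose(_flatten_atoms(native[flank_idx]),
                      _flatten_atoms(model[flank_idx]))
    moved = fit.apply(_flatten_atoms(model[start:stop]))
    return rmsd(moved, _flatten_atoms(native[start:stop]))


def global_rmsd(model: np.ndarray, native: np.ndarray,
                loop_range: tuple[int, int]) -> float:
    """Superpose everything except the loop, then measure loop RMSD."""
    model = np.asarray(model, dtype=float)
    native = np.asarray(native, dtype=float)
    if model.shape != native.shape:
        raise ValueError("model and native must share residue range")
    start, stop = _check_range(model.shape[0], loop_range)
    env_idx = list(range(0, start)) + list(range(stop, model.shape[0]))
    if not env_idx:
        raise ValueError("no environment residues available")
    fit = superimpose(_flatten_atoms(native[env_idx]),
                      _flatten_atoms(model[env_idx]))
    moved = fit.apply(_flatten_atoms(model[start:stop]))
    return rmsd(moved, _flatten_atoms(native[start:stop]))
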