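"""Procrustes machinery: superimposition, sliding semilandmarks, symmetry.

Implements the standard 2D geometric-morphometrics toolchain:

* centroid size and ordinary (pairwise) Procrustes alignment;
* generalized Procrustes analysis (GPA) — iterative least-squares removal of
  position, scale and orientation against an evolving consensus;
* thin-plate-spline (TPS) bending energy and minimum-bending-energy sliding
  of semilandmarks along their tangent chords;
* object-symmetry symmetrization (averaging each configuration with its
  reflected, relabeled, re-superimposed copy);
* TPS warping for deformation grids.

All shapes are ``(k, 2)`` arrays.  Aligned shapes are kept at unit centroid
size; physical centroid sizes (cm) are recorded separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkConfiguration, LandmarkScheme

__all__ = [
    "ProcrustesResult",
    "BendingEnergyModel",
    "centroid_size",
    "opa_align",
    "gpa",
    "slide_semilandmarks",
    "symmetrize",
    "tps_warp",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Square root of the summed squared distances of points to their centroid."""
    x = _as_coords(config)
    centered = x - x.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


@dataclass(frozen=True)
class OpaRecord:
    rotation: np.ndarray  # (2, 2) orthogonal
    scale: float
    residual: float  # root summed squared difference after fit
    reflected: bool  # a reflection would have fit better but was disallowed


def opa_align(
    target,
    reference,
    allow_reflection: bool = False,
    scale: bool = True,
) -> tuple[np.ndarray, OpaRecord]:
    """Least-squares superimposition of ``target`` onto ``reference``.

    Both configurations are centered; the optimal rotation comes from the SVD
    of the cross-covariance matrix.  With ``allow_reflection=False`` the
    nearest *proper* rotation is used and the record flags that a reflection
    would have fit better.
    """
    x = _as_coords(target)
    y = _as_coords(reference)
    if x.shape != y.shape:
        raise ValueError(f"point counts differ: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    det = np.linalg.det(u @ vt)
    reflected = False
    d = np.ones(2)
    if det < 0 and not allow_reflection:
        d[-1] = -1.0
        reflected = True
    rot = u @ np.diag(d) @ vt
    s_eff = s @ d
    if scale:
        sc = float(s_eff / np.sum(xc**2))
    else:
        sc = 1.0
    aligned = sc * xc @ rot
    residual = float(np.sqrt(np.sum((aligned - yc) ** 2)))
    return aligned, OpaRecord(rotation=rot, scale=sc, residual=residual, reflected=reflected)


@dataclass(frozen=True)
class ProcrustesResult:
    """Output of GPA: unit-size aligned shapes, consensus, sizes in cm."""

    aligned: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,), cm
    n_iterations: int
    converged: bool
    subject_ids: tuple[str, ...] = ()

    @property
    def flat(self) -> np.ndarray:
        """Shapes flattened to an (n, 2k) matrix for multivariate analysis."""
        n = self.aligned.shape[0]
        return self.aligned.reshape(n, -1)


def _unit(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean(axis=0)
    return centered / np.sqrt(np.sum(centered**2))


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation putting a shape into a deterministic orientation.

    The principal axis of the consensus is rotated onto y, with the sign
    chosen so the third moment along y is non-negative (ties broken on the
    x third moment).  This makes GPA output invariant — not merely
    invariant up to rotation — to similarity transforms of any input.
    """
    _, _, vt = np.linalg.svd(consensus - consensus.mean(axis=0), full_matrices=False)
    axis = vt[0]  # principal direction (x, y components)
    c, s = axis[1], axis[0]
    rot = np.array([[c, -s], [s, c]])  # sends `axis` to (0, 1)
    rotated = consensus @ rot.T
    m_y = np.sum(rotated[:, 1] ** 3)
    m_x = np.sum(rotated[:, 0] ** 3)
    if m_y < 0 or (m_y == 0 and m_x < 0):
        rot = -rot  # rotate a further 180 degrees (still proper)
    return rot


def gpa(
    configs,
    scheme: LandmarkScheme | None = None,
    slide: bool = True,
    max_iter: int = 100,
    tol: float = DEFAULT_TOL,
    max_slide_rounds: int = 5,
) -> ProcrustesResult:
    """Generalized Procrustes superimposition, optionally with sliding.

    Iterates align-to-consensus until the consensus moves less than ``tol``
    (root summed squared displacement).  When ``slide`` is true, semilandmark
    sliding against the evolving consensus is interleaved, at most
    ``max_slide_rounds`` times, stopping early once the total bending energy
    change falls below ``tol``.
    """
    if slide and (scheme is None or not scheme.sliders):
        raise ValueError("slide=True requires a scheme with slider definitions")
    coords = [_as_coords(c) for c in configs]
    if len(coords) < 2:
        raise ValueError("GPA needs at least two configurations")
    ids = tuple(
        c.subject_id if isinstance(c, LandmarkConfiguration) else f"config_{i}"
        for i, c in enumerate(configs)
    )
    sizes = np.array([centroid_size(x) for x in coords])
    shapes = np.stack([_unit(x) for x in coords])

    consensus = shapes[0].copy()
    converged = False
    n_iter = 0
    slide_rounds = 0
    prev_energy = np.inf
    for n_iter in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i], _ = opa_align(shapes[i], consensus, scale=True)
            shapes[i] = _unit(shapes[i])
        new_consensus = _unit(shapes.mean(axis=0))
        moved = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if slide and slide_rounds < max_slide_rounds:
            model = BendingEnergyModel(consensus)
            shapes, energy = slide_semilandmarks(
                shapes, consensus, scheme, model, return_energy=True
            )
            shapes = np.stack([_unit(s) for s in shapes])
            slide_rounds += 1
            if abs(prev_energy - energy) < tol:
                slide_rounds = max_slide_rounds  # sliding has converged
            prev_energy = energy
            continue  # consensus must be re-estimated after sliding
        if moved < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    # canonical orientation, then a final pass aligning every shape to it
    rot = _canonical_rotation(consensus)
    consensus = _unit(consensus @ rot.T)
    for i in range(shapes.shape[0]):
        shapes[i], _ = opa_align(shapes[i], consensus, scale=True)
        shapes[i] = _unit(shapes[i])
    return ProcrustesResult(
        aligned=shapes,
        consensus=_unit(shapes.mean(axis=0)),
        centroid_sizes=sizes,
        n_iterations=n_iter,
        converged=converged,
        subject_ids=ids,
    )


# --- thin-plate splines ----------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _tps_system(reference: np.ndarray) -> np.ndarray:
    k = reference.shape[0]
    d2 = np.sum((reference[:, None, :] - reference[None, :, :]) ** 2, axis=-1)
    kmat = _tps_kernel(d2)
    p = np.hstack([np.ones((k, 1)), reference])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    return lmat


class BendingEnergyModel:
    """Bending energy of displacement fields over a 2D reference shape.

    ``energy_matrix`` is the upper-left k-by-k block of the inverse TPS
    system matrix of the reference: symmetric, positive semi-definite, and
    annihilating every affine displacement field.
    """

    def __init__(self, reference) -> None:
        ref = _as_coords(reference)
        if ref.ndim != 2 or ref.shape[1] != 2:
            raise ValueError("reference must be (k, 2)")
        self.reference = ref
        lmat = _tps_system(ref)
        k = ref.shape[0]
        be = np.linalg.inv(lmat)[:k, :k]
        self.energy_matrix = (be + be.T) / 2.0

    def energy(self, target) -> float:
        """Bending energy of the map taking the reference onto ``target``."""
        d = _as_coords(target) - self.reference
        b = self.energy_matrix
        return float(d[:, 0] @ b @ d[:, 0] + d[:, 1] @ b @ d[:, 1])


def slide_semilandmarks(
    configs,
    consensus,
    scheme: LandmarkScheme,
    bending_model: BendingEnergyModel | None = None,
    ridge: float = 0.0,
    return_energy: bool = False,
):
    """Slide semilandmarks along their tangent chords, minimum bending energy.

    Each semilandmark may move only along the unit chord between its slider
    neighbors (evaluated on the configuration itself).  The sliding amounts
    minimize the bending energy of the deviation from the consensus,
    restricted to those tangent directions — a linear least-squares problem
    solved per configuration.  Total bending energy never increases (the
    zero-slide vector is feasible).
    """
    if bending_model is None:
        bending_model = BendingEnergyModel(_as_coords(consensus))
    cons = _as_coords(consensus)
    arr = np.stack([_as_coords(c) for c in configs])
    semis = list(scheme.sliders)
    m = len(semis)
    k = cons.shape[0]
    b = bending_model.energy_matrix
    bbig = np.zeros((2 * k, 2 * k))
    bbig[:k, :k] = b
    bbig[k:, k:] = b
    total_energy = 0.0
    out = arr.copy()
    for idx in range(arr.shape[0]):
        x = arr[idx]
        tangents = np.zeros((m, 2))
        for jj, j in enumerate(semis):
            a, _, c = scheme.sliders[j]
            chord = x[c] - x[a]
            norm = np.linalg.norm(chord)
            if norm == 0:
                raise ValueError(f"degenerate slider chord at semilandmark {j}")
            tangents[jj] = chord / norm
        # design matrix: column jj displaces semilandmark j along its tangent
        t = np.zeros((2 * k, m))
        for jj, j in enumerate(semis):
            t[j, jj] = tangents[jj, 0]
            t[k + j, jj] = tangents[jj, 1]
        d0 = np.concatenate([(x - cons)[:, 0], (x - cons)[:, 1]])
        lhs = t.T @ bbig @ t
        rhs = -t.T @ (bbig @ d0)
        if ridge > 0:
            lhs = lhs + ridge * np.eye(m)
        try:
            alpha = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            logger.warning("singular sliding system; using ridge-regularized solve")
            alpha = np.linalg.solve(lhs + 1e-10 * np.eye(m), rhs)
        d_new = d0 + t @ alpha
        e_new = float(d_new @ bbig @ d_new)
        e_old = float(d0 @ bbig @ d0)
        if e_new > e_old + 1e-12:  # exact solve guarantees non-increase
            alpha = np.zeros(m)
            e_new = e_old
        new_x = x.copy()
        for jj, j in enumerate(semis):
            new_x[j] = x[j] + alpha[jj] * tangents[jj]
        out[idx] = new_x
        total_energy += e_new
    if return_energy:
        return out, total_energy
    return out


# --- object symmetry -------------------------------------------------------


def _relabel_pairs(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    perm = np.arange(coords.shape[0])
    for left, right in scheme.bilateral_pairs:
        perm[left], perm[right] = right, left
    return coords[perm]


def _axis_align(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Rotate so the midline runs vertically, centered at x = 0.

    The midline direction is the dominant principal axis of the midline
    points; the sign is fixed so the face keeps y up (gnathion below nasion
    stays below after rotation).
    """
    x = coords - coords.mean(axis=0)
    mid = x[list(scheme.midline)]
    mid_c = mid - mid.mean(axis=0)
    _, _, vt = np.linalg.svd(mid_c, full_matrices=False)
    axis = vt[0]
    if axis[1] < 0:
        axis = -axis
    # rotation sending `axis` to (0, 1)
    c, s = axis[1], axis[0]
    rot = np.array([[c, -s], [s, c]])
    out = x @ rot.T
    out[:, 0] -= out[list(scheme.midline), 0].mean()
    return out


def symmetrize(configs, scheme: LandmarkScheme):
    """Remove asymmetric variation by reflect–relabel–refit averaging.

    Each configuration is averaged with its mirrored copy: reflect across
    the y axis, swap left/right labels, superimpose (reflection allowed —
    here it is the point) onto the original, average.  The average is then
    rotated so its midline is vertical and mirrored once more in that frame,
    which makes paired points exactly symmetric and midline points exactly
    on the axis.
    """
    if not scheme.bilateral_pairs or not scheme.midline:
        raise ValueError("symmetrize requires a scheme with pairs and midline")

    single = not isinstance(configs, (list, tuple)) and _as_coords(configs).ndim == 2
    items = [configs] if single else list(configs)
    out = []
    for cfg in items:
        x = _as_coords(cfg)
        xc = x - x.mean(axis=0)
        mirrored = xc * np.array([-1.0, 1.0])
        mirrored = _relabel_pairs(mirrored, scheme)
        fitted, _ = opa_align(mirrored, xc, allow_reflection=True, scale=True)
        avg = (xc + fitted) / 2.0
        avg = _axis_align(avg, scheme)
        # exact mirror averaging in the axis-aligned frame
        refl = _relabel_pairs(avg * np.array([-1.0, 1.0]), scheme)
        sym = (avg + refl) / 2.0
        sym[list(scheme.midline), 0] = 0.0
        if isinstance(cfg, LandmarkConfiguration):
            out.append(cfg.with_coords(sym))
        else:
            out.append(sym)
    return out[0] if single else out


# --- TPS warping -----------------------------------------------------------


def tps_warp(source_landmarks, target_landmarks, query_points) -> np.ndarray:
    """Thin-plate-spline interpolation mapping source onto target landmarks.

    Exact at the landmarks; the r^2 log r^2 kernel plus affine part gives the
    minimum-bending-energy smooth extension elsewhere.
    """
    src = _as_coords(source_landmarks)
    tgt = _as_coords(target_landmarks)
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    if src.shape != tgt.shape:
        raise ValueError("source and target must have the same shape")
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    if np.any(d2[~np.eye(src.shape[0], dtype=bool)] == 0):
        raise ValueError("duplicate source points")
    k = src.shape[0]
    lmat = _tps_system(src)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    params = np.linalg.solve(lmat, rhs)
    w, a = params[:k], params[k:]
    d2q = np.sum((q[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    u = _tps_kernel(d2q)
    return u @ w + np.hstack([np.ones((q.shape[0], 1)), q]) @ a
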