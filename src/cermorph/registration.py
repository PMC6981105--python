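"""Atlas-referenced registration: probability-map isolation, 12-DOF affine
alignment, and DCT-basis non-rigid registration producing deformation fields.

Conventions
-----------
* Displacement fields are **pull-back** fields in voxel units on the fixed
  grid: a warped image is ``moving`` sampled at ``x + d(x)``.  The deformed
  coordinates are ``(u, v, w) = (x, y, z) + d(x, y, z)``; the zero field is
  the identity mapping.
* The non-rigid displacement is a linear combination of the lowest ``K``
  3D discrete-cosine-transform basis functions per axis (coefficient tensor
  of shape ``3 x K x K x K``), regularized by the membrane energy (sum of
  squared first spatial derivatives of the displacement over the grid).
* Both stages minimize the sum of squared intensity differences (SSD) by
  Gauss-Newton with Levenberg damping; the cost is non-increasing across
  accepted steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import binary_dilation, map_coordinates, uniform_filter


class RegistrationError(RuntimeError):
    """Raised when a registration problem is ill-posed or diverges."""


# ---------------------------------------------------------------------------
# probability-map isolation


def threshold_probability(pmap: np.ndarray, p0: float = 0.5) -> np.ndarray:
    """Binary mask of voxels whose posterior probability strictly exceeds p0."""
    pmap = np.asarray(pmap)
    if pmap.min() < 0 or pmap.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return pmap > p0


# ---------------------------------------------------------------------------
# affine transforms


@dataclass
class AffineTransform:
    """12-parameter affine in voxel space, pull-back convention.

    ``matrix`` is the homogeneous 4x4 matrix mapping fixed voxel coordinates
    to moving voxel coordinates (the coordinates at which the moving image is
    sampled).  The 12-parameter vector is the 3 translations followed by the
    9 entries of the combined rotation/scale/shear matrix (row-major).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(cls, params: np.ndarray) -> "AffineTransform":
        params = np.asarray(params, dtype=np.float64)
        m = np.eye(4)
        m[:3, 3] = params[:3]
        m[:3, :3] = params[3:].reshape(3, 3)
        return cls(m)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.matrix[:3, 3], self.matrix[:3, :3].ravel()])

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of voxel coordinates."""
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {"matrix": self.matrix.tolist(), "params": self.params.tolist()},
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform":
        return cls(np.asarray(json.loads(Path(path).read_text())["matrix"]))


# ---------------------------------------------------------------------------
# sampling helpers


def _sample(vol: np.ndarray, pts: np.ndarray, mode: str = "constant") -> np.ndarray:
    """Trilinear sampling of ``vol`` at (N, 3) voxel coordinates."""
    return map_coordinates(vol, pts.T, order=1, mode=mode, cval=0.0)


def _grid_points(shape: tuple[int, ...]) -> np.ndarray:
    """All voxel coordinates of a grid, shape (nx, ny, nz, 3)."""
    ax = [np.arange(n, dtype=np.float64) for n in shape]
    return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

def default_mask(fixed: np.ndarray, dilate: int = 2) -> np.ndarray:
    """Support of the fixed image, slightly dilated: the SSD domain."""
    mask = np.abs(fixed) > 1e-3 * np.abs(fixed).max()
    if dilate:
        mask = binary_dilation(mask, iterations=dilate)
    return mask


def _downsample(vol: np.ndarray) -> np.ndarray:
    """Factor-2 downsampling after a 2-voxel box blur."""
    return uniform_filter(vol, size=2, mode="nearest")[::2, ::2, ::2]


# ---------------------------------------------------------------------------
# affine registration


def _gauss_newton_affine(
    moving: np.ndarray,
    fixed: np.ndarray,
    mask: np.ndarray,
    A: np.ndarray,
    t: np.ndarray,
    max_iter: int,
    tol: float,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    cf = (np.asarray(fixed.shape, dtype=np.float64) - 1) / 2
    cm = (np.asarray(moving.shape, dtype=np.float64) - 1) / 2
    idxs = np.argwhere(mask)
    if stride > 1:
        idxs = idxs[::stride]
    xc = idxs.astype(np.float64) - cf
    fvals = fixed[tuple(idxs.T)].astype(np.float64)
    grads = np.gradient(moving.astype(np.float64))

    def cost_at(A_, t_):
        pts = xc @ A_.T + (t_ + cm)
        r = _sample(moving, pts) - fvals
        return r, pts

    r, pts = cost_at(A, t)
    cost = float(r @ r)
    costs = [cost]
    mu = 0.0
    for _ in range(max_iter):
        g = np.stack([_sample(gr, pts) for gr in grads], axis=1)  # (N, 3)
        J = np.empty((xc.shape[0], 12))
        J[:, :3] = g
        J[:, 3:] = (g[:, :, None] * xc[:, None, :]).reshape(-1, 9)
        H = J.T @ J
        b = J.T @ r
        accepted = False
        for _ in range(8):
            damp = mu * np.diag(H) + 1e-12
            try:
                delta = np.linalg.solve(H + np.diag(damp), b)
            except np.linalg.LinAlgError:
                mu = max(mu * 10, 1e-6)
                continue
            t_new = t - delta[:3]
            A_new = A - delta[3:].reshape(3, 3)
            r_new, pts_new = cost_at(A_new, t_new)
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                A, t, r, pts = A_new, t_new, r_new, pts_new
                prev, cost = cost, cost_new
                costs.append(cost)
                mu = mu / 3 if mu > 1e-8 else 0.0
                accepted = True
                break
            mu = max(mu * 10, 1e-6)
        if not accepted:
            break
        if prev > 0 and (prev - cost) / prev < tol:
            break
    return A, t, costs


def affine_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
    stride: int = 1,
) -> AffineTransform:
    """12-DOF affine registration by multi-resolution Gauss-Newton SSD descent.

    Three of the parameters are the 3D translation; the other nine form the
    combined rotation/scale/shear matrix.  Volumes should be intensity
    normalized to a common range beforehand (:func:`~cermorph.atlas_io.
    normalize_intensity`).  Returns the transform mapping fixed voxel
    coordinates to moving voxel coordinates.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if mask is None:
        mask = default_mask(fixed)
    if not mask.any():
        raise RegistrationError("empty fixed-image mask: no overlap to register")

    pyr_m = [moving]
    pyr_f = [fixed]
    pyr_mask = [mask]
    for _ in range(levels - 1):
        if min(pyr_f[-1].shape) < 12:
            break
        pyr_m.append(_downsample(pyr_m[-1]))
        pyr_f.append(_downsample(pyr_f[-1]))
        pyr_mask.append(pyr_mask[-1][::2, ::2, ::2])

    A = np.eye(3)
    t = np.zeros(3)
    for lvl in range(len(pyr_f) - 1, -1, -1):
        if lvl < len(pyr_f) - 1:
            t = t * 2  # translations scale with resolution; the matrix does not
        lvl_stride = stride if pyr_mask[lvl].sum() > 4000 else 1
        A, t, _ = _gauss_newton_affine(
            pyr_m[lvl], pyr_f[lvl], pyr_mask[lvl], A, t, max_iter, tol,
            lvl_stride,
        )

    cf = (np.asarray(fixed.shape, dtype=np.float64) - 1) / 2
    cm = (np.asarray(moving.shape, dtype=np.float64) - 1) / 2
    m = np.eye(4)
    m[:3, :3] = A
    m[:3, 3] = t + cm - A @ cf
    return AffineTransform(m)


# ---------------------------------------------------------------------------
# DCT deformation model


def dct_basis(n: int, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal DCT-II basis (and its spatial derivative) on ``n`` points.

    Returns ``(B, dB)`` of shape (n, K): the K lowest-frequency components.
    """
    if K < 1:
        raise ValueError("basis order K must be >= 1")
    x = np.arange(n, dtype=np.float64)
    B = np.empty((n, K))
    dB = np.empty((n, K))
    for k in range(K):
        a = np.sqrt((1.0 if k == 0 else 2.0) / n)
        phase = np.pi * (2 * x + 1) * k / (2 * n)
        B[:, k] = a * np.cos(phase)
        dB[:, k] = -a * np.sin(phase) * (np.pi * k / n)
    return B, dB


@dataclass
class DCTDeformation:
    """Low-frequency DCT representation of a non-rigid displacement field.

    ``coeffs`` has shape (3, K, K, K): one K^3 coefficient block per
    displacement component, in voxel units on the fixed grid.
    """

    coeffs: np.ndarray
    shape: tuple[int, int, int]
    lam: float
    costs: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.coeffs.shape[1]

    def to_field(self) -> np.ndarray:
        """Reconstruct the dense displacement field, shape (nx, ny, nz, 3)."""
        bases = [dct_basis(n, self.K)[0] for n in self.shape]
        return np.ascontiguousarray(_synthesize(self.coeffs, *bases))


def membrane_matrix(shape: tuple[int, int, int], K: int) -> np.ndarray:
    """Gram matrix R with membrane energy = sum_c coeffs_c^T R coeffs_c.

    The membrane energy is the sum over grid voxels of the squared first
    spatial derivatives of the displacement; for the separable DCT basis it
    factorizes into Kronecker products of 1D Gram matrices.
    """
    mats = [dct_basis(n, K) for n in shape]
    G = [b.T @ b for b, _ in mats]
    Gd = [db.T @ db for _, db in mats]
    R = (
        np.kron(np.kron(Gd[0], G[1]), G[2])
        + np.kron(np.kron(G[0], Gd[1]), G[2])
        + np.kron(np.kron(G[0], G[1]), Gd[2])
    )
    return R


def _pair_products(B: np.ndarray) -> np.ndarray:
    """Row-wise outer products b_i(x) b_j(x), shape (n, K*K)."""
    n, K = B.shape
    return (B[:, :, None] * B[:, None, :]).reshape(n, K * K)


def _contract_sym(W: np.ndarray, Px, Py, Pz, K: int) -> np.ndarray:
    """Kronecker-separable J^T J block: sum_v W(v) b_i b_j ... -> (K^3, K^3).

    ``Px/Py/Pz`` are the per-axis basis pair products from
    :func:`_pair_products`; the triple contraction reduces to three matmuls.
    """
    t = np.tensordot(Px, W, axes=(0, 0))  # (Kx2, ny, nz)
    t = np.tensordot(Py, t, axes=(0, 1))  # (Ky2, Kx2, nz)
    t = np.tensordot(Pz, t, axes=(0, 2))  # (Kz2, Ky2, Kx2)
    t = t.reshape(K, K, K, K, K, K)  # (m, n, k, l, i, j) for z, y, x pairs
    # rows index (i, k, m), columns (j, l, n)
    return t.transpose(4, 2, 0, 5, 3, 1).reshape(K**3, K**3)


def _contract_vec(V: np.ndarray, Bx, By, Bz) -> np.ndarray:
    t = np.tensordot(Bx, V, axes=(0, 0))  # (K, ny, nz)
    t = np.tensordot(By, t, axes=(0, 1))  # (K, K, nz) -> (ky, kx, nz)
    t = np.tensordot(Bz, t, axes=(0, 2))  # (kz, ky, kx)
    return t.transpose(2, 1, 0).ravel()


def _synthesize(coeffs: np.ndarray, Bx, By, Bz) -> np.ndarray:
    """Dense displacement from DCT coefficients via separable tensordots.

    Returns shape (nx, ny, nz, 3) for coeffs (3, K, K, K).
    """
    t = np.tensordot(coeffs, Bx, axes=(1, 1))  # (3, K, K, nx)
    t = np.tensordot(t, By, axes=(1, 1))  # (3, K, nx, ny)
    t = np.tensordot(t, Bz, axes=(1, 1))  # (3, nx, ny, nz)
    return np.moveaxis(t, 0, -1)


def nonrigid_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    init: AffineTransform | None = None,
    K: int = 6,
    lam: float = 50.0,
    mask: np.ndarray | None = None,
    max_iter: int = 12,
    tol: float = 1e-4,
    stride: int = 1,
) -> tuple[DCTDeformation, np.ndarray]:
    """Non-rigid registration over DCT coefficients by Gauss-Newton.

    Minimizes ``SSD(fixed, moving o (affine o (id + d))) + lam * E(d)`` where
    ``E`` is the membrane energy of the displacement ``d`` and the affine
    pre-alignment ``init`` is held fixed.  The moving image is interpolated
    once per evaluation directly at ``affine(x + d(x))`` so no intermediate
    resampling error accumulates.  ``stride`` subsamples the masked voxels
    entering the normal equations (1 = use every voxel).  Returns the
    coefficient representation and the dense displacement field (voxel
    units, fixed grid); the Gauss-Newton cost is non-increasing across
    accepted steps (``DCTDeformation.costs``).
    """
    from scipy.linalg import cho_factor, cho_solve

    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if init is None:
        init = AffineTransform.identity()
    if mask is None:
        mask = default_mask(fixed)
    if not mask.any():
        raise RegistrationError("empty fixed-image mask")
    shape = fixed.shape

    idxs = np.argwhere(mask)
    lo, hi = idxs.min(axis=0), idxs.max(axis=0) + 1  # mask bounding box
    if stride > 1:
        idxs = idxs[::stride]
    local = idxs - lo
    bshape = tuple(hi - lo)
    fvals = fixed[tuple(idxs.T)]
    mpts = idxs.astype(np.float64)

    # basis rows restricted to the bounding box keep the contraction exact
    bases_full = [dct_basis(n, K)[0] for n in shape]
    Bc = [B[l:h] for B, l, h in zip(bases_full, lo, hi)]
    Pc = [_pair_products(B) for B in Bc]
    # membrane energy has a null space (constant displacements have zero
    # derivative); a small zeroth-order ridge pins that residual-translation
    # mode, which belongs to the affine stage anyway
    R = membrane_matrix(shape, K) + 1e-3 * np.eye(K**3)
    Amat = init.matrix[:3, :3]
    grads = np.gradient(moving)

    k3 = K**3
    coeffs = np.zeros((3, K, K, K))
    lidx = tuple(local.T)

    def evaluate(c):
        d = _synthesize(c, *Bc)  # displacement on the bounding box
        pts = mpts + d[lidx]
        q = init.map_points(pts)
        r = _sample(moving, q) - fvals
        pen = lam * sum(c[a].ravel() @ R @ c[a].ravel() for a in range(3))
        return q, r, float(r @ r) + pen

    q, r, cost = evaluate(coeffs)
    costs = [cost]
    mu = 0.0
    for _ in range(max_iter):
        g = np.stack([_sample(gr, q) for gr in grads], axis=1)  # (N, 3)
        ghat = g @ Amat  # chain rule through the fixed affine
        # scatter samples onto the box grid for the separable contraction
        Wg = np.zeros(bshape + (3,))
        Wg[lidx] = ghat
        Wr = np.zeros(bshape)
        Wr[lidx] = r

        H = np.zeros((3 * k3, 3 * k3))
        b = np.zeros(3 * k3)
        for a in range(3):
            for bb in range(a, 3):
                blk = _contract_sym(Wg[..., a] * Wg[..., bb], *Pc, K)
                H[a * k3:(a + 1) * k3, bb * k3:(bb + 1) * k3] = blk
                if bb != a:
                    H[bb * k3:(bb + 1) * k3, a * k3:(a + 1) * k3] = blk.T
            b[a * k3:(a + 1) * k3] = _contract_vec(
                Wg[..., a] * Wr, *Bc
            ) + lam * (R @ coeffs[a].ravel())
            H[a * k3:(a + 1) * k3, a * k3:(a + 1) * k3] += lam * R

        accepted = False
        hdiag = np.diag(H).copy() + 1e-9
        for _ in range(8):
            try:
                fac = cho_factor(H + np.diag(mu * hdiag), check_finite=False)
                delta = cho_solve(fac, b, check_finite=False)
            except np.linalg.LinAlgError:
                mu = max(mu * 10, 1e-6)
                continue
            trial = coeffs - delta.reshape(3, K, K, K)
            q_t, r_t, cost_t = evaluate(trial)
            if cost_t < cost:
                coeffs, q, r = trial, q_t, r_t
                prev, cost = cost, cost_t
                costs.append(cost)
                mu = mu / 3 if mu > 1e-8 else 0.0
                accepted = True
                break
            mu = max(mu * 10, 1e-6)
        if not accepted:
            break
        if prev > 0 and (prev - cost) / prev < tol:
            break

    deform = DCTDeformation(coeffs=coeffs, shape=tuple(shape), lam=lam, costs=costs)
    return deform, deform.to_field()


# ---------------------------------------------------------------------------
# applying, composing with the affine, and inverting fields


def apply_deformation(volume: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Resample ``volume`` at ``x + d(x)`` (trilinear; out of bounds -> 0)."""
    volume = np.asarray(volume)
    disp = np.asarray(disp)
    if disp.shape != volume.shape + (3,):
        raise ValueError(
            f"field grid {disp.shape} does not match volume {volume.shape}"
        )
    if not np.isfinite(disp).all():
        raise ValueError("displacement field contains non-finite values")
    pts = _grid_points(volume.shape) + disp
    return _sample(volume, pts.reshape(-1, 3)).reshape(volume.shape)


def apply_affine(volume: np.ndarray, affine: AffineTransform) -> np.ndarray:
    """Resample ``volume`` at affine-mapped coordinates."""
    pts = affine.map_points(_grid_points(volume.shape).reshape(-1, 3))
    return _sample(np.asarray(volume, dtype=np.float64), pts).reshape(volume.shape)


def warp_scan(
    moving: np.ndarray, affine: AffineTransform, disp: np.ndarray
) -> np.ndarray:
    """Resample ``moving`` at ``affine(x + d(x))`` in a single interpolation."""
    grid = _grid_points(disp.shape[:3])
    pts = affine.map_points((grid + disp).reshape(-1, 3))
    return _sample(np.asarray(moving, dtype=np.float64), pts).reshape(disp.shape[:3])


def invert_deformation(
    disp: np.ndarray, max_iter: int = 30, tol: float = 0.01
) -> np.ndarray:
    """Numerically invert a displacement field by fixed-point iteration.

    Solves ``d_inv(x) = -d(x + d_inv(x))`` so that composing the field with
    its inverse is (numerically) the identity.  Fields must be small relative
    to the grid (max |d| < grid/4).  Raises on non-convergence, reporting the
    final composition residual.
    """
    disp = np.asarray(disp, dtype=np.float64)
    shape = disp.shape[:3]
    limit = min(shape) / 4
    maxd = float(np.abs(disp).max())
    if maxd >= limit:
        raise RegistrationError(
            f"field too large to invert reliably (max |d| = {maxd:.2f} voxels)"
        )
    grid = _grid_points(shape)
    inv = -disp.copy()
    step = np.inf
    for _ in range(max_iter):
        pts = (grid + inv).reshape(-1, 3)
        d_at = np.stack(
            [_sample(disp[..., a], pts, mode="nearest") for a in range(3)], axis=-1
        ).reshape(disp.shape)
        new = -d_at
        step = float(np.abs(new - inv).max())
        inv = new
        if step < tol:
            break
    # composition residual ||d_inv(x) + d(x + d_inv(x))||_inf
    pts = (grid + inv).reshape(-1, 3)
    d_at = np.stack(
        [_sample(disp[..., a], pts, mode="nearest") for a in range(3)], axis=-1
    ).reshape(disp.shape)
    resid = float(np.abs(inv + d_at).max())
    if step >= tol:
        raise RegistrationError(
            f"deformation inversion did not converge (residual {resid:.4f} voxels)"
        )
    return inv


# ---------------------------------------------------------------------------
# persistence


def save_field(disp: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Persist a displacement field as a 4D NIfTI (last axis = component)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(disp, dtype=np.float32), affine), path)
    return path


def load_field(path: str | Path) -> np.ndarray:
    img = nib.load(path)
    if img.ndim != 4 or img.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 4D displacement field with 3 components")
    return np.asarray(img.dataobj, dtype=np.float64)
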