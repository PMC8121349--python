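"""SPDE mesh, finite-element matrices and Matérn/AR1 GMRF precisions.

A Matérn Gaussian field (smoothness nu = 1) is approximated by a Gaussian
Markov random field on a triangulation: piecewise-linear basis functions at
the mesh nodes ("knots") give sparse mass (C, lumped) and stiffness (G)
matrices, and the alpha = 2 SPDE precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)

whose solution field has Matérn covariance with range parameter kappa.
``range_km`` is parameterised as the distance at which correlation drops to
about 0.13 (kappa = sqrt(8 nu)/range), and ``sigma`` as the marginal SD
(tau = 1/(2 sqrt(pi) kappa sigma) for nu = 1 in two dimensions).  Monthly
fields are linked by a stationary AR1 process via a Kronecker-product
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from sklearn.cluster import KMeans


@dataclass
class FieldParams:
    """Matérn range (0.13-correlation distance, km), marginal SD, AR1 rho."""

    range_km: float
    sigma: float
    rho: float = 0.0

    def __post_init__(self):
        if self.range_km <= 0 or self.sigma <= 0:
            raise ValueError("range_km and sigma must be positive")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def kappa(self) -> float:
        return np.sqrt(8.0) / self.range_km  # nu = 1

    @property
    def tau(self) -> float:
        # marginal variance of the alpha=2, d=2 SPDE field: 1/(4 pi kappa^2 tau^2)
        return 1.0 / (2.0 * np.sqrt(np.pi) * self.kappa * self.sigma)


@dataclass
class SpdeMesh:
    nodes: np.ndarray          # (n_k, 2) km coordinates
    triangles: np.ndarray      # (n_t, 3) vertex indices
    C: sp.spmatrix = field(repr=False, default=None)  # lumped mass (diagonal)
    G: sp.spmatrix = field(repr=False, default=None)  # stiffness
    _tri: Delaunay = field(repr=False, default=None, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def point_locator(self) -> Delaunay:
        if self._tri is None:
            self._tri = Delaunay(self.nodes)
        return self._tri

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"nodes": self.nodes.tolist(), "triangles": self.triangles.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SpdeMesh":
        with open(path) as fh:
            d = json.load(fh)
        mesh = cls(np.asarray(d["nodes"], float), np.asarray(d["triangles"], int))
        mesh.C, mesh.G = fem_matrices(mesh)
        return mesh


def _thin_by_cutoff(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy thinning: keep a point only if >= cutoff from all kept ones."""
    kept: list[np.ndarray] = []
    for pt in points:
        if all(np.hypot(*(pt - q)) >= cutoff for q in kept):
            kept.append(pt)
    return np.asarray(kept)


def build_mesh(
    locations: np.ndarray,
    n_knots: int = 200,
    cutoff_km: float = 10.0,
    buffer_km: float | None = None,
    seed: int = 0,
) -> SpdeMesh:
    """Triangulation with interior knots from seeded k-means on data locations.

    Knots are k-means centres thinned to a minimum spacing of ``cutoff_km``;
    a ring of boundary nodes offset ``buffer_km`` outwards from the data
    bounding box avoids boundary inflation of the field variance.
    Deterministic given ``seed``.
    """
    locations = np.asarray(locations, float)
    if locations.ndim != 2 or locations.shape[1] != 2:
        raise ValueError("locations must be (n, 2)")
    uniq = np.unique(locations, axis=0)
    if uniq.shape[0] < 3:
        raise ValueError("need at least 3 distinct locations")
    span = uniq.max(axis=0) - uniq.min(axis=0)
    if np.any(span <= 0) or _collinear(uniq):
        raise ValueError("degenerate collinear input locations: no 2-D mesh exists")

    if buffer_km is None:
        buffer_km = 0.15 * float(np.hypot(*span))

    n_fit = min(n_knots, uniq.shape[0])
    km = KMeans(n_clusters=n_fit, n_init=3, random_state=seed)
    km.fit(uniq)
    centers = km.cluster_centers_[np.lexsort(km.cluster_centers_.T)]
    knots = _thin_by_cutoff(centers, cutoff_km)

    lo = uniq.min(axis=0) - buffer_km
    hi = uniq.max(axis=0) + buffer_km
    spacing = max(2.0 * cutoff_km, float(np.hypot(*(hi - lo))) / 40.0)
    ring = _boundary_ring(lo, hi, spacing)

    nodes = np.vstack([knots, ring])
    try:
        tri = Delaunay(nodes)
    except QhullError as e:  # pragma: no cover - guarded above
        raise ValueError(f"triangulation failed (degenerate geometry): {e}") from e
    mesh = SpdeMesh(nodes=tri.points, triangles=tri.simplices.copy(), _tri=tri)
    mesh.C, mesh.G = fem_matrices(mesh)
    return mesh


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    p0 = points[0]
    d = points[1:] - p0
    cross = d[:, 0, None] * d[None, :, 1] - d[:, 1, None] * d[None, :, 0]
    scale = max(np.abs(d).max(), 1.0)
    return bool(np.all(np.abs(cross) < tol * scale**2))


def _boundary_ring(lo, hi, spacing):
    xs = np.linspace(lo[0], hi[0], max(int(np.ceil((hi[0] - lo[0]) / spacing)), 2) + 1)
    ys = np.linspace(lo[1], hi[1], max(int(np.ceil((hi[1] - lo[1]) / spacing)), 2) + 1)
    pts = (
        [(x, lo[1]) for x in xs]
        + [(x, hi[1]) for x in xs]
        + [(lo[0], y) for y in ys[1:-1]]
        + [(hi[0], y) for y in ys[1:-1]]
    )
    return np.asarray(pts)


def fem_matrices(mesh: SpdeMesh) -> tuple[sp.spmatrix, sp.spmatrix]:
    """Linear-basis FEM mass (lumped, diagonal) and stiffness matrices.

    For each triangle with vertices v0,v1,v2 and area T, the element
    stiffness entries are ``T * grad_i . grad_j`` with the constant
    barycentric gradients; the lumped mass assigns T/3 to each vertex.
    """
    n = mesh.n_nodes
    c = np.zeros(n)
    rows, cols, vals = [], [], []
    for t in mesh.triangles:
        xy = mesh.nodes[t]
        e1 = xy[1] - xy[0]
        e2 = xy[2] - xy[0]
        det = e1[0] * e2[1] - e1[1] * e2[0]
        area = 0.5 * abs(det)
        if area <= 0 or not np.isfinite(area):
            raise ValueError(f"zero-area triangle {t.tolist()}")
        # gradients of barycentric coordinates
        g = np.array(
            [
                [xy[1, 1] - xy[2, 1], xy[2, 0] - xy[1, 0]],
                [xy[2, 1] - xy[0, 1], xy[0, 0] - xy[2, 0]],
                [xy[0, 1] - xy[1, 1], xy[1, 0] - xy[0, 0]],
            ]
        ) / det
        ke = area * (g @ g.T)
        for a in range(3):
            c[t[a]] += area / 3.0
            for b in range(3):
                rows.append(t[a])
                cols.append(t[b])
                vals.append(ke[a, b])
    C = sp.diags(c).tocsc()
    G = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    G.sum_duplicates()
    return C, G


def matern_precision(mesh: SpdeMesh, kappa: float, tau: float) -> sp.spmatrix:
    """alpha = 2 SPDE precision Q = tau^2 (k^4 C + 2 k^2 G + G C^-1 G)."""
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be positive")
    C, G = mesh.C, mesh.G
    cinv = sp.diags(1.0 / C.diagonal())
    Q = tau**2 * (kappa**4 * C + 2.0 * kappa**2 * G + G @ cinv @ G)
    Q = ((Q + Q.T) * 0.5).tocsc()
    _ = cholesky_dense(Q)  # fail fast with a clear message if not SPD
    return Q


def precision_from_params(mesh: SpdeMesh, params: FieldParams) -> sp.spmatrix:
    return matern_precision(mesh, params.kappa, params.tau)


def projector(mesh: SpdeMesh, locations: np.ndarray) -> sp.spmatrix:
    """Sparse bilinear (barycentric) interpolation matrix, rows sum to 1."""
    locations = np.atleast_2d(np.asarray(locations, float))
    tri = mesh.point_locator()
    simplex = tri.find_simplex(locations)
    if np.any(simplex < 0):
        bad = np.where(simplex < 0)[0]
        raise ValueError(
            f"{bad.size} location(s) outside mesh hull, indices {bad.tolist()[:10]}"
        )
    X = tri.transform[simplex]
    b = np.einsum("nij,nj->ni", X[:, :2, :], locations - X[:, 2, :])
    bary = np.c_[b, 1.0 - b.sum(axis=1)]
    verts = tri.simplices[simplex]
    n = locations.shape[0]
    rows = np.repeat(np.arange(n), 3)
    A = sp.csr_matrix(
        (bary.ravel(), (rows, verts.ravel())), shape=(n, mesh.n_nodes)
    )
    return A


def ar1_precision(rho: float, n_time: int) -> np.ndarray:
    """AR1 precision scaled to unit marginal variance per time slice."""
    if not (-1.0 < rho < 1.0):
        raise ValueError("|rho| must be < 1")
    if n_time < 1:
        raise ValueError("n_time must be >= 1")
    if n_time == 1:
        return np.array([[1.0]])
    Q = np.zeros((n_time, n_time))
    s = 1.0 / (1.0 - rho**2)
    np.fill_diagonal(Q, (1.0 + rho**2) * s)
    Q[0, 0] = Q[-1, -1] = s
    idx = np.arange(n_time - 1)
    Q[idx, idx + 1] = Q[idx + 1, idx] = -rho * s
    return Q


def spacetime_precision(Q_space: sp.spmatrix, rho: float, n_time: int) -> sp.spmatrix:
    """Kronecker AR1 (x) space precision over ``n_time * n_k`` effects.

    Time is the slow index: the field vector stacks the spatial field of
    time slice 0, then slice 1, ...
    """
    Qt = ar1_precision(rho, n_time)
    return sp.kron(sp.csc_matrix(Qt), sp.csc_matrix(Q_space), format="csc")


def cholesky_dense(Q) -> np.ndarray:
    """Lower Cholesky factor of a (sparse or dense) SPD matrix."""
    Qd = Q.toarray() if sp.issparse(Q) else np.asarray(Q, float)
    try:
        return sla.cholesky(Qd, lower=True)
    except sla.LinAlgError as e:
        raise ValueError(
            f"precision matrix not positive definite (n={Qd.shape[0]}): {e}"
        ) from e


def gmrf_logdet(Q) -> float:
    L = cholesky_dense(Q)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def sample_gmrf(Q, seed=None, n_draws: int = 1, rng=None) -> np.ndarray:
    """Draw zero-mean GMRF realisations x ~ N(0, Q^-1) via L^T x = z.

    Returns shape (n,) for a single draw, (n_draws, n) otherwise.
    Deterministic given ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = cholesky_dense(Q)
    n = L.shape[0]
    z = rng.standard_normal((n, n_draws))
    x = sla.solve_triangular(L.T, z, lower=False)
    return x[:, 0] if n_draws == 1 else x.T
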