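"""Thin-plate spline deformation grids and wireframe plotting (2D).

The TPS interpolant with kernel U(r) = r^2 log r is the classic deformation
visualization for landmark data: it is the unique minimum-bending-energy
interpolating map, and warping a regular grid by it renders a shape change as
a deformation of the reference form.  Grids here are strictly 2D — 3D shapes
are first orthogonally projected onto a viewing plane, matching how published
figures render 3D landmark data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TPSModel",
    "project_to_plane",
    "tps_fit",
    "tps_apply",
    "deformation_grid",
    "plot_deformation_grid",
    "plot_wireframe",
    "read_wireframe_edges",
]


@dataclass
class TPSModel:
    """Fitted 2D thin-plate spline ``source -> target``."""

    source: np.ndarray          # (m, 2) control points
    affine: np.ndarray          # (3, 2): [constant; x; y] rows per output dim
    weights: np.ndarray         # (m, 2) kernel coefficients
    bending_energy: float


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, evaluated from squared radii with U(0) = 0."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])  # r^2 log r = (r^2 log r^2)/2
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return _tps_kernel((diff**2).sum(axis=2))


def project_to_plane(shape: np.ndarray, plane="xy") -> np.ndarray:
    """Orthogonal projection of a (k, 3) shape onto a 2D viewing plane.

    ``plane`` is one of the axis pairs 'xy', 'xz', 'yz', or a 3-vector normal;
    for a normal, an orthonormal in-plane basis is built deterministically
    from the coordinate axis least aligned with it.
    2D input is returned unchanged (idempotent).
    """
    shape = np.asarray(shape, dtype=float)
    if shape.ndim != 2:
        raise ValueError(f"expected (k, d) shape, got {shape.shape}")
    if shape.shape[1] == 2:
        return shape.copy()
    if isinstance(plane, str):
        try:
            cols = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
        except KeyError:
            raise ValueError(f"plane must be 'xy', 'xz' or 'yz', got {plane!r}") from None
        return shape[:, cols]
    normal = np.asarray(plane, dtype=float).ravel()
    if normal.shape != (3,):
        raise ValueError("plane normal must be a 3-vector")
    nn = np.linalg.norm(normal)
    if nn == 0.0:
        raise ValueError("zero plane normal")
    nhat = normal / nn
    e = np.zeros(3)
    e[int(np.argmin(np.abs(nhat)))] = 1.0
    u = e - (e @ nhat) * nhat
    u /= np.linalg.norm(u)
    v = np.cross(nhat, u)
    return np.column_stack([shape @ u, shape @ v])


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSModel:
    """Fit the exact TPS interpolant from source to target control points.

    Solves the standard bordered system [[K, P], [P', 0]] for the kernel
    weights and affine part per output dimension; the side conditions
    (weights orthogonal to constants and coordinates) are implied by the
    border.  Bending energy is the quadratic form w' K w summed over output
    dimensions.
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2 or S.shape != T.shape:
        raise ValueError("source and target must be matching (m, 2) arrays")
    m = S.shape[0]
    if m < 3:
        raise ValueError("TPS needs at least 3 control points")
    if len(np.unique(S, axis=0)) != m:
        raise ValueError("singular TPS system: duplicate source points")
    K = _kernel_matrix(S, S)
    P = np.column_stack([np.ones(m), S])
    if np.linalg.matrix_rank(P) < 3:
        raise ValueError("singular TPS system: collinear source points")
    L = np.zeros((m + 3, m + 3))
    L[:m, :m] = K
    L[:m, m:] = P
    L[m:, :m] = P.T
    rhs = np.zeros((m + 3, 2))
    rhs[:m] = T
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: collinear or duplicate source points"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular TPS system: collinear or duplicate source points")
    w = sol[:m]
    a = sol[m:]
    # bending energy; clamp the tiny negative round-off the quadratic form can produce
    be = float(max(0.0, np.einsum("id,ij,jd->", w, K, w)))
    return TPSModel(source=S.copy(), affine=a, weights=w, bending_energy=be)


def tps_apply(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Map points through a fitted TPS: affine part + kernel expansion."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (p, 2)")
    Pm = np.column_stack([np.ones(len(pts)), pts])
    K = _kernel_matrix(pts, model.source)
    return Pm @ model.affine + K @ model.weights


def deformation_grid(
    reference: np.ndarray,
    deformed: np.ndarray,
    grid_n: int = 20,
    magnify: float = 1.0,
) -> dict:
    """Warp a regular lattice by the TPS from reference to (magnified) deformed.

    The target is ``reference + magnify * (deformed - reference)`` — shape
    changes in real data are small, so published grids exaggerate them; the
    factor is explicit and recorded in the output.  The lattice is
    ``grid_n x grid_n`` over the reference bounding box padded by 10%.

    Returns a dict with ``rows`` and ``cols`` (lists of (grid_n, 2) polylines),
    ``landmarks`` (warped landmark positions), ``reference_landmarks`` and
    ``magnify``.
    """
    ref = np.asarray(reference, dtype=float)
    def_ = np.asarray(deformed, dtype=float)
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if magnify <= 0:
        raise ValueError("magnify must be > 0")
    target = ref + magnify * (def_ - ref)
    model = tps_fit(ref, target)
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    pad = 0.10 * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_n)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_n)
    rows = []
    for y in ys:
        line = np.column_stack([xs, np.full(grid_n, y)])
        rows.append(tps_apply(model, line))
    cols = []
    for x in xs:
        line = np.column_stack([np.full(grid_n, x), ys])
        cols.append(tps_apply(model, line))
    return {
        "rows": rows,
        "cols": cols,
        "landmarks": tps_apply(model, ref),
        "reference_landmarks": ref,
        "magnify": float(magnify),
        "bending_energy": model.bending_energy,
    }


def read_wireframe_edges(path, landmark_names) -> list[tuple[int, int]]:
    """Read a two-column edge file of landmark-name pairs into index pairs."""
    names = list(landmark_names)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two landmark names")
            for p in parts:
                if p not in names:
                    raise KeyError(
                        f"{path}:{lineno}: unknown landmark {p!r}; "
                        f"available: {names}"
                    )
            edges.append((names.index(parts[0]), names.index(parts[1])))
    return edges


def plot_deformation_grid(grid: dict, ax=None, landmark_color="tab:red"):
    """Draw a warped deformation grid onto a matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for line in grid["rows"]:
        ax.plot(line[:, 0], line[:, 1], color="0.6", lw=0.7)
    for line in grid["cols"]:
        ax.plot(line[:, 0], line[:, 1], color="0.6", lw=0.7)
    lm = grid["landmarks"]
    ax.scatter(lm[:, 0], lm[:, 1], s=18, color=landmark_color, zorder=3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax


def plot_wireframe(shape2d, edges, ax=None, **line_kw):
    """Draw landmarks and wireframe edges for a 2D shape."""
    import matplotlib.pyplot as plt

    shape2d = np.asarray(shape2d, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    kw = {"color": "tab:blue", "lw": 1.5} | line_kw
    for i, j in edges:
        ax.plot(
            [shape2d[i, 0], shape2d[j, 0]],
            [shape2d[i, 1], shape2d[j, 1]],
            **kw,
        )
    ax.scatter(shape2d[:, 0], shape2d[:, 1], s=18, color="k", zorder=3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax
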