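"""Independent brute-force oracles used by the unit and acceptance tests."""

import numpy as np


def theta_grid_plane(axis_point, axis_dir, targets, n_theta=10_000):
    """Brute-force axis-plane fit: scan plane angle theta on a grid.

    Planes containing the axis are parameterized by the angle of their
    normal within the axis-orthogonal 2D subspace.  Returns (best_normal,
    best_objective, objectives) where objective is the sum of squared
    point-plane distances over targets.
    """
    axis_point = np.asarray(axis_point, float)
    d = np.asarray(axis_dir, float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    offsets = np.asarray(targets, float) - axis_point
    u = offsets @ np.column_stack([e1, e2])  # (m, 2)
    thetas = np.linspace(0.0, np.pi, n_theta, endpoint=False)
    normals2d = np.column_stack([np.cos(thetas), np.sin(thetas)])  # (T, 2)
    obj = ((u @ normals2d.T) ** 2).sum(axis=0)  # (T,)
    best = int(np.argmin(obj))
    n3d = normals2d[best, 0] * e1 + normals2d[best, 1] * e2
    return n3d, float(obj[best]), obj


def plane_objective(plane, targets):
    """Sum of squared point-plane distances for an OrientedPlane."""
    t = np.asarray(targets, float)
    return float((((t - plane.point) @ plane.normal) ** 2).sum())


def random_rigid(rng):
    """A uniformly random rotation matrix and a random translation."""
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-100.0, 100.0, size=3)
    return q, t
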