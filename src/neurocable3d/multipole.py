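"""Spherical-harmonics multipole expansion of the extracellular potential.

For a spherical cell of radius R the exterior potential is a generalized
Fourier series

    Phi_out(r, theta, phi) = sum_{l,m} b_lm r^{-(l+1)} Y_lm(theta, phi),

whose coefficients are fixed by matching the radial derivative at r = R to
the transmembrane flux boundary condition
``-sigma_out dPhi/dr|_R = j_all``:

    b_lm = R^{l+2} / ((l+1) sigma_out) * \\oint j_all Y_lm dOmega.

The l = 0 coefficient is proportional to the total transmembrane current,
which vanishes for every converged simulation state (flux balance), so the
extracellular potential of a cell carries no current monopole and decays at
least as r^{-2}.

Real orthonormal spherical harmonics are used; the quadrature is the
per-triangle barycenter rule, whose vertex weights coincide exactly with
the finite-volume dual areas, so the fitted monopole inherits the solver's
discrete flux-balance identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .units import UA_PER_CM2_TO_NA_PER_UM2, sigma_to_internal

__all__ = [
    "MultipoleExpansion",
    "real_sph_harm",
    "fit_coefficients",
    "fit_coefficients_grid",
    "monopole_coefficient",
    "evaluate_potential",
    "flux_from_expansion",
]


def real_sph_harm(l: int, m: int, theta, phi):
    """Real orthonormal spherical harmonic Y_lm(theta, phi).

    ``theta`` is the polar angle from +z, ``phi`` the azimuth.  For m > 0
    the cosine combination, for m < 0 the sine combination, both carrying
    the sqrt(2) orthonormalization; Condon-Shortley phases cancel.
    """
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


@dataclass
class MultipoleExpansion:
    """Exterior expansion coefficients of the extracellular potential.

    ``coefficients[l][l + m]`` is b_lm in mV * um^(l+1) for 0 <= l <= l_max,
    -l <= m <= l.
    """

    radius: float  #: um
    l_max: int
    coefficients: list  #: list of (2l+1,) arrays

    def __post_init__(self):
        if len(self.coefficients) != self.l_max + 1:
            raise ValueError("coefficient list does not match l_max")
        for l, c in enumerate(self.coefficients):
            if len(c) != 2 * l + 1:
                raise ValueError(f"degree {l} must have {2 * l + 1} orders")
            if not np.all(np.isfinite(c)):
                raise ValueError("non-finite multipole coefficient")

    def coefficient(self, l: int, m: int) -> float:
        return float(self.coefficients[l][l + m])

    def max_abs(self, l_min: int = 0) -> float:
        vals = [np.abs(c).max() / self.radius ** (l + 1)
                for l, c in enumerate(self.coefficients) if l >= l_min]
        return float(max(vals)) if vals else 0.0

    def table(self):
        """(l, m, b_lm) rows for CSV export."""
        rows = []
        for l, c in enumerate(self.coefficients):
            for m in range(-l, l + 1):
                rows.append((l, m, float(c[l + m])))
        return rows


def _sphere_angles(points: np.ndarray):
    r = np.linalg.norm(points, axis=-1)
    theta = np.arccos(np.clip(points[..., 2] / r, -1.0, 1.0))
    phi = np.arctan2(points[..., 1], points[..., 0])
    return r, theta, phi


def _surface_quadrature(mesh, center):
    """Per-triangle barycenter quadrature on a closed triangulated sphere:
    returns (unit directions, solid-angle weights, vertex-average operator)."""
    from .mesh.core import triangle_area_vectors

    tris = mesh.mem_tris
    if len(tris) == 0:
        raise ValueError("mesh has no membrane surface")
    verts = mesh.vertices - np.asarray(center, float)
    areas = np.linalg.norm(triangle_area_vectors(mesh.vertices, tris), axis=1)
    centers = verts[tris].mean(axis=1)
    r = np.linalg.norm(centers, axis=1)
    return centers, areas, r


def fit_coefficients(
    flux_on_sphere: np.ndarray,
    mesh,
    *,
    radius: float | None = None,
    sigma_out: float = 20.0,
    l_max: int = 8,
    center=(0.0, 0.0, 0.0),
) -> MultipoleExpansion:
    """Fit b_lm from a per-vertex transmembrane current density field.

    ``flux_on_sphere`` gives j_all in uA/cm^2 on the mesh's membrane
    vertices (ordered as ``mesh.membrane_vertices()``); ``sigma_out`` in
    mS/cm.  The surface integral uses the triangle-barycenter rule with the
    vertex-mean flux per triangle.  Raises on a non-closed surface (the
    integrated surface normal must vanish).
    """
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    from .mesh.core import triangle_area_vectors

    mem_verts = mesh.membrane_vertices()
    flux = np.asarray(flux_on_sphere, float)
    if flux.shape != mem_verts.shape:
        raise ValueError("flux array must match the membrane vertex set")
    g2m = np.full(mesh.n_vertices, -1, dtype=np.int64)
    g2m[mem_verts] = np.arange(len(mem_verts))

    area_vecs = triangle_area_vectors(mesh.vertices, mesh.mem_tris)
    areas = np.linalg.norm(area_vecs, axis=1)
    if np.linalg.norm(area_vecs.sum(axis=0)) > 1e-6 * areas.sum():
        raise ValueError("membrane surface is not closed")

    centers = mesh.vertices[mesh.mem_tris].mean(axis=1) - np.asarray(center, float)
    r_tri, theta, phi = _sphere_angles(centers)
    if radius is None:
        radius = float(
            np.linalg.norm(
                mesh.vertices[mem_verts] - np.asarray(center, float), axis=1
            ).mean()
        )
    j_tri = flux[g2m[mesh.mem_tris]].mean(axis=1)  # vertex-mean per triangle

    # surface integral on the unit sphere: dOmega = dS / R^2
    j_na = j_tri * UA_PER_CM2_TO_NA_PER_UM2  # nA/um^2
    w = areas / radius**2
    sig = sigma_to_internal(sigma_out)
    coefficients = []
    for l in range(l_max + 1):
        c = np.empty(2 * l + 1)
        for m in range(-l, l + 1):
            y = real_sph_harm(l, m, theta, phi)
            integral = float((j_na * y * w).sum())
            c[l + m] = radius ** (l + 2) / ((l + 1) * sig) * integral
        coefficients.append(c)
    return MultipoleExpansion(radius=float(radius), l_max=l_max, coefficients=coefficients)


def fit_coefficients_grid(
    flux_fn,
    radius: float,
    *,
    sigma_out: float = 20.0,
    l_max: int = 8,
    n_theta: int | None = None,
) -> MultipoleExpansion:
    """Fit b_lm for an arbitrary flux *field* ``flux_fn(theta, phi)``
    (uA/cm^2) on a Gauss-Legendre x uniform-azimuth product grid.

    The grid integrates products of spherical harmonics up to degree
    ``2 l_max`` exactly, so the discrete basis is orthonormal to machine
    precision and fit -> reconstruct -> fit is the identity (the high-order
    alternative to the per-triangle barycenter rule).
    """
    from scipy.special import roots_legendre

    if n_theta is None:
        n_theta = l_max + 2
    nodes, weights = roots_legendre(n_theta)
    theta = np.arccos(nodes)
    n_phi = 2 * l_max + 2
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    W = np.repeat(weights[:, None], n_phi, axis=1) * (2.0 * np.pi / n_phi)

    j = np.asarray(flux_fn(TH, PH), float) * UA_PER_CM2_TO_NA_PER_UM2
    sig = sigma_to_internal(sigma_out)
    coefficients = []
    for l in range(l_max + 1):
        c = np.empty(2 * l + 1)
        for m in range(-l, l + 1):
            y = real_sph_harm(l, m, TH, PH)
            c[l + m] = radius ** (l + 2) / ((l + 1) * sig) * float((j * y * W).sum())
        coefficients.append(c)
    return MultipoleExpansion(radius=float(radius), l_max=l_max, coefficients=coefficients)


def monopole_coefficient(
    flux_on_sphere: np.ndarray,
    mesh,
    *,
    radius: float | None = None,
    sigma_out: float = 20.0,
    center=(0.0, 0.0, 0.0),
) -> float:
    """b_00 alone (mV * um): proportional to the total transmembrane
    current, hence ~0 for any converged simulation state."""
    exp = fit_coefficients(
        flux_on_sphere, mesh, radius=radius, sigma_out=sigma_out, l_max=0, center=center
    )
    return exp.coefficient(0, 0)


def evaluate_potential(exp: MultipoleExpansion, r, theta, phi):
    """Truncated exterior series at (r, theta, phi); requires r > R.

    With b_00 = 0 the magnitude decays at least as r^-2.
    """
    r = np.asarray(r, float)
    if np.any(r <= exp.radius):
        raise ValueError("exterior expansion only valid for r > R")
    out = np.zeros(np.broadcast(r, theta, phi).shape)
    for l, c in enumerate(exp.coefficients):
        radial = r ** (-(l + 1))
        for m in range(-l, l + 1):
            if c[l + m] != 0.0:
                out = out + c[l + m] * radial * real_sph_harm(l, m, theta, phi)
    return out


def flux_from_expansion(exp: MultipoleExpansion, theta, phi, sigma_out: float = 20.0):
    """Reconstruct j_all (uA/cm^2) on the sphere from the coefficients via
    the radial-derivative matching (the inverse of :func:`fit_coefficients`;
    used by the re-fit consistency check)."""
    sig = sigma_to_internal(sigma_out)
    out = np.zeros(np.broadcast(theta, phi).shape)
    for l, c in enumerate(exp.coefficients):
        fac = (l + 1) * sig / exp.radius ** (l + 2)
        for m in range(-l, l + 1):
            if c[l + m] != 0.0:
                out = out + c[l + m] * fac * real_sph_harm(l, m, theta, phi)
    return out / UA_PER_CM2_TO_NA_PER_UM2
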