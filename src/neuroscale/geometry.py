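"""Synthetic head geometry: folded quasi-spherical cortex and conductor shells.

The cortical surface stands in for a FreeSurfer-style reconstruction: each
hemisphere is a closed icosphere mesh (so ico6 gives the canonical 40962
nodes per hemisphere) deformed by a band-limited spherical-harmonic random
radial field, ``r(u) = R0 + A * f(u)``.  The undeformed unit vertex of every
node is kept as its spherical mapping, exactly as FreeSurfer keeps a
``?h.sphere`` coordinate for every ``?h.pial`` vertex.  A polar cap on the
medial side of each hemisphere is flagged non-cortical (the medial wall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import sph_harm_y

__all__ = [
    "HeadModel",
    "CorticalSurface",
    "icosphere",
    "icosphere_vertex_count",
    "build_cortical_surface",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def icosphere_vertex_count(level: int) -> int:
    """Vertices of a subdivided icosahedron: 12, 42, 162, ..., 10*4**L + 2."""
    return 10 * 4**level + 2


def icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere with *nested* vertex ordering.

    Vertices of subdivision ``k`` are the first ``icosphere_vertex_count(k)``
    vertices of every deeper subdivision, which lets coarse icosahedral
    lattices be read off as index prefixes of a fine mesh.

    Returns
    -------
    vertices : (V, 3) float array of unit vectors
    faces : (F, 3) int array, counter-clockwise seen from outside
    """
    phi = _GOLDEN
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    vlist = [v for v in verts]
    for _ in range(level):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = cache.get(key)
            if idx is None:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                idx = len(vlist)
                vlist.append(m)
                cache[key] = idx
            return idx

        new_faces = np.empty((len(faces) * 4, 3), dtype=np.int64)
        for k, (a, b, c) in enumerate(faces):
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces[4 * k + 0] = (a, ab, ca)
            new_faces[4 * k + 1] = (b, bc, ab)
            new_faces[4 * k + 2] = (c, ca, bc)
            new_faces[4 * k + 3] = (ab, bc, ca)
        faces = new_faces
    return np.array(vlist), faces


@dataclass
class HeadModel:
    """Concentric-shell conductor and optical bulk properties.

    Radii in cm, conductivities in S/m, optical coefficients in 1/cm.
    ``shell_radii`` are (inner skull, outer skull, scalp).
    """

    shell_radii: tuple[float, float, float] = (8.2, 8.7, 9.2)
    conductivities: tuple[float, float, float] = (0.3, 0.006, 0.3)  # brain, skull, scalp
    optical_mu_a: float = 0.1
    optical_mu_s_prime: float = 10.0
    cortex_mean_radius: float = 6.2
    fold_amplitude: float = 1.4
    fold_band: tuple[int, int] = (12, 24)

    def validate(self) -> None:
        r = (self.cortex_mean_radius + self.fold_amplitude,) + tuple(self.shell_radii)
        if not all(a < b for a, b in zip(r, r[1:])):
            raise ValueError(
                f"radii must increase from cortex+fold {r[0]:.2f} through shells {self.shell_radii}"
            )
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.optical_mu_a <= 0 or self.optical_mu_s_prime <= 0:
            raise ValueError("optical coefficients must be positive")

    @property
    def scalp_radius(self) -> float:
        return self.shell_radii[2]


@dataclass
class CorticalSurface:
    """Two-hemisphere folded source mesh with spherical mapping.

    Nodes of both hemispheres are concatenated (left first).  ``faces``
    index into the concatenated node array.  Coordinates are cm, origin at
    the conductor centre, +z through the vertex.
    """

    node_positions: np.ndarray  # (M, 3) cm
    node_normals: np.ndarray  # (M, 3) unit
    node_areas: np.ndarray  # (M,) cm^2
    sphere_map: np.ndarray  # (M, 3) unit sphere coordinate
    hemisphere_label: np.ndarray  # (M,) 0 = left, 1 = right
    cortical_mask: np.ndarray  # (M,) bool
    faces: np.ndarray  # (F, 3)
    mesh_level: int = 0
    mean_radius: float = 7.0
    fold_amplitude: float = 0.0
    fold_band: tuple[int, int] = (12, 24)
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def nodes_per_hemisphere(self) -> int:
        return self.n_nodes // 2

    def hemisphere_indices(self, hemi: int) -> np.ndarray:
        return np.nonzero(self.hemisphere_label == hemi)[0]

    def hemisphere_area(self, hemi: int, cortical_only: bool = False) -> float:
        sel = self.hemisphere_label == hemi
        if cortical_only:
            sel = sel & self.cortical_mask
        return float(self.node_areas[sel].sum())

    @property
    def cortical_area_per_hemisphere(self) -> float:
        """Mean cortical (medial wall excluded) area of the two hemispheres, cm^2."""
        return 0.5 * (self.hemisphere_area(0, True) + self.hemisphere_area(1, True))

    @property
    def max_radius(self) -> float:
        return float(np.linalg.norm(self.node_positions, axis=1).max())

    def triangle_area_total(self, hemi: int | None = None) -> float:
        """Total triangle area (cm^2), directly from the face list."""
        f = self.faces
        if hemi is not None:
            half = self.nodes_per_hemisphere
            f = f[(f[:, 0] < half) if hemi == 0 else (f[:, 0] >= half)]
        p = self.node_positions
        cross = np.cross(p[f[:, 1]] - p[f[:, 0]], p[f[:, 2]] - p[f[:, 0]])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [f"{'lh' if h == 0 else 'rh'}-{i}" for i, h in enumerate(self.hemisphere_label)],
                "x": self.node_positions[:, 0],
                "y": self.node_positions[:, 1],
                "z": self.node_positions[:, 2],
                "nx": self.node_normals[:, 0],
                "ny": self.node_normals[:, 1],
                "nz": self.node_normals[:, 2],
                "area": self.node_areas,
                "sx": self.sphere_map[:, 0],
                "sy": self.sphere_map[:, 1],
                "sz": self.sphere_map[:, 2],
                "hemisphere": self.hemisphere_label,
                "cortical": self.cortical_mask.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorticalSurface":
        """Re-import a node table written by :meth:`to_csv`.

        The face list is not part of the tabular format, so the returned
        surface supports everything except mesh-area recomputation.
        """
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            node_positions=df[["x", "y", "z"]].to_numpy(float),
            node_normals=df[["nx", "ny", "nz"]].to_numpy(float),
            node_areas=df["area"].to_numpy(float),
            sphere_map=df[["sx", "sy", "sz"]].to_numpy(float),
            hemisphere_label=df["hemisphere"].to_numpy(np.int8),
            cortical_mask=df["cortical"].to_numpy(bool),
            faces=np.empty((0, 3), dtype=np.int64),
        )


def _band_limited_field(sphere_pts: np.ndarray, band: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field on the sphere, band-limited to degrees [lo, hi].

    Real spherical-harmonic expansion with i.i.d. standard-normal
    coefficients, normalized to unit empirical standard deviation.
    """
    lo, hi = band
    theta = np.arccos(np.clip(sphere_pts[:, 2], -1.0, 1.0))
    phi = np.arctan2(sphere_pts[:, 1], sphere_pts[:, 0])
    f = np.zeros(len(sphere_pts))
    for l in range(lo, hi + 1):
        coeffs = rng.standard_normal(2 * l + 1)
        y0 = sph_harm_y(l, 0, theta, phi)
        f += coeffs[0] * y0.real
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            f += np.sqrt(2.0) * (coeffs[2 * m - 1] * y.real + coeffs[2 * m] * y.imag)
    sd = f.std()
    if sd > 0:
        f /= sd
    # Bound the profile to |f| < 1 (soft-clipped at ~1.5 sigma) so the fold
    # amplitude is the maximum radial excursion and the folded cortex stays
    # strictly inside the inner-skull shell.
    return np.tanh(f / 1.5)


def _mesh_area(points: np.ndarray, faces: np.ndarray) -> float:
    cross = np.cross(points[faces[:, 1]] - points[faces[:, 0]], points[faces[:, 2]] - points[faces[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def _vertex_normals_areas(points: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted vertex normals and Voronoi-type (1/3 face) vertex areas."""
    e1 = points[faces[:, 1]] - points[faces[:, 0]]
    e2 = points[faces[:, 2]] - points[faces[:, 0]]
    fn = 0.5 * np.cross(e1, e2)  # face normal scaled by area
    fa = np.linalg.norm(fn, axis=1)
    normals = np.zeros_like(points)
    areas = np.zeros(len(points))
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
        np.add.at(areas, faces[:, k], fa / 3.0)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm, areas


def build_cortical_surface(
    mesh_level: int = 5,
    fold_amplitude: float | None = None,
    fold_band: tuple[int, int] = (12, 24),
    target_area: float = 1100.0,
    mean_radius: float = 6.2,
    seed: int = 0,
    symmetric: bool = False,
    medial_cap_deg: float = 15.0,
    center_offset: float = 0.0,
    area_tol: float = 0.01,
) -> CorticalSurface:
    """Build the folded two-hemisphere cortical surface.

    Parameters
    ----------
    mesh_level : icosphere subdivision depth, in [4, 7].
    fold_amplitude : radial fold amplitude A in cm; ``None`` auto-calibrates
        A so each hemisphere's total area hits ``target_area``.
    fold_band : spherical-harmonic degree range of the fold field.
    target_area : target total surface area per hemisphere, cm^2.
    mean_radius : unfolded hemisphere sphere radius R0, cm.
    seed : seeds the two hemisphere fold fields.
    symmetric : mirror the right-hemisphere folds onto the left instead of
        drawing an independent field.
    medial_cap_deg : half-angle of the non-cortical medial-wall cap.
    center_offset : superior (+z) shift of the cortex centre relative to
        the conductor centre, cm.  A positive value mimics the brain
        sitting in the upper cranium, leaving the inferior scalp without
        cortex directly beneath it.
    """
    if not 4 <= mesh_level <= 7:
        raise ValueError("mesh_level must be in [4, 7]")
    if fold_amplitude is not None and fold_amplitude < 0:
        raise ValueError("fold_amplitude must be >= 0")
    if target_area <= 0:
        raise ValueError("target_area must be > 0")

    sphere, faces = icosphere(mesh_level)
    rng = np.random.default_rng(seed)
    field_rh = _band_limited_field(sphere, fold_band, rng)
    if symmetric:
        field_lh = field_rh
    else:
        field_lh = _band_limited_field(sphere, fold_band, rng)

    def fold(points_field: np.ndarray, amp: float) -> np.ndarray:
        r = mean_radius + amp * points_field
        return sphere * r[:, None]

    max_field = float(max(np.abs(field_rh).max(), np.abs(field_lh).max()))
    amp_cap = 0.9 * mean_radius / max_field  # keep radius positive; crude fold-overlap guard

    calibrated = fold_amplitude is None
    if fold_amplitude is None:
        smooth_area = _mesh_area(sphere * mean_radius, faces)

        def area_err(amp: float) -> float:
            a = 0.5 * (_mesh_area(fold(field_rh, amp), faces) + _mesh_area(fold(field_lh, amp), faces))
            return a - target_area

        if target_area < smooth_area:
            raise ValueError(
                f"target_area {target_area} below smooth-sphere area {smooth_area:.1f}; "
                "increase mean_radius or target"
            )
        if area_err(amp_cap) < 0:
            achievable = area_err(amp_cap) + target_area
            raise ValueError(
                f"target_area {target_area} cm^2 unreachable within fold band {fold_band}; "
                f"achievable ~{achievable:.0f} cm^2 at max amplitude {amp_cap:.2f} cm"
            )
        fold_amplitude = float(brentq(area_err, 0.0, amp_cap, xtol=1e-4 * mean_radius))
    elif fold_amplitude > amp_cap:
        raise ValueError(
            f"fold_amplitude {fold_amplitude} self-intersecting; max permissible ~{amp_cap:.2f} cm"
        )

    shift = np.array([0.0, 0.0, center_offset])
    pos_rh = fold(field_rh, fold_amplitude) + shift
    pos_lh = fold(field_lh, fold_amplitude) + shift
    # Left hemisphere mirrored through the midsagittal plane (x -> -x).  The
    # reflection flips triangle orientation, so the left face winding is
    # swapped to keep normals outward.
    mirror = np.array([-1.0, 1.0, 1.0])
    pos_lh = pos_lh * mirror
    sphere_lh = sphere * mirror
    faces_lh = faces[:, [0, 2, 1]]

    n = len(sphere)
    normals_lh, areas_lh = _vertex_normals_areas(pos_lh, faces_lh)
    normals_rh, areas_rh = _vertex_normals_areas(pos_rh, faces)
    if fold_amplitude == 0.0:
        # the smooth-limit normal is analytically radial; bypass the
        # O(h^2) facet bias of the discrete estimator
        normals_lh, normals_rh = sphere_lh.copy(), sphere.copy()

    positions = np.vstack([pos_lh, pos_rh])
    normals = np.vstack([normals_lh, normals_rh])
    areas = np.concatenate([areas_lh, areas_rh])
    smap = np.vstack([sphere_lh, sphere])
    hemi = np.concatenate([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
    all_faces = np.vstack([faces_lh, faces + n])

    # Medial wall: right hemisphere's medial pole faces -x, the mirrored
    # left hemisphere's faces +x; both reduce to sphere_map . (-x) for rh
    # and . (+x) for lh, which after mirroring is the same expression.
    cos_cap = np.cos(np.deg2rad(medial_cap_deg))
    medial_axis = np.where(hemi == 0, 1.0, -1.0)
    cortical = smap[:, 0] * medial_axis < cos_cap

    surf = CorticalSurface(
        node_positions=positions,
        node_normals=normals,
        node_areas=areas,
        sphere_map=smap,
        hemisphere_label=hemi,
        cortical_mask=cortical,
        faces=all_faces,
        mesh_level=mesh_level,
        mean_radius=mean_radius,
        fold_amplitude=float(fold_amplitude),
        fold_band=tuple(fold_band),
        seed=seed,
        metadata={
            "target_area": target_area,
            "medial_cap_deg": medial_cap_deg,
            "symmetric": symmetric,
        },
    )
    if calibrated:
        for h in (0, 1):
            a = surf.hemisphere_area(h)
            if abs(a - target_area) > 0.10 * target_area:
                raise ValueError(
                    f"hemisphere {h} area {a:.0f} cm^2 outside 10% of target {target_area}"
                )
    return surf
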