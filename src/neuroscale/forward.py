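"""Analytic forward models mapping cortical sources to sensors.

EEG: current-dipole potential in three concentric conducting shells
(brain/skull/scalp), evaluated as a Legendre series whose per-degree
radial transfer factors come from a 2x2 layer-matrix solve; average
reference over electrodes.

MEG: magnetic field of a current dipole in a spherically symmetric
conductor (Sarvas' closed form, volume currents included); magnetometers
read the radial component, planar gradiometers the finite difference of
that component across a tangential baseline.

DOT: continuous-wave Rytov sensitivity built from semi-infinite diffusion
Green's functions with an extrapolated boundary, each optode's half-space
set by its scalp tangent plane.

fMRI: uniform averaging of cortical nodes within 3 mm voxels, with
node-count and gray-matter-fraction inclusion filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import CorticalSurface, HeadModel
from .montage import SensorMontage

__all__ = [
    "ForwardModel",
    "eeg_leadfield",
    "meg_leadfield",
    "dot_sensitivity",
    "fmri_voxel_model",
    "normalize_rows",
]

_MU0_4PI = 1e-7  # SI; overall gain scale is irrelevant after row normalization


@dataclass
class ForwardModel:
    """N x M sensor-by-source gain matrix (the A of y = A x)."""

    gains: np.ndarray | sp.spmatrix
    modality: str
    montage: SensorMontage
    surface: CorticalSurface | None = None
    normalized: bool = False
    valid_channel_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.gains.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gains.shape[1]

    def row_norms(self) -> np.ndarray:
        if sp.issparse(self.gains):
            return np.sqrt(np.asarray(self.gains.multiply(self.gains).sum(axis=1)).ravel())
        return np.linalg.norm(self.gains, axis=1)

    def to_mtx(self, path) -> None:
        """Export the gain matrix as MatrixMarket for interoperability."""
        from scipy.io import mmwrite

        g = self.gains if sp.issparse(self.gains) else sp.coo_matrix(self.gains)
        mmwrite(str(path), g)

    def focality(self, threshold: float = 0.5) -> np.ndarray:
        """Per-channel percentage of sources with |gain| >= threshold * row max."""
        if sp.issparse(self.gains):
            g = np.abs(self.gains.toarray())
        else:
            g = np.abs(self.gains)
        mx = g.max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        return 100.0 * (g >= threshold * mx).mean(axis=1)


def _eeg_transfer_factors(head: HeadModel, lmax: int) -> np.ndarray:
    """Per-degree radial transfer factor T_l of the three-shell conductor.

    Solves, for each degree l, the layered-sphere potential
    V_j = A_j t^l + B_j t^-(l+1) (t = r/scalp radius) with continuity of
    potential and radial current at the shell boundaries and zero current
    at the scalp, propagated inward from the scalp by 2x2 layer matrices.
    T_l multiplies the source's infinite-medium coefficient; for equal
    conductivities T_l = (2l+1)/l, the classic bounded homogeneous sphere.
    """
    r1, r2, r3 = head.shell_radii
    s1, s2, s3 = head.conductivities
    ls = np.arange(1, lmax + 1, dtype=float)
    # start at the scalp: zero-current condition gives (A3, B3) ~ (l+1, l)
    A, B = ls + 1.0, ls.copy()

    def across(t, s_out, s_in, A, B):
        # value/flux continuity at radius ratio t, from layer 'out' into 'in'
        tl = t**ls
        tm = t ** -(ls + 1.0)
        V = A * tl + B * tm
        F = s_out * (A * ls * tl / t - B * (ls + 1.0) * tm / t)
        # solve in inner layer: a*tl + b*tm = V ; s_in*(a*l*tl - b*(l+1)*tm)/t = F
        det = -s_in * (2.0 * ls + 1.0) * tl * tm / t
        a = (V * (-s_in * (ls + 1.0) * tm / t) - tm * F) / det
        b = (tl * F - V * s_in * ls * tl / t) / det
        return a, b

    A, B = across(r2 / r3, s3, s2, A, B)
    A, B = across(r1 / r3, s2, s1, A, B)
    return (2.0 * ls + 1.0) / B


def eeg_leadfield(
    surface: CorticalSurface,
    montage: SensorMontage,
    head: HeadModel,
    rel_tol: float = 1e-8,
    chunk: int = 2048,
    average_reference: bool = True,
) -> ForwardModel:
    """Scalp potentials of unit dipoles along the node normals (three-shell sphere).

    The Legendre series is truncated when the largest remaining term falls
    below ``rel_tol`` of the accumulated potential (bounded via the source
    depth ratio).  ``average_reference`` re-references every topography to
    the electrode mean; with it off the potentials are against a reference
    at infinity, which keeps the far-field component every electrode
    shares (the convention of BEM-based forward pipelines that defer
    referencing to the inverse stage).
    """
    if montage.modality != "eeg":
        raise ValueError("montage must be EEG")
    head.validate()
    r1 = head.shell_radii[0]
    r3 = head.scalp_radius
    pos = surface.node_positions
    b = np.linalg.norm(pos, axis=1)
    bad = np.nonzero(b >= r1)[0]
    if bad.size:
        raise ValueError(f"source node {bad[0]} at radius {b[bad[0]]:.2f} cm outside inner skull {r1} cm")

    ratio = float(b.max() / r3)
    lmax = int(np.ceil(np.log(rel_tol) / np.log(ratio))) + 20
    lmax = min(max(lmax, 40), 400)
    T = _eeg_transfer_factors(head, lmax)

    e_units = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    q = surface.node_normals
    M = surface.n_nodes
    E = montage.n_channels
    gains = np.empty((E, M))
    s1 = head.conductivities[0]
    prefactor = 1.0 / (4.0 * np.pi * s1 * r3**2)
    for start in range(0, M, chunk):
        sl = slice(start, min(start + chunk, M))
        r0 = pos[sl]
        bn = b[sl]
        r0u = r0 / np.where(bn > 0, bn, 1.0)[:, None]
        qc = q[sl]
        qr = np.einsum("ij,ij->i", qc, r0u)  # radial moment component
        u = r0u @ e_units.T  # (C, E) cos(angle node-electrode)
        qdotr = qc @ e_units.T
        tang = qdotr - u * qr[:, None]

        V = np.zeros_like(u)
        Pm1 = np.ones_like(u)  # P_0
        P = u.copy()  # P_1
        dPm1 = np.zeros_like(u)  # P_0'
        dP = np.ones_like(u)  # P_1'
        pw = np.ones(u.shape[0])  # (b/r3)^(l-1)
        for l in range(1, lmax + 1):
            if l > 1:
                Pm2, Pm1 = Pm1, P
                P = ((2 * l - 1) * u * Pm1 - (l - 1) * Pm2) / l
                dPm2, dPm1 = dPm1, dP
                dP = dPm2 + (2 * l - 1) * Pm1
                pw = pw * (bn / r3)
            term = (T[l - 1] * pw)[:, None] * (l * qr[:, None] * P + tang * dP)
            V += term
            if l > 10 and np.abs(term).max() < rel_tol * max(np.abs(V).max(), 1e-300):
                break
        V *= prefactor
        if average_reference:
            V -= V.mean(axis=1, keepdims=True)
        gains[:, sl] = V.T
    return ForwardModel(
        gains=gains,
        modality="eeg",
        montage=montage,
        surface=surface,
        metadata={"lmax": lmax, "rel_tol": rel_tol},
    )


def _sarvas_field(r0: np.ndarray, q: np.ndarray, sensor: np.ndarray) -> np.ndarray:
    """Magnetic field at one sensor from dipoles q at r0 (spherical conductor).

    Sarvas (1987) closed form with the conductor centred at the origin;
    radial dipoles are silent.  Returns (C, 3).
    """
    r = sensor[None, :]
    a = r - r0
    an = np.linalg.norm(a, axis=1)
    rn = float(np.linalg.norm(sensor))
    adotr = np.einsum("ij,j->i", a, sensor)
    F = an * (rn * an + rn**2 - np.einsum("ij,j->i", r0, sensor))
    gF_r = an**2 / rn + adotr / an + 2.0 * an + 2.0 * rn
    gF_r0 = an + 2.0 * rn + adotr / an
    gradF = gF_r[:, None] * r - gF_r0[:, None] * r0
    Q = np.cross(q, r0)
    Qdotr = np.einsum("ij,j->i", Q, sensor)
    return _MU0_4PI * (F[:, None] * Q - Qdotr[:, None] * gradF) / (F**2)[:, None]


def meg_leadfield(
    surface: CorticalSurface,
    montage: SensorMontage,
    head: HeadModel,
    kind: str | None = None,
) -> ForwardModel:
    """Magnetometer or planar-gradiometer gains of normal-oriented unit dipoles."""
    kind = kind or ("magnetometer" if montage.modality == "meg_mag" else "gradiometer")
    expected = "meg_mag" if kind == "magnetometer" else "meg_grad"
    if montage.modality != expected:
        raise ValueError(f"montage modality {montage.modality} does not match kind {kind}")
    rad = np.linalg.norm(montage.positions, axis=1)
    inside = rad <= head.scalp_radius
    if inside.any():
        raise ValueError(f"{int(inside.sum())} MEG sensors inside the conductor")
    r0 = surface.node_positions
    q = surface.node_normals
    gains = np.empty((montage.n_channels, surface.n_nodes))
    if kind == "magnetometer":
        for i in range(montage.n_channels):
            Bf = _sarvas_field(r0, q, montage.positions[i])
            gains[i] = Bf @ montage.normals[i]
    else:
        if montage.baseline is None:
            raise ValueError("gradiometer montage needs a baseline")
        h = montage.baseline / 2.0
        for i in range(montage.n_channels):
            e = montage.orientations[i]
            n = montage.normals[i]
            Bp = _sarvas_field(r0, q, montage.positions[i] + h * e)
            Bm = _sarvas_field(r0, q, montage.positions[i] - h * e)
            gains[i] = (Bp @ n - Bm @ n) / montage.baseline
    return ForwardModel(gains=gains, modality=montage.modality, montage=montage, surface=surface)


def _semi_infinite_fluence(
    rho2: np.ndarray, z: np.ndarray, head: HeadModel
) -> np.ndarray:
    """CW fluence in a semi-infinite medium, extrapolated-boundary image source.

    ``rho2`` squared lateral distance and ``z`` depth (cm) of the field
    points; the isotropic source sits one transport mean free path below
    the surface.  Points with z < 0 (outside the medium) get fluence 0.
    """
    mua, musp = head.optical_mu_a, head.optical_mu_s_prime
    D = 1.0 / (3.0 * (mua + musp))
    mu_eff = np.sqrt(mua / D)
    z0 = 1.0 / (mua + musp)
    reff = 0.493  # effective reflection coefficient, tissue-air n ~ 1.4
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    r1 = np.sqrt(rho2 + (z - z0) ** 2)
    r2 = np.sqrt(rho2 + (z + z0 + 2.0 * zb) ** 2)
    r1 = np.maximum(r1, 1e-6)
    r2 = np.maximum(r2, 1e-6)
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * np.pi * D)
    return np.where(z >= 0.0, phi, 0.0)


def dot_sensitivity(
    surface: CorticalSurface, montage: SensorMontage, head: HeadModel
) -> ForwardModel:
    """Rytov sensitivity A(sd, r) = Phi_s(r) Phi_d(r) / Phi(source->detector).

    Each optode defines its own half-space through the scalp tangent plane;
    nodes behind an optode's plane contribute zero for that optode (counted
    in metadata).  The normalizing fluence uses the optode chord distance
    at the surface, which makes every channel exactly reciprocal.
    """
    if montage.modality != "dot" or montage.pairing is None:
        raise ValueError("montage must be DOT with source-detector pairing")
    head.validate()
    opt = montage.optode_positions
    nodes = surface.node_positions
    n_opt = len(opt)
    # per-optode fluence at every node
    phi = np.empty((n_opt, surface.n_nodes))
    outside = 0
    for i in range(n_opt):
        nrm = opt[i] / np.linalg.norm(opt[i])  # outward scalp normal = tangent-plane normal
        rel = opt[i][None, :] - nodes
        z = rel @ nrm  # depth below the tangent plane
        rho2 = np.einsum("ij,ij->i", rel, rel) - z**2
        outside += int((z < 0).sum())
        phi[i] = _semi_infinite_fluence(np.clip(rho2, 0.0, None), z, head)
    gains = np.empty((montage.n_channels, surface.n_nodes))
    for c, (s, d) in enumerate(montage.pairing):
        sep = float(np.linalg.norm(opt[s] - opt[d]))
        phi0 = _semi_infinite_fluence(np.array([sep**2]), np.array([0.0]), head)[0]
        gains[c] = phi[s] * phi[d] / phi0
    return ForwardModel(
        gains=gains,
        modality="dot",
        montage=montage,
        surface=surface,
        metadata={"nodes_outside_tangent_planes": outside},
    )


def fmri_voxel_model(
    surface: CorticalSurface,
    voxel_size: float = 0.3,
    min_nodes: int = 4,
    min_gm_fraction: float = 0.5,
    cortical_thickness: float = 0.3,
    z_range: tuple[float, float] | None = None,
) -> ForwardModel:
    """Voxel-averaging fMRI forward model on an axis-aligned grid.

    Each cortical node is assigned to the ``voxel_size`` (cm) voxel
    containing it.  Kept voxels need >= ``min_nodes`` member nodes and an
    approximate gray-matter fraction >= ``min_gm_fraction``, where the GM
    fraction is (node count x mean member-node area x cortical thickness) /
    voxel volume, capped at 1.  ``z_range`` keeps only voxels whose centers
    fall in the given z window (single-slice analysis mode).  Each kept
    voxel's row averages its member nodes uniformly.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    mask = surface.cortical_mask
    nodes = np.nonzero(mask)[0]
    pos = surface.node_positions[nodes]
    origin = pos.min(axis=0) - 1e-9
    ijk = np.floor((pos - origin) / voxel_size).astype(np.int64)
    keys, inverse, counts = np.unique(ijk, axis=0, return_inverse=True, return_counts=True)
    area_sum = np.bincount(inverse, weights=surface.node_areas[nodes], minlength=len(keys))
    mean_area = area_sum / counts
    gm = np.minimum(1.0, counts * mean_area * cortical_thickness / voxel_size**3)
    keep = (counts >= min_nodes) & (gm >= min_gm_fraction)
    centers = origin + (keys + 0.5) * voxel_size
    if z_range is not None:
        keep &= (centers[:, 2] >= z_range[0]) & (centers[:, 2] <= z_range[1])
    if not keep.any():
        raise ValueError(
            f"no voxels survive: {len(keys)} candidate voxels, "
            f"{int((counts >= min_nodes).sum())} pass min_nodes={min_nodes}, "
            f"{int((gm >= min_gm_fraction).sum())} pass min_gm_fraction={min_gm_fraction}"
            + ("" if z_range is None else f", z_range={z_range}")
        )
    kept_ids = np.nonzero(keep)[0]
    remap = -np.ones(len(keys), dtype=np.int64)
    remap[kept_ids] = np.arange(len(kept_ids))
    rows_all = remap[inverse]
    sel = rows_all >= 0
    data = 1.0 / counts[kept_ids][rows_all[sel]]
    gains = sp.csr_matrix(
        (data, (rows_all[sel], nodes[sel])),
        shape=(len(kept_ids), surface.n_nodes),
    )
    mont = SensorMontage(
        modality="fmri",
        positions=centers[kept_ids],
        channel_ids=[f"VOX{i:06d}" for i in range(len(kept_ids))],
        metadata={
            "voxel_size": voxel_size,
            "min_nodes": min_nodes,
            "min_gm_fraction": min_gm_fraction,
            "cortical_thickness": cortical_thickness,
            "z_range": z_range,
            "n_candidate_voxels": int(len(keys)),
        },
    )
    return ForwardModel(
        gains=gains,
        modality="fmri",
        montage=mont,
        surface=surface,
        metadata=dict(mont.metadata),
    )


def normalize_rows(model: ForwardModel) -> ForwardModel:
    """Divide each row by its L2 norm; drop (and report) zero-norm rows.

    Idempotent: a normalized model is returned unchanged.
    """
    if model.normalized:
        return model
    norms = model.row_norms()
    keep = norms > 0
    dropped = int((~keep).sum())
    gains = model.gains
    montage = model.montage
    if dropped:
        gains = gains[keep]
        montage = montage.subset(keep)
        norms = norms[keep]
    if sp.issparse(gains):
        gains = sp.diags(1.0 / norms) @ gains
    else:
        gains = gains / norms[:, None]
    return ForwardModel(
        gains=gains,
        modality=model.modality,
        montage=montage,
        surface=model.surface,
        normalized=True,
        valid_channel_mask=keep,
        metadata={**model.metadata, "dropped_zero_rows": dropped},
    )
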