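"""Forward model physics: EEG shell series, MEG Sarvas field, DOT Rytov,
fMRI voxel averaging, and row normalization."""

import numpy as np
import pytest
import scipy.sparse as sp

from neuroscale import HeadModel, build_cortical_surface, build_montage
from neuroscale.forward import (
    _eeg_transfer_factors,
    _sarvas_field,
    _semi_infinite_fluence,
    dot_sensitivity,
    eeg_leadfield,
    fmri_voxel_model,
    meg_leadfield,
    normalize_rows,
)
from neuroscale.geometry import CorticalSurface


# ---------------------------------------------------------------- EEG ----
def _homogeneous_sphere_potential(q, r0, electrodes, sigma, R, lmax=200):
    """Independent oracle: bounded homogeneous sphere dipole potential.

    Writes the solution as the exact infinite-medium dipole potential plus
    the interior harmonic correction whose coefficients follow directly
    from the zero-current boundary condition a_l = c_l (l+1)/l R^-(2l+1);
    a decomposition disjoint from the implementation's layer-matrix series.
    """
    out = np.zeros(len(electrodes))
    b = np.linalg.norm(r0)
    for e_i, r in enumerate(electrodes):
        d = r - r0
        v_inf = q @ d / np.linalg.norm(d) ** 3
        # expansion coefficients of the infinite-medium dipole about origin
        u = (r0 @ r) / (b * np.linalg.norm(r)) if b > 0 else 0.0
        rn = np.linalg.norm(r)
        rhat = r / rn
        r0hat = r0 / b if b > 0 else np.zeros(3)
        qr = q @ r0hat
        qtan = q @ rhat - u * qr
        corr = 0.0
        # c_l r^-(l+1) terms -> correction a_l r^l with a_l = c_l (l+1)/l R^-(2l+1)
        P = [1.0, u]
        dP = [0.0, 1.0]
        for l in range(1, lmax + 1):
            if l > 1:
                P.append(((2 * l - 1) * u * P[l - 1] - (l - 1) * P[l - 2]) / l)
                dP.append(dP[l - 2] + (2 * l - 1) * P[l - 1])
            c_ang = b ** (l - 1) * (l * qr * P[l] + qtan * dP[l])
            corr += (l + 1) / l * R ** -(2 * l + 1) * rn**l * c_ang
        out[e_i] = (v_inf + corr) / (4 * np.pi * sigma)
    return out


def test_eeg_transfer_reduces_to_homogeneous_sphere():
    head = HeadModel(conductivities=(0.3, 0.3, 0.3))
    T = _eeg_transfer_factors(head, 50)
    ls = np.arange(1, 51)
    assert np.allclose(T, (2 * ls + 1) / ls, rtol=1e-10)


def test_eeg_matches_closed_form_homogeneous_oracle(surf4_smooth, head):
    """Equal conductivities: the shell series equals the independently
    derived bounded homogeneous-sphere potential."""
    hom = HeadModel(conductivities=(0.3, 0.3, 0.3), fold_amplitude=head.fold_amplitude)
    mont = build_montage("eeg", hom, n=40)
    lf = eeg_leadfield(surf4_smooth, mont, hom)
    rng = np.random.default_rng(0)
    for node in rng.choice(surf4_smooth.n_nodes, 5, replace=False):
        v = _homogeneous_sphere_potential(
            surf4_smooth.node_normals[node],
            surf4_smooth.node_positions[node],
            mont.positions,
            0.3,
            hom.scalp_radius,
        )
        v -= v.mean()  # average reference
        assert np.allclose(lf.gains[:, node], v, rtol=1e-6, atol=1e-9 * np.abs(v).max())


def test_eeg_center_dipole_average_reference(head):
    """Near-central dipole: potentials sum to zero after average reference
    and follow the l=1 harmonic pattern."""
    pos = np.array([[0.0, 0.0, 1e-6]])
    surf = CorticalSurface(
        node_positions=pos,
        node_normals=np.array([[0.0, 0.0, 1.0]]),
        node_areas=np.array([1.0]),
        sphere_map=np.array([[0.0, 0.0, 1.0]]),
        hemisphere_label=np.array([1], dtype=np.int8),
        cortical_mask=np.array([True]),
        faces=np.empty((0, 3), dtype=np.int64),
    )
    mont = build_montage("eeg", head)
    lf = eeg_leadfield(surf, mont, head)
    assert lf.gains.shape == (286, 1)
    assert abs(lf.gains[:, 0].sum()) < 1e-12 * np.abs(lf.gains).max()
    # l=1 only: potential proportional to cos(polar angle) up to the reference shift
    cosz = mont.positions[:, 2] / head.scalp_radius
    c = np.corrcoef(lf.gains[:, 0], cosz - cosz.mean())[0, 1]
    assert c > 1.0 - 1e-9


def test_eeg_source_outside_inner_skull_rejected(head, montages):
    bad = CorticalSurface(
        node_positions=np.array([[8.5, 0.0, 0.0]]),
        node_normals=np.array([[1.0, 0.0, 0.0]]),
        node_areas=np.array([1.0]),
        sphere_map=np.array([[1.0, 0.0, 0.0]]),
        hemisphere_label=np.array([1], dtype=np.int8),
        cortical_mask=np.array([True]),
        faces=np.empty((0, 3), dtype=np.int64),
    )
    with pytest.raises(ValueError, match="outside inner skull"):
        eeg_leadfield(bad, montages["eeg"], head)


def test_eeg_three_shell_matches_mne_sphere_model(head):
    """Independent cross-check: three-shell potentials against the sphere
    model of an established M/EEG toolbox (topography correlation and
    residual after optimal scaling)."""
    mne = pytest.importorskip("mne")
    mne.set_log_level("ERROR")
    from neuroscale.montage import SensorMontage, fibonacci_cap

    sphere = mne.make_sphere_model(
        r0=(0, 0, 0),
        head_radius=0.092,
        relative_radii=(8.2 / 9.2, 8.7 / 9.2, 1.0),
        sigmas=(0.3, 0.006, 0.3),
    )
    units = fibonacci_cap(50, 120.0)
    names = [f"E{i:02d}" for i in range(50)]
    info = mne.create_info(names, 1000.0, "eeg")
    info.set_montage(
        mne.channels.make_dig_montage(
            ch_pos=dict(zip(names, units * 0.092)), coord_frame="head"
        )
    )
    for ori in (np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]])):
        dip = mne.Dipole(
            times=[0.0], pos=np.array([[0, 0, 0.070]]), amplitude=[1e-9], ori=ori, gof=[100.0]
        )
        fwd, _ = mne.forward.make_forward_dipole(dip, sphere, info)
        v_ref = fwd["sol"]["data"][:, 0]
        v_ref = v_ref - v_ref.mean()
        surf = CorticalSurface(
            node_positions=np.array([[0.0, 0.0, 7.0]]),
            node_normals=ori.astype(float),
            node_areas=np.array([1.0]),
            sphere_map=np.array([[0.0, 0.0, 1.0]]),
            hemisphere_label=np.array([1], dtype=np.int8),
            cortical_mask=np.array([True]),
            faces=np.empty((0, 3), dtype=np.int64),
        )
        mont = SensorMontage(modality="eeg", positions=units * 9.2, channel_ids=names)
        v_us = eeg_leadfield(surf, mont, head)
        v = v_us.gains[:, 0]
        assert np.corrcoef(v, v_ref)[0, 1] > 0.9999
        scale = np.linalg.norm(v_ref) / np.linalg.norm(v)
        assert np.linalg.norm(v * scale - v_ref) < 0.01 * np.linalg.norm(v_ref)


# ---------------------------------------------------------------- MEG ----
def test_meg_radial_dipoles_silent_on_smooth_sphere(surf4_smooth, head, montages):
    lf = meg_leadfield(surf4_smooth, montages["meg_mag"], head)
    assert np.abs(lf.gains).max() < 1e-12


def test_meg_channel_counts(surf4, head, montages):
    mag = meg_leadfield(surf4, montages["meg_mag"], head)
    grad = meg_leadfield(surf4, montages["meg_grad"], head)
    assert mag.gains.shape[0] == 102
    assert grad.gains.shape[0] == 204
    assert np.isfinite(mag.gains).all() and np.isfinite(grad.gains).all()


def test_gradiometer_converges_to_field_derivative(surf4, head):
    """Richardson extrapolation of the finite-difference gradiometer gain
    converges to the analytic tangential derivative of the radial field."""
    mont = build_montage("meg_grad", head)
    i = 17  # arbitrary channel
    e, n, p = mont.orientations[i], mont.normals[i], mont.positions[i]
    r0 = surf4.node_positions[:50]
    q = surf4.node_normals[:50]

    def grad_gain(h):
        return (_sarvas_field(r0, q, p + h / 2 * e) @ n - _sarvas_field(r0, q, p - h / 2 * e) @ n) / h

    g1, g2 = grad_gain(0.4), grad_gain(0.2)
    richardson = (4 * g2 - g1) / 3  # O(h^4) limit of the central difference
    tiny = grad_gain(1e-4)  # reference derivative
    scale = np.abs(tiny).max()
    assert np.abs(richardson - tiny).max() < 1e-4 * scale
    assert np.abs(g1 - tiny).max() > np.abs(g2 - tiny).max()  # O(h^2) shrinkage


def test_meg_sign_flips_with_dipole_orientation(surf4, head, montages):
    lf = meg_leadfield(surf4, montages["meg_mag"], head)
    import dataclasses

    flipped = dataclasses.replace(surf4, node_normals=-surf4.node_normals)
    lf2 = meg_leadfield(flipped, montages["meg_mag"], head)
    assert np.allclose(lf.gains, -lf2.gains)


def test_meg_sensor_inside_conductor_rejected(surf4, head):
    import dataclasses

    mont = build_montage("meg_mag", head)
    bad = dataclasses.replace(mont, positions=mont.positions * 0.5)
    with pytest.raises(ValueError, match="inside the conductor"):
        meg_leadfield(surf4, bad, head)


# ---------------------------------------------------------------- DOT ----
def test_dot_reciprocity(surf4, head, montages):
    """Swapping source and detector of a channel leaves its sensitivity
    profile unchanged."""
    dot = montages["dot"]
    lf = dot_sensitivity(surf4, dot, head)
    import dataclasses

    swapped = dataclasses.replace(dot, pairing=dot.pairing[:, ::-1])
    lf2 = dot_sensitivity(surf4, swapped, head)
    assert np.allclose(lf.gains, lf2.gains)


def test_dot_peak_depth_by_grid_search(head):
    """Max sensitivity beneath the pair midpoint sits at positive depth,
    and moves deeper as the source-detector separation grows."""

    def peak_depth(sep):
        # both optodes on a plane; brute-force grid down the midline
        depths = np.linspace(0.05, 3.0, 400)
        rho = sep / 2.0
        phi_s = _semi_infinite_fluence(np.full_like(depths, rho**2), depths, head)
        phi0 = _semi_infinite_fluence(np.array([sep**2]), np.array([0.0]), head)[0]
        sens = phi_s * phi_s / phi0  # symmetric midline: Phi_s == Phi_d
        return depths[np.argmax(sens)]

    d25 = peak_depth(2.5)
    assert 0.1 < d25 < 2.0
    assert peak_depth(3.0) > peak_depth(2.0)


def test_dot_sensitivity_decays_below_peak(head):
    depths = np.linspace(0.05, 4.0, 500)
    phi = _semi_infinite_fluence(np.full_like(depths, 1.0), depths, head)
    peak = np.argmax(phi)
    assert (np.diff(phi[peak:]) < 0).all()


# --------------------------------------------------------------- fMRI ----
def test_fmri_voxel_averaging_identity(surf4):
    fm = fmri_voxel_model(surf4, min_nodes=1)
    v = np.full(surf4.n_nodes, 3.7)
    v[~surf4.cortical_mask] = 0.0
    y = fm.gains @ v
    assert np.allclose(y, 3.7)


def test_fmri_filters_match_exhaustive_recount(surf4):
    """Surviving-voxel count equals a brute-force per-voxel recount."""
    fm = fmri_voxel_model(surf4, min_nodes=2, min_gm_fraction=0.2)
    # brute force: re-bin a 500-node patch... use all cortical nodes directly
    mask = surf4.cortical_mask
    pos = surf4.node_positions[mask]
    areas = surf4.node_areas[mask]
    origin = pos.min(axis=0) - 1e-9
    keys = {}
    for p, a in zip(pos, areas):
        k = tuple(np.floor((p - origin) / 0.3).astype(int))
        keys.setdefault(k, []).append(a)
    survivors = 0
    for k, alist in keys.items():
        gm = min(1.0, len(alist) * np.mean(alist) * 0.3 / 0.3**3)
        if len(alist) >= 2 and gm >= 0.2:
            survivors += 1
    assert fm.gains.shape[0] == survivors


def test_fmri_no_survivors_reports_diagnostics(surf4):
    with pytest.raises(ValueError, match="min_nodes"):
        fmri_voxel_model(surf4, min_nodes=1000)


def test_fmri_rows_nonnegative_and_sum_to_one(surf4):
    fm = fmri_voxel_model(surf4, min_nodes=2)
    g = fm.gains
    assert (g.data >= 0).all()
    assert np.allclose(np.asarray(g.sum(axis=1)).ravel(), 1.0)


# ------------------------------------------------------ normalization ----
def test_normalize_rows_properties(surf4, head, montages):
    lf = meg_leadfield(surf4, montages["meg_mag"], head)
    norm = normalize_rows(lf)
    assert np.allclose(np.linalg.norm(norm.gains, axis=1), 1.0, atol=1e-9)
    again = normalize_rows(norm)  # idempotent
    assert again is norm
    # relative gains within a row preserved
    rng = np.random.default_rng(4)
    for i in rng.choice(lf.gains.shape[0], 5, replace=False):
        j, l = rng.choice(lf.gains.shape[1], 2, replace=False)
        if lf.gains[i, l] != 0:
            assert norm.gains[i, j] / norm.gains[i, l] == pytest.approx(
                lf.gains[i, j] / lf.gains[i, l]
            )


def test_normalize_drops_zero_rows(surf4, montages):
    from neuroscale.forward import ForwardModel

    g = np.vstack([np.ones(surf4.n_nodes), np.zeros(surf4.n_nodes), np.ones(surf4.n_nodes)])
    mont = montages["eeg"].subset(np.arange(286) < 3)
    fm = ForwardModel(gains=g, modality="eeg", montage=mont)
    out = normalize_rows(fm)
    assert out.gains.shape[0] == 2
    assert out.metadata["dropped_zero_rows"] == 1


def test_forward_linearity_and_smooth_sphere_contrast(surf4_smooth, head, montages):
    """On the unfolded sphere MEG carries ~no signal while EEG does ---
    folding is what gives MEG its sensitivity."""
    eeg = normalize_rows(eeg_leadfield(surf4_smooth, montages["eeg"], head))
    rng = np.random.default_rng(0)
    x1 = rng.standard_normal(surf4_smooth.n_nodes)
    x2 = rng.standard_normal(surf4_smooth.n_nodes)
    assert np.allclose(eeg.gains @ (x1 + x2), eeg.gains @ x1 + eeg.gains @ x2, atol=1e-12)
    mag_raw = meg_leadfield(surf4_smooth, montages["meg_mag"], head)
    assert np.abs(mag_raw.gains).max() < 1e-12  # nothing to normalize: silent
    assert np.abs(eeg.gains @ x1).max() > 1e-3
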