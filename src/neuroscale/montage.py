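"""Sensor montages for the four modalities.

Electrode/optode layouts are quasi-uniform Fibonacci lattices on a spherical
cap around the vertex, standing in for 10/5-system positioning; the MEG
helmet is a sphere offset beyond the scalp carrying one radial magnetometer
and two orthogonal tangential planar gradiometers per site, like a
Vectorview array.  DOT optodes sit in alternating source/detector rows and
every source-detector pair inside the separation window becomes a channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HeadModel

__all__ = ["SensorMontage", "build_montage", "montage_from_csv"]

MODALITIES = ("eeg", "meg_mag", "meg_grad", "dot", "fmri")


@dataclass
class SensorMontage:
    """Modality-tagged sensor channels.

    ``positions`` is the per-channel 3D location used for inter-sensor
    distances (DOT: pair midpoint; gradiometers: helmet site, so the two
    channels of a site are 0 cm apart).  ``orientations`` is the
    magnetometer normal / gradiometer baseline direction; ``normals`` the
    measured field component direction for MEG channels.
    """

    modality: str
    positions: np.ndarray  # (N, 3) cm
    channel_ids: list[str]
    orientations: np.ndarray | None = None  # (N, 3)
    normals: np.ndarray | None = None  # (N, 3), MEG measured component
    baseline: float | None = None  # cm, gradiometers
    optode_positions: np.ndarray | None = None  # (P, 3), DOT
    optode_is_source: np.ndarray | None = None  # (P,), DOT
    pairing: np.ndarray | None = None  # (N, 2) optode indices, DOT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.channel_ids) != len(set(self.channel_ids)):
            raise ValueError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def min_separation(self) -> float:
        """Smallest nonzero inter-channel distance, cm."""
        d = np.linalg.norm(self.positions[:, None, :] - self.positions[None, :, :], axis=-1)
        d = d[d > 1e-9]
        return float(d.min()) if d.size else 0.0

    def subset(self, mask: np.ndarray) -> "SensorMontage":
        idx = np.nonzero(mask)[0]
        return SensorMontage(
            modality=self.modality,
            positions=self.positions[idx],
            channel_ids=[self.channel_ids[i] for i in idx],
            orientations=None if self.orientations is None else self.orientations[idx],
            normals=None if self.normals is None else self.normals[idx],
            baseline=self.baseline,
            optode_positions=self.optode_positions,
            optode_is_source=self.optode_is_source,
            pairing=None if self.pairing is None else self.pairing[idx],
            metadata=dict(self.metadata),
        )

    def to_dataframe(self):
        import pandas as pd

        cols = {
            "id": self.channel_ids,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
        }
        ori = self.orientations if self.orientations is not None else np.zeros_like(self.positions)
        cols.update({"nx": ori[:, 0], "ny": ori[:, 1], "nz": ori[:, 2]})
        if self.pairing is not None:
            cols["source_index"] = self.pairing[:, 0]
            cols["detector_index"] = self.pairing[:, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def fibonacci_cap(n: int, cap_deg: float) -> np.ndarray:
    """n quasi-uniform unit vectors on the polar cap of half-angle cap_deg."""
    i = np.arange(n)
    z = 1.0 - (1.0 - np.cos(np.deg2rad(cap_deg))) * (i + 0.5) / n
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))  # golden angle
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tangent_frame(units: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangential directions (azimuthal, polar-ish) per unit vector."""
    zhat = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(np.broadcast_to(zhat, units.shape), units)
    n1 = np.linalg.norm(e1, axis=1, keepdims=True)
    degenerate = n1[:, 0] < 1e-12
    if degenerate.any():
        e1[degenerate] = [1.0, 0.0, 0.0]
        n1[degenerate] = 1.0
    e1 = e1 / n1
    e2 = np.cross(units, e1)
    return e1, e2


def _check_cap_capacity(n: int, cap_deg: float, radius: float, min_spacing: float, what: str) -> None:
    """Fail if n sensors of footprint min_spacing cannot fit on the cap."""
    cap_area = 2 * np.pi * radius**2 * (1 - np.cos(np.deg2rad(cap_deg)))
    achievable = int(cap_area / min_spacing**2)
    if n > achievable:
        raise ValueError(
            f"cap of {cap_deg} deg fits at most {achievable} {what} "
            f"at {min_spacing} cm spacing; {n} requested"
        )


def _eeg_montage(head: HeadModel, n: int, cap_deg: float, min_spacing: float = 0.5) -> SensorMontage:
    _check_cap_capacity(n, cap_deg, head.scalp_radius, min_spacing, "electrodes")
    units = fibonacci_cap(n, cap_deg)
    pos = units * head.scalp_radius
    return SensorMontage(
        modality="eeg",
        positions=pos,
        channel_ids=[f"EEG{i:03d}" for i in range(n)],
        orientations=units.copy(),
        metadata={"cap_deg": cap_deg},
    )


def _meg_montages(
    head: HeadModel, n_sites: int, cap_deg: float, helmet_offset: float, baseline: float
) -> tuple[SensorMontage, SensorMontage]:
    r = head.scalp_radius + helmet_offset
    _check_cap_capacity(n_sites, cap_deg, r, 2.0, "MEG sites")
    units = fibonacci_cap(n_sites, cap_deg)
    sites = units * r
    e1, e2 = _tangent_frame(units)
    mag = SensorMontage(
        modality="meg_mag",
        positions=sites,
        channel_ids=[f"MAG{i:03d}" for i in range(n_sites)],
        orientations=units.copy(),
        normals=units.copy(),
        metadata={"cap_deg": cap_deg, "helmet_offset": helmet_offset},
    )
    grad_pos = np.repeat(sites, 2, axis=0)
    grad_ori = np.empty_like(grad_pos)
    grad_ori[0::2] = e1
    grad_ori[1::2] = e2
    grad_norm = np.repeat(units, 2, axis=0)
    ids = []
    for i in range(n_sites):
        ids += [f"GRD{i:03d}a", f"GRD{i:03d}b"]
    grad = SensorMontage(
        modality="meg_grad",
        positions=grad_pos,
        channel_ids=ids,
        orientations=grad_ori,
        normals=grad_norm,
        baseline=baseline,
        metadata={"cap_deg": cap_deg, "helmet_offset": helmet_offset},
    )
    return mag, grad


def _dot_montage(
    head: HeadModel,
    cap_deg: float,
    row_spacing: float,
    in_row_spacing: float,
    pair_window: tuple[float, float],
) -> SensorMontage:
    R = head.scalp_radius
    dtheta = row_spacing / R
    n_rows = int(np.deg2rad(cap_deg) / dtheta)
    optodes, is_source = [], []
    for i in range(n_rows + 1):
        theta = i * dtheta
        if i == 0:
            ring = np.array([[0.0, 0.0, 1.0]])
        else:
            circ = 2 * np.pi * R * np.sin(theta)
            m = max(1, int(round(circ / in_row_spacing)))
            phi = 2 * np.pi * np.arange(m) / m + (np.pi / m if i % 2 else 0.0)
            ring = np.column_stack(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.full(m, np.cos(theta))]
            )
        optodes.append(ring * R)
        is_source += [i % 2 == 0] * len(ring)
    optodes = np.vstack(optodes)
    is_source = np.array(is_source)
    src_idx = np.nonzero(is_source)[0]
    det_idx = np.nonzero(~is_source)[0]
    lo, hi = pair_window
    pairs, pos = [], []
    for s in src_idx:
        d = np.linalg.norm(optodes[det_idx] - optodes[s], axis=1)
        for j, dj in zip(det_idx, d):
            if lo <= dj <= hi:
                pairs.append((s, j))
                pos.append(0.5 * (optodes[s] + optodes[j]))
    if not pairs:
        raise ValueError("DOT cap too small: no source-detector pairs inside the window")
    return SensorMontage(
        modality="dot",
        positions=np.array(pos),
        channel_ids=[f"DOT{s:03d}-{d:03d}" for s, d in pairs],
        optode_positions=optodes,
        optode_is_source=is_source,
        pairing=np.array(pairs, dtype=np.int64),
        metadata={"cap_deg": cap_deg, "pair_window": tuple(pair_window)},
    )


def build_montage(modality: str, head: HeadModel, **params) -> SensorMontage:
    """Build the default montage for one modality.

    EEG: ``n`` (286) electrodes on a ``cap_deg`` (120) scalp cap.
    MEG: ``n_sites`` (102) helmet sites -> returns the magnetometer montage
    for ``meg_mag`` and the 2x tangential gradiometer montage (baseline
    ``baseline`` = 1.68 cm) for ``meg_grad``.
    DOT: alternating source/detector rows (spacings 2.2 cm), channels are
    all pairs separated by ``pair_window`` = (2, 3) cm.
    fMRI channels are voxel centers chosen by the forward model; see
    :func:`neuroscale.forward.fmri_voxel_model`.
    """
    head.validate()
    modality = modality.lower()
    if modality == "eeg":
        return _eeg_montage(head, params.pop("n", 286), params.pop("cap_deg", 120.0))
    if modality in ("meg_mag", "meg_grad"):
        mag, grad = _meg_montages(
            head,
            params.pop("n_sites", 102),
            params.pop("cap_deg", 110.0),
            params.pop("helmet_offset", 2.5),
            params.pop("baseline", 1.68),
        )
        return mag if modality == "meg_mag" else grad
    if modality == "dot":
        return _dot_montage(
            head,
            params.pop("cap_deg", 120.0),
            params.pop("row_spacing", 2.2),
            params.pop("in_row_spacing", 2.2),
            tuple(params.pop("pair_window", (2.0, 3.0))),
        )
    if modality == "fmri":
        raise ValueError("fMRI sensors are voxel centers; use forward.fmri_voxel_model")
    raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")


def montage_from_csv(path, modality: str) -> SensorMontage:
    """Load a user-provided sensor table (id, x, y, z[, nx, ny, nz])."""
    import pandas as pd

    df = pd.read_csv(path)
    pos = df[["x", "y", "z"]].to_numpy(float)
    ori = df[["nx", "ny", "nz"]].to_numpy(float) if "nx" in df else None
    return SensorMontage(
        modality=modality.lower(),
        positions=pos,
        channel_ids=[str(s) for s in df["id"]],
        orientations=ori,
        normals=ori,
        metadata={"source": str(path)},
    )
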