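"""Trajectory statistics: contact probability, Z-density profiles, MSD → D.

These implement the analysis definitions used to characterize packed and
simulated systems: Cα–Cα contact probability at a 7 Å cutoff, symmetrized and
normalized Z-density histograms (2.46 Å bins), and the lateral diffusion
coefficient from a time-and-ensemble averaged 2-D mean square displacement.
"""

from __future__ import annotations

import numpy as np

from .cg import minimum_image

CONTACT_CUTOFF = 7.0  # Å, Cα-Cα
Z_BIN = 2.46  # Å
A2_PER_NS_TO_UM2_PER_S = 10.0  # 1 Å²/ns = 10 µm²/s


def contact_probability(
    traj_a: np.ndarray,
    traj_b: np.ndarray,
    box: np.ndarray | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> float:
    """Fraction of frames with at least one Cα–Cα pair within ``cutoff``.

    ``traj_a``/``traj_b`` are (frames, atoms, 3) arrays with equal frame
    counts; distances use the minimum image when a box is given.
    """
    a = np.asarray(traj_a, float)
    b = np.asarray(traj_b, float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[0] != b.shape[0]:
        raise ValueError("trajectories must be (frames, atoms, 3) with equal frames")
    if a.shape[0] == 0:
        raise ValueError("empty trajectory")
    hits = 0
    for fa, fb in zip(a, b):
        d = fa[:, None, :] - fb[None, :, :]
        if box is not None:
            d = minimum_image(d, np.asarray(box, float))
        if np.any((d**2).sum(-1) <= cutoff**2):
            hits += 1
    return hits / a.shape[0]


def z_density_profile(
    coords_per_frame: np.ndarray,
    box_z: float,
    bin_size: float = Z_BIN,
    symmetrize: bool = True,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Z histogram over frames with optional ±z symmetrization.

    Returns (bin_centers, heights).  Z values are wrapped into
    [-box_z/2, box_z/2); bins are symmetric about 0.  Symmetrization averages
    the bins at +z and -z; normalization scales the heights to sum to 1.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    z = np.asarray(coords_per_frame, float).reshape(-1, 3)[:, 2]
    z = minimum_image(z, box_z * np.ones_like(z))
    # odd bin count with the middle bin centered on z = 0, so symmetrization
    # maps bins onto bins
    half_n = max(1, int(np.ceil((box_z / bin_size - 1) / 2)))
    edges = bin_size * (np.arange(-half_n, half_n + 2) - 0.5)
    hist, _ = np.histogram(z, bins=edges)
    hist = hist.astype(float)
    if symmetrize:
        hist = 0.5 * (hist + hist[::-1])
    if normalize and hist.sum() > 0:
        hist = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist


def msd_diffusion(
    xy_traj: np.ndarray,
    dt_per_frame: float,
    lag_range: tuple[float, float] = (1.0, 250.0),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Lateral diffusion coefficient from a 2-D MSD fit.

    ``xy_traj`` is (frames, particles, 2) of unwrapped coordinates in Å;
    ``dt_per_frame`` in ns.  The MSD is averaged over particles and over all
    time origins for every lag in ``lag_range`` (ns); the least-squares slope
    m of MSD(τ) gives D = m/4, returned in µm²/s together with the (lags
    in ns, MSD in Å²) arrays used for the fit.
    """
    xy = np.asarray(xy_traj, float)
    if xy.ndim == 2:
        xy = xy[:, None, :]
    n_frames = xy.shape[0]
    lag_lo = max(1, int(round(lag_range[0] / dt_per_frame)))
    lag_hi = int(round(lag_range[1] / dt_per_frame))
    if lag_hi >= n_frames:
        raise ValueError("lag range exceeds trajectory length")
    lags = np.arange(lag_lo, lag_hi + 1)
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        msd[k] = np.mean((d**2).sum(-1))
    tau = lags * dt_per_frame
    slope = np.polyfit(tau, msd, 1)[0]  # Å²/ns
    d_coeff = slope / 4.0 * A2_PER_NS_TO_UM2_PER_S
    return float(d_coeff), tau, msd
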