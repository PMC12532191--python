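"""Synthetic data generators with known ground truth.

Every analysis in this package consumes one of four kinds of raw data:

* blinking single-molecule localization tables (clustered point patterns
  with fiducial markers and stage drift),
* photon-count traces from molecules diffusing through a Gaussian
  confocal observation volume (3D in the medium, 2D in the membrane),
* two-channel ratiometric calcium-indicator time series with
  photobleaching, and
* two-channel images of a ring-shaped plasma membrane with a prescribed
  generalized polarization.

The generators here emulate the statistical structure those analyses
assume, and return the ground truth alongside the data so that every
estimator can be tested as a recovery problem.  All randomness flows
from a single ``numpy.random.Generator`` seeded per call; the same seed
and the same truth give bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SmlmGroundTruth",
    "FcsGroundTruth",
    "TransientGroundTruth",
    "simulate_smlm",
    "simulate_fcs_trace",
    "simulate_ratio_trace",
    "simulate_gp_image",
    "write_ground_truth",
]

MAX_LOCALIZATIONS = 10_000_000
MAX_TRACE_BINS = 100_000_000


class SimulationSizeError(ValueError):
    """Requested simulation would exceed the documented size guard."""


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------


@dataclass
class SmlmGroundTruth:
    """Parameters (and, after simulation, realized truth) of an SMLM field.

    Lengths are nm unless noted; densities are per μm²; times are s.

    Parameters
    ----------
    cluster_density : float
        Intensity of the homogeneous Poisson process of cluster centers,
        clusters/μm².
    molecules_per_cluster_mean : float
        Poisson mean of the member count per cluster.
    cluster_sigma : float
        Isotropic Gaussian spread of member molecules around their
        cluster center, nm.
    background_density : float
        Density of non-clustered (CSR) molecules, molecules/μm².
    alpha_true : float
        Mean number of localization appearances per molecule (≥ 1);
        appearance counts are 1 + Geometric with mean ``alpha_true``.
    dark_time_scale : float
        Exponential scale of the dark gaps between successive
        appearances of one molecule, s.
    localization_precision : float
        Gaussian localization error per appearance, nm.
    drift_velocity : tuple
        Linear stage drift, (nm/frame, nm/frame).
    field_size : float
        Side of the square field of view, μm.
    n_frames, frame_exposure : int, float
        Acquisition length (frames) and exposure per frame (s).
    n_fiducials : int
        Fiducial beads emitted in every frame.
    random_walk_drift_sd : float
        If > 0, adds a per-frame random-walk component (nm/√frame) on
        top of the linear drift.
    """

    cluster_density: float = 5.0
    molecules_per_cluster_mean: float = 10.0
    cluster_sigma: float = 30.0
    background_density: float = 20.0
    alpha_true: float = 3.3
    dark_time_scale: float = 2.0
    localization_precision: float = 15.0
    drift_velocity: tuple = (0.001, 0.0005)
    field_size: float = 5.0
    n_frames: int = 60_000
    frame_exposure: float = 0.010
    n_fiducials: int = 3
    random_walk_drift_sd: float = 0.0
    # populated by simulate_smlm
    molecule_positions: np.ndarray | None = field(default=None, repr=False)
    cluster_centers: np.ndarray | None = field(default=None, repr=False)
    fiducial_positions: np.ndarray | None = field(default=None, repr=False)
    drift_trajectory: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.cluster_density < 0 or self.background_density < 0:
            raise ValueError("densities must be >= 0")
        if self.localization_precision < 0:
            raise ValueError("localization_precision must be >= 0")
        if self.alpha_true < 1:
            raise ValueError("alpha_true must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.field_size <= 0 or self.frame_exposure <= 0:
            raise ValueError("field_size and frame_exposure must be > 0")


@dataclass
class FcsGroundTruth:
    """Parameters of a mixed 3D (medium) + 2D (membrane) diffusion trace.

    ``D_2d``/``D_3d`` are μm²/s, radii μm, times s, brightness counts/s
    per molecule at the center of the observation volume.
    """

    D_2d: float = 0.5
    D_3d: float = 47.0
    n_particles_2d: int = 50
    n_particles_3d: int = 0
    triplet_fraction: float = 0.0
    triplet_tau: float = 5e-6
    omega_xy: float = 0.2
    omega_z: float = 1.0
    brightness: float = 30_000.0
    bin_time: float = 2e-4
    duration: float = 200.0
    box_size: float = 2.0

    def __post_init__(self):
        if min(self.D_2d, self.D_3d, self.omega_xy, self.omega_z,
               self.bin_time, self.duration, self.box_size) <= 0:
            raise ValueError("rates and sizes must be > 0")
        if not 0 <= self.triplet_fraction < 1:
            raise ValueError("triplet_fraction must be in [0, 1)")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")

    @property
    def fraction_2d(self) -> float:
        """Box-count fraction of membrane-confined particles."""
        total = self.n_particles_2d + self.n_particles_3d
        return self.n_particles_2d / total if total else 0.0


@dataclass
class TransientGroundTruth:
    """Truth for a two-channel ratiometric calcium transient.

    The true ratio trace is ``baseline_ratio`` before the stimulus and
    peaks at ``baseline_ratio + amplitude`` after a linear rise of
    ``rise_frames`` frames followed by an exponential decay with scale
    ``decay_frames``.
    """

    baseline_ratio: float = 1.0
    amplitude: float = 0.5
    rise_frames: int = 3
    decay_frames: int = 20
    bleach_rate_bound: float = 0.005
    bleach_rate_unbound: float = 0.005
    noise_sd: float = 1.0
    stim_frame: int = 4
    n_frames: int = 55
    base_intensity: float = 100.0

    def __post_init__(self):
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")
        if self.stim_frame < 4:
            raise ValueError("stim_frame must be >= 4 (pre-stimulus frames)")
        if self.n_frames <= self.stim_frame:
            raise ValueError("n_frames must exceed stim_frame")


# ---------------------------------------------------------------------------
# SMLM
# ---------------------------------------------------------------------------


def _blink_frames(rng, n_molecules, alpha, dark_scale_frames, n_frames):
    """Appearance frames for each molecule.

    Appearance count per molecule is geometric on {1, 2, ...} with mean
    ``alpha`` (equivalently 1 + a geometric number of re-appearances with
    mean alpha − 1); successive appearances are separated by
    exponential dark gaps.  Returns (molecule_index, frame) arrays.
    """
    if alpha == 1.0:
        counts = np.ones(n_molecules, dtype=np.int64)
    else:
        counts = rng.geometric(1.0 / alpha, size=n_molecules)
    first = rng.integers(0, n_frames, size=n_molecules)
    total = int(counts.sum())
    mol_idx = np.repeat(np.arange(n_molecules), counts)
    frames = np.empty(total, dtype=np.int64)
    pos = 0
    for i in range(n_molecules):
        k = counts[i]
        f = np.empty(k, dtype=np.int64)
        f[0] = first[i]
        if k > 1:
            gaps = np.maximum(
                1, np.round(rng.exponential(dark_scale_frames, size=k - 1))
            ).astype(np.int64)
            f[1:] = first[i] + np.cumsum(gaps)
        frames[pos:pos + k] = f
        pos += k
    keep = frames < n_frames
    return mol_idx[keep], frames[keep]


def simulate_smlm(truth: SmlmGroundTruth, seed: int):
    """Simulate a blinking localization table with fiducials and drift.

    Returns ``(table, truth)`` where ``table`` is a DataFrame with
    columns ``frame, x_nm, y_nm, precision_nm, is_fiducial`` sorted by
    frame, and ``truth`` is the input object with realized molecule,
    cluster-center, fiducial positions and the drift trajectory filled
    in.  Coordinates are nm with the origin at the field corner.
    """
    rng = np.random.default_rng(seed)
    L_nm = truth.field_size * 1e3
    area_um2 = truth.field_size ** 2

    expected = (
        (truth.cluster_density * truth.molecules_per_cluster_mean
         + truth.background_density) * area_um2 * truth.alpha_true
        + truth.n_fiducials * truth.n_frames
    )
    if expected > MAX_LOCALIZATIONS:
        raise SimulationSizeError(
            f"expected ~{expected:.0f} localizations exceeds {MAX_LOCALIZATIONS}"
        )

    n_clusters = rng.poisson(truth.cluster_density * area_um2)
    centers = rng.uniform(0, L_nm, size=(n_clusters, 2))
    members = []
    for c in range(n_clusters):
        m = rng.poisson(truth.molecules_per_cluster_mean)
        if m:
            members.append(centers[c] + rng.normal(0, truth.cluster_sigma, (m, 2)))
    n_bg = rng.poisson(truth.background_density * area_um2)
    bg = rng.uniform(0, L_nm, size=(n_bg, 2))
    parts = [p for p in members if len(p)] + [bg]
    molecules = np.vstack(parts) if parts else np.empty((0, 2))
    # keep everything inside the field
    molecules = molecules[
        (molecules[:, 0] >= 0) & (molecules[:, 0] < L_nm)
        & (molecules[:, 1] >= 0) & (molecules[:, 1] < L_nm)
    ]

    dark_frames = truth.dark_time_scale / truth.frame_exposure
    mol_idx, frames = _blink_frames(
        rng, len(molecules), truth.alpha_true, dark_frames, truth.n_frames
    )

    # drift trajectory, nm, per frame
    f = np.arange(truth.n_frames)
    drift = np.column_stack([f * truth.drift_velocity[0],
                             f * truth.drift_velocity[1]]).astype(float)
    if truth.random_walk_drift_sd > 0:
        drift += np.cumsum(
            rng.normal(0, truth.random_walk_drift_sd, (truth.n_frames, 2)), axis=0
        )

    xy = molecules[mol_idx] + drift[frames]
    if truth.localization_precision > 0:
        xy = xy + rng.normal(0, truth.localization_precision, xy.shape)

    fid_pos = rng.uniform(0.1 * L_nm, 0.9 * L_nm, size=(truth.n_fiducials, 2))
    fid_frames = np.tile(np.arange(truth.n_frames), truth.n_fiducials)
    fid_idx = np.repeat(np.arange(truth.n_fiducials), truth.n_frames)
    fid_xy = fid_pos[fid_idx] + drift[fid_frames]
    if truth.localization_precision > 0:
        fid_xy = fid_xy + rng.normal(0, truth.localization_precision, fid_xy.shape)

    table = pd.DataFrame({
        "frame": np.concatenate([frames, fid_frames]),
        "x_nm": np.concatenate([xy[:, 0], fid_xy[:, 0]]),
        "y_nm": np.concatenate([xy[:, 1], fid_xy[:, 1]]),
        "precision_nm": truth.localization_precision,
        "is_fiducial": np.concatenate([
            np.zeros(len(frames), dtype=bool),
            np.ones(len(fid_frames), dtype=bool),
        ]),
    })
    table = table.sort_values("frame", kind="stable").reset_index(drop=True)

    truth.molecule_positions = molecules
    truth.cluster_centers = centers
    truth.fiducial_positions = fid_pos
    truth.drift_trajectory = drift
    return table, truth


# ---------------------------------------------------------------------------
# FCS
# ---------------------------------------------------------------------------


def _telegraph_duty(rng, n_bins, bin_time, f_t, tau_t):
    """Per-bin emitting fraction of a two-state triplet telegraph process.

    Simulated as a discrete Markov chain at the bin resolution; valid
    when ``bin_time`` ≲ ``tau_t``/2 (the generator's stated regime).
    """
    # rates: bright->dark k_d = F_T/tau_T, dark->bright k_b = (1-F_T)/tau_T
    p_bd = min(1.0, bin_time * f_t / tau_t)
    p_db = min(1.0, bin_time * (1.0 - f_t) / tau_t)
    state = np.empty(n_bins, dtype=bool)  # True = bright
    u = rng.random(n_bins)
    s = rng.random() >= f_t
    for i in range(n_bins):
        if s:
            if u[i] < p_bd:
                s = False
        else:
            if u[i] < p_db:
                s = True
        state[i] = s
    return state.astype(float)


def simulate_fcs_trace(truth: FcsGroundTruth, seed: int,
                       initial_positions_2d=None, initial_positions_3d=None):
    """Simulate a binned photon-count trace from Brownian particles.

    Particles random-walk in a periodic box centered on the observation
    volume (2D particles are confined to the focal plane z = 0), the
    Gaussian detection profile ``exp(−2 r²_xy/ω²_xy) exp(−2 z²/ω²_z)``
    weights their emission, an optional triplet telegraph process gates
    it, and photon counts per bin are Poisson.  Steps use the bin time
    directly (no sub-stepping).

    ``initial_positions_2d``/``_3d`` pin starting positions (μm,
    relative to the beam center) instead of uniform placement — useful
    for controlled configurations such as an immobile molecule at the
    focus.

    Returns ``(times_s, counts)``; both 1-D arrays of equal length.
    """
    n_bins = int(round(truth.duration / truth.bin_time))
    if n_bins > MAX_TRACE_BINS:
        raise SimulationSizeError(f"{n_bins} bins exceeds {MAX_TRACE_BINS}")
    if truth.box_size < 10 * truth.omega_xy:
        warnings.warn("box_size < 10 omega_xy; periodic images may correlate")

    rng = np.random.default_rng(seed)
    L = truth.box_size
    rate = np.zeros(n_bins)

    inits = {2: initial_positions_2d, 3: initial_positions_3d}
    for kind, n_p, D, dims in (("2d", truth.n_particles_2d, truth.D_2d, 2),
                               ("3d", truth.n_particles_3d, truth.D_3d, 3)):
        sd = np.sqrt(2.0 * D * truth.bin_time)
        pinned = None if inits[dims] is None else np.asarray(inits[dims], float)
        for ip in range(n_p):
            if pinned is not None and ip < len(pinned):
                pos0 = pinned[ip]
            else:
                pos0 = rng.uniform(-L / 2, L / 2, size=dims)
            steps = rng.normal(0.0, sd, size=(n_bins, dims))
            traj = pos0 + np.cumsum(steps, axis=0)
            traj = (traj + L / 2) % L - L / 2
            w = np.exp(-2.0 * (traj[:, 0] ** 2 + traj[:, 1] ** 2)
                       / truth.omega_xy ** 2)
            if dims == 3:
                w *= np.exp(-2.0 * traj[:, 2] ** 2 / truth.omega_z ** 2)
            rate += w

    if truth.triplet_fraction > 0:
        rate *= _telegraph_duty(rng, n_bins, truth.bin_time,
                                truth.triplet_fraction, truth.triplet_tau)

    counts = rng.poisson(truth.brightness * truth.bin_time * rate)
    times = np.arange(n_bins) * truth.bin_time
    return times, counts.astype(np.int64)


# ---------------------------------------------------------------------------
# ratiometric calcium transient
# ---------------------------------------------------------------------------


def simulate_ratio_trace(truth: TransientGroundTruth, seed: int):
    """Two-channel (Ca-bound, Ca-unbound) intensity series.

    The depolarization-evoked transient multiplies the true ratio by
    ``1 + (amplitude/baseline_ratio)·s(t)`` with s rising linearly to 1
    over ``rise_frames`` and decaying exponentially; the effect is
    split symmetrically between the channels (bound up, unbound down)
    so the channel product is transient-free, mimicking an indicator
    that converts between the two forms.  Both channels photobleach
    exponentially and carry additive Gaussian noise.

    Returns ``(bound, unbound, truth)``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(truth.n_frames)
    s = np.zeros(truth.n_frames)
    rise_end = truth.stim_frame + truth.rise_frames
    rising = (t >= truth.stim_frame) & (t < rise_end)
    s[rising] = (t[rising] - truth.stim_frame + 1) / truth.rise_frames
    after = t >= rise_end
    s[after] = np.exp(-(t[after] - (rise_end - 1)) / truth.decay_frames)

    g = 1.0 + (truth.amplitude / truth.baseline_ratio) * s
    unbound0 = truth.base_intensity
    bound0 = truth.baseline_ratio * unbound0
    bound = bound0 * np.exp(-truth.bleach_rate_bound * t) * np.sqrt(g)
    unbound = unbound0 * np.exp(-truth.bleach_rate_unbound * t) / np.sqrt(g)
    if truth.noise_sd > 0:
        bound = bound + rng.normal(0, truth.noise_sd, truth.n_frames)
        unbound = unbound + rng.normal(0, truth.noise_sd, truth.n_frames)
    return bound, unbound, truth


# ---------------------------------------------------------------------------
# GP ring-cell image
# ---------------------------------------------------------------------------


def simulate_gp_image(gp_true: float, cell_radius: float = 5.0,
                      ring_width: float = 0.4, noise_sd: float = 0.02,
                      seed: int = 0, pixel_size: float = 0.1,
                      image_size: int | None = None):
    """Two-channel image of a ring-shaped plasma membrane.

    The membrane is a Gaussian-profile ring of radius ``cell_radius``
    (μm) and 1/e half-width ``ring_width`` (μm); at the ring the summed
    channel intensity is 1 and the split obeys the generalized
    polarization ``gp_true``: ch1 = (1+GP)/2, ch2 = (1−GP)/2.  The
    interior is dim (10 % of the membrane), background dimmer (2 %),
    and both channels carry additive Gaussian noise of SD ``noise_sd``.

    Returns ``(image, truth_dict)`` with ``image`` shaped (2, H, W).
    """
    if not -1.0 <= gp_true <= 1.0:
        raise ValueError("gp_true must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    if image_size is None:
        image_size = int(np.ceil(2 * (cell_radius + 4 * ring_width) / pixel_size))
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(xx - c, yy - c) * pixel_size
    ring = np.exp(-((r - cell_radius) ** 2) / (2 * ring_width ** 2))
    interior = 0.10 * (r < cell_radius - 2 * ring_width)
    total = np.maximum(ring, interior) + 0.02
    ch1 = total * (1.0 + gp_true) / 2.0
    ch2 = total * (1.0 - gp_true) / 2.0
    img = np.stack([ch1, ch2])
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    truth = {"gp_true": gp_true, "cell_radius_um": cell_radius,
             "ring_width_um": ring_width, "pixel_size_um": pixel_size,
             "center_px": (c, c), "channels": ["I_560_580", "I_640_660"]}
    return img, truth


# ---------------------------------------------------------------------------
# sidecar ground truth
# ---------------------------------------------------------------------------


def write_ground_truth(truth, path) -> None:
    """Write a ground-truth object (or dict) as sidecar JSON."""
    if hasattr(truth, "__dataclass_fields__"):
        d = asdict(truth)
    else:
        d = dict(truth)
    clean = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            if v.size <= 40_000:
                clean[k] = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            clean[k] = v.item()
        else:
            clean[k] = v
    Path(path).write_text(json.dumps(clean, indent=1))
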