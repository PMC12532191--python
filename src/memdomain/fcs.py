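"""Fluorescence correlation spectroscopy: correlation, model fitting, derived quantities.

The autocorrelation of the photon-count trace,

    G(tau) = <I(t) I(t+tau)> / <I(t)>^2,

is computed on a quasi-logarithmic (multi-tau style) lag grid and
fitted with either a one-component free-3D-diffusion model (used for
calibration with a reference dye of known diffusion coefficient) or a
two-component model mixing free 3D diffusion in the medium with free
2D diffusion in the membrane plane.  Both include a triplet-blinking
factor.  From the fits follow the observation-volume radii, the
membrane surface density of the probe, its molecular brightness
(counts per second per molecule) and its membrane diffusion
coefficient.

Model functions (tau in seconds):

    one component:  G = 1 + T(tau) * (1/N) * (1 + tau/tau_D)^-1 (1 + tau/(S^2 tau_D))^-1/2
    two component:  G = 1 + T(tau) * (1/N) * [ F1 (1 + tau/tau_D1)^-1 (1 + tau/(S^2 tau_D1))^-1/2
                                               + (1-F1) (1 + tau/tau_D2)^-1 ]
    triplet factor: T(tau) = 1 + F_T e^(-tau/tau_T) / (1 - F_T)

F1 is the mole fraction of the freely diffusing (3D) component, so
1 - F1 is the membrane-bound fraction; S = omega_z / omega_xy is the
structure parameter of the Gaussian observation volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "IntensityTrace",
    "AutocorrelationCurve",
    "FcsFitResult",
    "Calibration",
    "MembraneDensityResult",
    "multi_tau_lags",
    "autocorrelate",
    "g_one_component",
    "g_two_component",
    "OneComponentModel",
    "TwoComponentModel",
    "fit_one_component",
    "fit_two_component",
    "calibrate",
    "derive_membrane_quantities",
]

DEFAULT_TAU_D1 = 213e-6  # s, free probe in medium
DEFAULT_D_REF = 330.0    # um^2/s, reference dye


@dataclass
class IntensityTrace:
    """Uniformly binned photon-count (or intensity) trace."""

    bin_time: float
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_time <= 0:
            raise ValueError("bin_time must be > 0")

    @property
    def duration(self) -> float:
        return len(self.counts) * self.bin_time

    @property
    def mean_rate(self) -> float:
        """Mean intensity in counts/s."""
        return float(self.counts.mean()) / self.bin_time

    @classmethod
    def from_arrays(cls, times, counts):
        times = np.asarray(times, dtype=float)
        dt = np.diff(times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time base must be uniform")
        return cls(bin_time=float(dt[0]) if len(dt) else 1.0,
                   counts=np.asarray(counts, dtype=float))


@dataclass
class AutocorrelationCurve:
    """Segment-averaged G(tau) with per-lag spread."""

    lags: np.ndarray          # s, strictly increasing
    G: np.ndarray
    sd: np.ndarray            # per-lag SD across segments
    n_segments: int
    mean_intensity: float = np.nan   # counts/s over the accepted segments
    n_excluded: int = 0

    def plot(self, ax=None, fit: "FcsFitResult | None" = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.lags, self.G, "o", ms=3, label="G(tau)")
        if fit is not None:
            ax.semilogx(self.lags, fit.model_curve(self.lags), "-", label="fit")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("G")
        ax.legend()
        return ax


def multi_tau_lags(n_bins: int, channels_per_octave: int = 16,
                   max_lag_bins: int | None = None) -> np.ndarray:
    """Quasi-logarithmic lag grid in units of bins.

    The first octave holds ``channels_per_octave`` linearly spaced
    lags; each subsequent level appends half as many channels at twice
    the previous spacing (the multi-tau layout).
    """
    if max_lag_bins is None:
        max_lag_bins = n_bins // 8
    lags = list(range(1, channels_per_octave + 1))
    spacing = 2
    while lags[-1] + spacing <= max_lag_bins:
        for _ in range(channels_per_octave // 2):
            nxt = lags[-1] + spacing
            if nxt > max_lag_bins:
                break
            lags.append(nxt)
        spacing *= 2
    return np.array([l for l in lags if l < n_bins], dtype=int)


def _segment_bleached(seg: np.ndarray, n_blocks: int = 10,
                      drop_threshold: float = 0.2) -> bool:
    """Monotone intensity drop > threshold across the segment."""
    m = len(seg) // n_blocks
    if m == 0:
        return False
    blocks = seg[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    if blocks[0] <= 0:
        return False
    drop = (blocks[0] - blocks[-1]) / blocks[0]
    monotone = np.all(np.diff(blocks) <= 0.02 * blocks[0])
    return bool(monotone and drop > drop_threshold)


def autocorrelate(trace: IntensityTrace, segment_length: float = 20.0,
                  max_lag: float | None = None,
                  channels_per_octave: int = 16,
                  bleach_filter: bool = True) -> AutocorrelationCurve:
    """Segmented autocorrelation on a multi-tau lag grid.

    The trace is split into segments of ``segment_length`` seconds
    (default 20 s, matching series of consecutive 20 s measurements);
    for each segment G(tau) = <I(t)I(t+tau)> / <I>^2 is evaluated
    exactly at every grid lag, and the curve is the mean over segments
    with the per-lag SD recorded.  Segments with a monotone intensity
    drop > 20 % (photobleaching) or zero mean are excluded.
    """
    counts = trace.counts
    seg_bins = int(round(segment_length / trace.bin_time))
    n_seg = len(counts) // seg_bins
    if n_seg < 1:
        raise ValueError("trace shorter than one segment")
    if n_seg < 2:
        warnings.warn("fewer than 2 segments; SD will be zero")

    lag_bins = multi_tau_lags(
        seg_bins, channels_per_octave,
        None if max_lag is None else int(max_lag / trace.bin_time),
    )
    curves, means = [], []
    n_excluded = 0
    for s in range(n_seg):
        seg = counts[s * seg_bins:(s + 1) * seg_bins]
        mu = seg.mean()
        if mu == 0:
            warnings.warn(f"segment {s} has zero mean; excluded")
            n_excluded += 1
            continue
        if bleach_filter and _segment_bleached(seg):
            warnings.warn(f"segment {s} fails bleach filter; excluded")
            n_excluded += 1
            continue
        g = np.empty(len(lag_bins))
        for i, k in enumerate(lag_bins):
            g[i] = np.dot(seg[:-k], seg[k:]) / (len(seg) - k) / mu ** 2
        curves.append(g)
        means.append(mu)
    if not curves:
        raise ValueError("all segments excluded")
    curves = np.asarray(curves)
    return AutocorrelationCurve(
        lags=lag_bins * trace.bin_time,
        G=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(curves.shape[1]),
        n_segments=len(curves),
        mean_intensity=float(np.mean(means)) / trace.bin_time,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------


def _triplet(tau, f_t, tau_t):
    if f_t == 0:
        return np.ones_like(tau)
    return 1.0 + f_t * np.exp(-tau / tau_t) / (1.0 - f_t)


def g_one_component(tau, N, F_T, tau_T, tau_D, S):
    """One-component free 3D diffusion with triplet blinking."""
    tau = np.asarray(tau, dtype=float)
    diff = (1.0 + tau / tau_D) ** -1 * (1.0 + tau / (S ** 2 * tau_D)) ** -0.5
    return 1.0 + _triplet(tau, F_T, tau_T) / N * diff


def g_two_component(tau, N, F_T, tau_T, F1, tau_D1, tau_D2, S):
    """Two-component model: free 3D (fraction F1) + free 2D diffusion."""
    tau = np.asarray(tau, dtype=float)
    c1 = F1 * (1.0 + tau / tau_D1) ** -1 * (1.0 + tau / (S ** 2 * tau_D1)) ** -0.5
    c2 = (1.0 - F1) * (1.0 + tau / tau_D2) ** -1
    return 1.0 + _triplet(tau, F_T, tau_T) / N * (c1 + c2)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class FcsFitResult:
    """Fitted FCS parameters with uncertainties and fixed/free flags.

    ``params`` holds N, F_T, tau_T, S and either tau_D (one component)
    or F1, tau_D1, tau_D2 (two components); times in seconds.
    """

    model: str
    params: dict
    stderr: dict
    fixed: dict
    success: bool
    redchi: float
    at_bound: list = field(default_factory=list)
    ordering_violation: bool = False
    fit_report: str = ""
    mean_intensity: float = np.nan

    def __getitem__(self, key):
        return self.params[key]

    @property
    def flagged(self) -> bool:
        return (not self.success) or bool(self.at_bound)

    def model_curve(self, tau):
        p = self.params
        off = p.get("G_inf", 1.0) - 1.0
        if self.model == "one_component":
            return off + g_one_component(tau, p["N"], p["F_T"], p["tau_T"],
                                         p["tau_D"], p["S"])
        return off + g_two_component(tau, p["N"], p["F_T"], p["tau_T"], p["F1"],
                                     p["tau_D1"], p["tau_D2"], p["S"])

    def summary(self) -> str:
        rows = []
        for k, v in self.params.items():
            err = self.stderr.get(k)
            tag = "fixed" if self.fixed.get(k) else (
                f"+/- {err:.3g}" if err is not None and np.isfinite(err) else "")
            rows.append(f"  {k:>7s} = {v:12.6g}  {tag}")
        head = [f"FCS fit: {self.model}",
                f"  success: {self.success}  reduced chi2: {self.redchi:.4g}"]
        if self.at_bound:
            head.append(f"  parameters at bounds: {self.at_bound}")
        if self.ordering_violation:
            head.append("  warning: expected ordering tau_T < tau_D1 < tau_D2 violated")
        return "\n".join(head + rows)


def _weights(acc: AutocorrelationCurve, weighting: str):
    if weighting == "uniform":
        return np.ones_like(acc.G)
    sd = np.asarray(acc.sd, dtype=float)
    if not np.all(np.isfinite(sd)) or np.any(sd <= 0):
        return np.ones_like(acc.G)
    return 1.0 / sd


def _initial_values(acc: AutocorrelationCurve):
    g0 = acc.G[0]
    n0 = 1.0 / max(g0 - 1.0, 1e-6)
    half = 1.0 + (g0 - 1.0) / 2.0
    below = np.nonzero(acc.G <= half)[0]
    tau_d0 = acc.lags[below[0]] if len(below) else acc.lags[len(acc.lags) // 2]
    return n0, float(tau_d0)


class _FcsModelBase:
    """Shared weighted-least-squares machinery for the FCS models."""

    model_name = ""

    def __init__(self, acc: AutocorrelationCurve, weighting: str = "sd",
                 fit_range: tuple = (1e-6, 10.0), fit_offset: bool = True):
        self.acc = acc
        self.weighting = weighting
        self.fit_range = fit_range
        self.fit_offset = fit_offset

    def _mask(self):
        lo, hi = self.fit_range
        return (self.acc.lags >= lo) & (self.acc.lags <= hi)

    def _run(self, params, model_fn):
        m = self._mask()
        tau = self.acc.lags[m]
        g = self.acc.G[m]
        w = _weights(self.acc, self.weighting)[m]

        def resid(p):
            return (model_fn(tau, p) - g) * w

        out = lmfit.minimize(resid, params, method="leastsq")
        fitted = {k: float(out.params[k].value) for k in out.params}
        stderr = {k: (float(out.params[k].stderr)
                      if out.params[k].stderr is not None else np.nan)
                  for k in out.params}
        fixed = {k: not out.params[k].vary for k in out.params}
        at_bound = []
        for k, par in out.params.items():
            if not par.vary:
                continue
            span = (par.max - par.min) if np.isfinite(par.max - par.min) else None
            tol = 1e-8 * (span if span else max(abs(par.value), 1.0))
            if (np.isfinite(par.min) and abs(par.value - par.min) < tol and par.min != 0) \
               or (np.isfinite(par.max) and abs(par.value - par.max) < tol):
                at_bound.append(k)
        return out, fitted, stderr, fixed, at_bound


class OneComponentModel(_FcsModelBase):
    """Free 3D diffusion + triplet; used for calibration-dye curves."""

    model_name = "one_component"

    def fit(self, fix: dict | None = None) -> FcsFitResult:
        fix = fix or {}
        n0, tau_d0 = _initial_values(self.acc)
        params = lmfit.Parameters()
        params.add("N", value=n0, min=1e-8)
        params.add("F_T", value=0.1, min=0.0, max=0.9999)
        params.add("tau_T", value=5e-6, min=1e-9)
        params.add("tau_D", value=tau_d0, min=1e-9)
        params.add("S", value=5.0, min=1.0, max=20.0)
        params.add("G_inf", value=1.0, vary=self.fit_offset)
        for k, v in fix.items():
            params[k].set(value=v, vary=False)

        def model_fn(tau, p):
            return (p["G_inf"] - 1.0) + g_one_component(
                tau, p["N"], p["F_T"], p["tau_T"], p["tau_D"], p["S"])

        out, fitted, stderr, fixed, at_bound = self._run(params, model_fn)
        res = FcsFitResult(
            model=self.model_name, params=fitted, stderr=stderr, fixed=fixed,
            success=bool(out.success), redchi=float(out.redchi),
            at_bound=at_bound, fit_report=lmfit.fit_report(out),
            mean_intensity=self.acc.mean_intensity,
        )
        res.ordering_violation = not (fitted["tau_T"] < fitted["tau_D"])
        return res


class TwoComponentModel(_FcsModelBase):
    """3D (medium) + 2D (membrane) diffusion with triplet blinking.

    By convention the 3D diffusion time ``tau_D1`` is fixed to the
    value measured in the medium alone (default 213 us) and the
    structure parameter ``S`` is fixed from calibration.
    """

    model_name = "two_component"

    def __init__(self, acc, tau_d1: float = DEFAULT_TAU_D1, structure: float = 5.0,
                 weighting: str = "sd", fit_range: tuple = (1e-6, 10.0),
                 fit_offset: bool = True):
        super().__init__(acc, weighting=weighting, fit_range=fit_range,
                         fit_offset=fit_offset)
        if tau_d1 <= 0:
            raise ValueError("tau_d1 must be > 0")
        self.tau_d1 = tau_d1
        self.structure = structure

    def fit(self, fix: dict | None = None) -> FcsFitResult:
        fix = fix or {}
        n0, tau_d0 = _initial_values(self.acc)
        params = lmfit.Parameters()
        params.add("N", value=n0, min=1e-8)
        params.add("F_T", value=0.1, min=0.0, max=0.9999)
        params.add("tau_T", value=5e-6, min=1e-9)
        params.add("F1", value=0.3, min=0.0, max=1.0)
        params.add("tau_D1", value=self.tau_d1, vary=False)
        params.add("tau_D2", value=max(tau_d0, 2 * self.tau_d1), min=1e-9)
        params.add("S", value=self.structure, vary=False)
        params.add("G_inf", value=1.0, vary=self.fit_offset)
        for k, v in fix.items():
            params[k].set(value=v, vary=False)

        def model_fn(tau, p):
            return (p["G_inf"] - 1.0) + g_two_component(
                tau, p["N"], p["F_T"], p["tau_T"], p["F1"],
                p["tau_D1"], p["tau_D2"], p["S"])

        out, fitted, stderr, fixed, at_bound = self._run(params, model_fn)
        res = FcsFitResult(
            model=self.model_name, params=fitted, stderr=stderr, fixed=fixed,
            success=bool(out.success), redchi=float(out.redchi),
            at_bound=at_bound, fit_report=lmfit.fit_report(out),
            mean_intensity=self.acc.mean_intensity,
        )
        res.ordering_violation = not (
            fitted["tau_T"] < fitted["tau_D1"] < fitted["tau_D2"])
        return res


def fit_one_component(acc: AutocorrelationCurve, weighting: str = "sd",
                      **kwargs) -> FcsFitResult:
    """Convenience wrapper: ``OneComponentModel(acc).fit()``."""
    return OneComponentModel(acc, weighting=weighting).fit(**kwargs)


def fit_two_component(acc: AutocorrelationCurve, tau_d1: float = DEFAULT_TAU_D1,
                      structure: float = 5.0, weighting: str = "sd",
                      **kwargs) -> FcsFitResult:
    """Convenience wrapper: ``TwoComponentModel(acc, tau_d1, S).fit()``."""
    return TwoComponentModel(acc, tau_d1=tau_d1, structure=structure,
                             weighting=weighting).fit(**kwargs)


# ---------------------------------------------------------------------------
# calibration and derived quantities
# ---------------------------------------------------------------------------


@dataclass
class Calibration:
    """Observation-volume geometry from a reference-dye measurement.

    omega_xy = sqrt(4 D_ref tau_D_ref), omega_z = omega_xy * S.
    """

    omega_xy: float
    omega_z: float
    S: float
    D_ref: float
    tau_D_ref: float

    def __post_init__(self):
        if min(self.omega_xy, self.omega_z, self.S, self.D_ref, self.tau_D_ref) <= 0:
            raise ValueError("all calibration quantities must be > 0")
        if not np.isclose(self.omega_z, self.omega_xy * self.S, rtol=1e-9):
            raise ValueError("omega_z must equal omega_xy * S")


def calibrate(fit: FcsFitResult, D_ref: float = DEFAULT_D_REF) -> Calibration:
    """Observation-volume radii from a one-component reference-dye fit."""
    if D_ref <= 0:
        raise ValueError("D_ref must be > 0")
    tau_d = fit.params["tau_D"]
    omega_xy = np.sqrt(4.0 * D_ref * tau_d)
    S = fit.params["S"]
    return Calibration(omega_xy=omega_xy, omega_z=omega_xy * S, S=S,
                       D_ref=D_ref, tau_D_ref=tau_d)


@dataclass
class MembraneDensityResult:
    """Derived membrane quantities: density, brightness, diffusion."""

    rho: float          # molecules/um^2
    cpm: float          # counts/s/molecule
    D_membrane: float   # um^2/s

    def __post_init__(self):
        if min(self.rho, self.cpm, self.D_membrane) < 0:
            raise ValueError("derived quantities must be >= 0")


def derive_membrane_quantities(fit: FcsFitResult, cal: Calibration,
                               mean_intensity: float | None = None) -> MembraneDensityResult:
    """Membrane surface density, molecular brightness and diffusion.

    rho = (1 - F1) N / omega_xy^2 (molecules per um^2 of membrane in
    the beam waist), CPM = mean intensity / N, and
    D_membrane = omega_xy^2 / (4 tau_D2).
    """
    if mean_intensity is None:
        mean_intensity = fit.mean_intensity
    p = fit.params
    f2 = 1.0 - p["F1"]
    rho = f2 * p["N"] / cal.omega_xy ** 2
    cpm = mean_intensity / p["N"]
    d_mem = cal.omega_xy ** 2 / (4.0 * p["tau_D2"])
    return MembraneDensityResult(rho=rho, cpm=cpm, D_membrane=d_mem)
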