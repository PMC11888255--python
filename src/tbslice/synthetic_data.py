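"""Ground-truthed synthetic inputs for every analysis stage.

Four generators emulate the data modalities of the slice-culture
stimulation study, each returning both the synthetic input and the ground
truth needed to score the corresponding analysis module:

* GCaMP6f-like fluorescence traces: Poisson spiking convolved with a
  difference-of-exponentials transient kernel, on a baseline with slow
  sinusoidal drift and Gaussian noise (plus a renderer that turns traces
  into a labeled movie for the extraction stage).
* Spine-size trajectories over the 11-point imaging schedule: mean-reverting
  log-sizes with distance-dependent cross-spine innovation correlations and
  an optional post-stimulation enlargement of the smallest size tercile.
* mEPSC current traces: Poisson-timed negative biexponential events with
  log-normal amplitudes in Gaussian noise.
* c-Fos-like image stacks: non-overlapping elliptical blobs with
  controllable size and eccentricity over a noisy background.

All generators are deterministic given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cfos_counting
from .calcium_pipeline import TraceSet
from .mepsc_analysis import biexp_kernel
from .protocol import DEFAULT_SCHEDULE, ImagingSchedule
from .spine_dynamics import SpineTrajectorySet


def _require_positive(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v!r}")


# ---------------------------------------------------------------------------
# calcium traces

@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the GCaMP6f-like trace generator.

    Rates in Hz, times in seconds; ``transient_amplitude``, ``drift_amplitude``
    and ``noise_sd`` are fractions of ``baseline`` (so ``transient_amplitude``
    is directly the peak dF/F0 of an isolated transient).
    """

    n_units: int = 20
    duration: float = 300.0
    frame_rate: float = 10.0
    spike_rate: float = 1.0 / 60.0     # 1 spike/min, slow network activity
    kernel_rise: float = 0.1
    kernel_decay: float = 0.6
    transient_amplitude: float = 0.25
    drift_amplitude: float = 0.05
    drift_period: float = 120.0
    noise_sd: float = 0.05
    baseline: float = 100.0
    group_rate_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive(self, ["n_units", "duration", "frame_rate",
                                 "kernel_rise", "kernel_decay",
                                 "transient_amplitude", "drift_period",
                                 "baseline", "group_rate_multiplier"])
        if self.spike_rate < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("spike_rate, noise_sd and drift_amplitude must be >= 0")
        if self.frame_rate * self.duration < 2:
            raise ValueError("need at least 2 frames")
        if not self.kernel_rise < self.kernel_decay:
            raise ValueError("kernel_rise must be < kernel_decay")


def calcium_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient for t >= 0 (seconds)."""
    return biexp_kernel(np.asarray(t, dtype=float) * 1e3, rise * 1e3, decay * 1e3)


def simulate_calcium_traceset(p: CalciumSimParams,
                              forced_spikes: list | None = None,
                              group: str = "control"
                              ) -> tuple[TraceSet, list[np.ndarray]]:
    """Simulate fluorescence traces; returns (TraceSet, true spike times).

    Spikes are homogeneous Poisson per unit (rate multiplied by
    ``group_rate_multiplier`` for the "stimulated" group); each spike adds a
    difference-of-exponentials transient peaking at
    ``transient_amplitude * baseline``.  ``forced_spikes`` (list of arrays,
    one per unit) overrides the Poisson draw for deterministic fixtures.
    """
    rng = np.random.default_rng(p.seed)
    n_frames = int(round(p.duration * p.frame_rate))
    t = np.arange(n_frames) / p.frame_rate
    rate = p.spike_rate * (p.group_rate_multiplier if group == "stimulated" else 1.0)
    kernel_len = t[t <= 10 * p.kernel_decay]
    kern = calcium_kernel(kernel_len, p.kernel_rise, p.kernel_decay)
    traces = np.empty((p.n_units, n_frames))
    truth: list[np.ndarray] = []
    for u in range(p.n_units):
        if forced_spikes is not None:
            spikes = np.asarray(forced_spikes[u], dtype=float)
        else:
            n_spk = rng.poisson(rate * p.duration)
            spikes = np.sort(rng.uniform(0, p.duration, size=n_spk))
        phase = rng.uniform(0, 2 * np.pi)
        drift = p.drift_amplitude * np.sin(2 * np.pi * t / p.drift_period + phase)
        signal = np.zeros(n_frames)
        for s in spikes:
            i0 = int(np.ceil((s - 1e-12) * p.frame_rate))
            if i0 >= n_frames:
                continue
            seg = kern.size if i0 + kern.size <= n_frames else n_frames - i0
            # kernel evaluated at frame times relative to the spike
            tk = t[i0:i0 + seg] - s
            signal[i0:i0 + seg] += calcium_kernel(tk, p.kernel_rise, p.kernel_decay)
        noise = rng.normal(0, p.noise_sd * p.baseline, size=n_frames) \
            if p.noise_sd > 0 else 0.0
        traces[u] = (p.baseline * (1 + drift)
                     + p.transient_amplitude * p.baseline * signal + noise)
        truth.append(spikes)
    ts = TraceSet(traces, p.frame_rate,
                  meta={"group": group, "spike_rate": rate})
    return ts, truth


def render_traceset_movie(ts: TraceSet, patch: int = 4, pad: int = 2
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Render a TraceSet to a (frames, label mask) movie pair.

    Each unit occupies a ``patch x patch`` square on a zero background; the
    pixel value of a unit's patch equals its trace value in every frame, so
    mean-intensity extraction recovers the traces exactly (up to dtype).
    """
    n = ts.n_units
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    H = rows * (patch + pad) + pad
    W = cols * (patch + pad) + pad
    mask = np.zeros((H, W), dtype=np.int32)
    frames = np.zeros((ts.n_frames, H, W), dtype=float)
    for u in range(n):
        r, c = divmod(u, cols)
        y = pad + r * (patch + pad)
        x = pad + c * (patch + pad)
        mask[y:y + patch, x:x + patch] = u + 1
        frames[:, y:y + patch, x:x + patch] = ts.traces[u][:, None, None]
    return frames, mask


# ---------------------------------------------------------------------------
# spine trajectories

@dataclass(frozen=True)
class SpineSimParams:
    """Parameters of the spine-trajectory generator.

    Log-sizes revert toward ``log_size_mean`` at ``reversion_rate`` per day
    with per-scan-step Gaussian innovations of SD ``fluctuation_sd`` whose
    cross-spine correlation decays with ID distance d as exp(-d/corr_length),
    rescaled so adjacent spines correlate at ``spatial_corr_near`` and the
    most distant pair at ``spatial_corr_far``.  In the stimulated condition
    the smallest day-4 size tercile is enlarged by ``stim_effect_small``
    (fractional) at all post-stimulation scans.
    """

    n_segments: int = 20
    spines_per_segment: int = 20
    schedule: ImagingSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)
    log_size_mean: float = 0.0
    log_size_sd: float = 0.4
    reversion_rate: float = 0.3      # per day
    fluctuation_sd: float = 0.15     # per scan step
    spatial_corr_near: float = 0.5
    spatial_corr_far: float = -0.2
    corr_length: float = 4.0
    stim_effect_small: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive(self, ["n_segments", "spines_per_segment",
                                 "log_size_sd", "corr_length"])
        for name in ("spatial_corr_near", "spatial_corr_far"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")
        if self.reversion_rate < 0 or self.fluctuation_sd < 0:
            raise ValueError("reversion_rate and fluctuation_sd must be >= 0")
        # PSD check of the innovation correlation matrix (construction-time)
        C = spine_innovation_correlation(self.spines_per_segment,
                                         self.spatial_corr_near,
                                         self.spatial_corr_far,
                                         self.corr_length)
        if np.linalg.eigvalsh(C).min() < -1e-9:
            raise ValueError("spine innovation covariance is not positive "
                             "semi-definite for these correlation parameters")


def spine_innovation_correlation(n: int, near: float, far: float,
                                 length: float) -> np.ndarray:
    """Distance-dependent innovation correlation matrix.

    exp(-d/length) rescaled affinely so C(1) = near and C(n-1) = far;
    unit diagonal.
    """
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    if n == 1:
        return np.ones((1, 1))
    g = np.exp(-d / length)
    g1, gm = np.exp(-1.0 / length), np.exp(-(n - 1.0) / length)
    if n == 2 or np.isclose(g1, gm):
        C = np.full((n, n), near)
    else:
        C = far + (near - far) * (g - gm) / (g1 - gm)
    np.fill_diagonal(C, 1.0)
    return C


def simulate_spine_trajectory_set(p: SpineSimParams, condition: str = "control"
                                  ) -> tuple[SpineTrajectorySet, pd.DataFrame]:
    """Simulate spine-size trajectories; returns (set, truth table).

    Truth rows: (segment_id, spine_id, tercile, condition, baseline_size)
    with terciles assigned within segment by day-4 size (0 = smallest).
    """
    if condition not in ("control", "stimulated"):
        raise ValueError(f"condition must be control|stimulated, got {condition!r}")
    rng = np.random.default_rng(p.seed)
    sched = p.schedule
    times_d = np.asarray(sched.times_h) / 24.0
    base_idx = sched.labels.index(sched.baseline_label)
    post = set(sched.post_stim_labels)
    C = spine_innovation_correlation(p.spines_per_segment, p.spatial_corr_near,
                                     p.spatial_corr_far, p.corr_length)
    # symmetric PSD square root for correlated innovations
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0, None))
    rows, truth_rows = [], []
    stim_offset = np.log1p(p.stim_effect_small)
    for seg in range(p.n_segments):
        seg_id = f"{condition[:4]}_seg{seg:03d}"
        x = rng.normal(p.log_size_mean, p.log_size_sd, size=p.spines_per_segment)
        logsizes = np.empty((len(sched.labels), p.spines_per_segment))
        logsizes[0] = x
        for ti in range(1, len(sched.labels)):
            dt = times_d[ti] - times_d[ti - 1]
            eps = L @ rng.standard_normal(p.spines_per_segment) * p.fluctuation_sd
            x = x + p.reversion_rate * dt * (p.log_size_mean - x) + eps
            logsizes[ti] = x
        base_sizes = np.exp(logsizes[base_idx])
        terciles = np.searchsorted(np.quantile(base_sizes, [1 / 3, 2 / 3]),
                                   base_sizes, side="left")
        small = terciles == 0
        for ti, lab in enumerate(sched.labels):
            vals = logsizes[ti].copy()
            if condition == "stimulated" and lab in post:
                vals[small] += stim_offset
            for sp in range(p.spines_per_segment):
                rows.append((seg_id, sp, lab, float(np.exp(vals[sp]))))
        for sp in range(p.spines_per_segment):
            truth_rows.append((seg_id, sp, int(terciles[sp]), condition,
                               float(base_sizes[sp])))
    sizes = pd.DataFrame(rows, columns=["segment_id", "spine_id",
                                        "time_label", "size_au"])
    # per-segment density series: stable around ~1.2 spines/um with jitter
    dens_rows = []
    seg_ids = sizes["segment_id"].unique()
    for seg_id in seg_ids:
        dens0 = rng.normal(1.2, 0.15)
        for lab in sched.labels:
            dens_rows.append((seg_id, lab,
                              float(max(dens0 * np.exp(rng.normal(0, 0.03)), 0.1))))
    density = pd.DataFrame(dens_rows,
                           columns=["segment_id", "time_label", "spines_per_um"])
    condition_map = {s: condition for s in seg_ids}
    truth = pd.DataFrame(truth_rows, columns=["segment_id", "spine_id",
                                              "tercile", "condition",
                                              "baseline_size"])
    return SpineTrajectorySet(sizes, density, condition_map, sched), truth


# ---------------------------------------------------------------------------
# mEPSC traces

@dataclass(frozen=True)
class MepscSimParams:
    """Parameters of the mEPSC current-trace generator.

    Events are Poisson at ``event_rate`` (Hz) with log-normal amplitudes
    (log-pA parameters); each event is a negative biexponential deflection
    (taus in ms); baseline noise is Gaussian with SD ``noise_sd`` pA.
    """

    duration: float = 120.0
    sampling_rate: float = 10000.0
    event_rate: float = 1.0
    amp_log_mean: float = float(np.log(15.0))
    amp_log_sd: float = 0.35
    rise_tau: float = 0.5
    decay_tau: float = 4.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive(self, ["duration", "sampling_rate",
                                 "rise_tau", "decay_tau"])
        if self.event_rate < 0 or self.noise_sd < 0 or self.amp_log_sd < 0:
            raise ValueError("event_rate, noise_sd and amp_log_sd must be >= 0")
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be < decay_tau")


def simulate_mepsc_trace(p: MepscSimParams,
                         forced_events: list[tuple[float, float]] | None = None
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a current trace (pA); returns (samples, truth table).

    Truth rows: (time_s, amplitude_pA, area_pA_ms) with the analytic kernel
    area A*(decay-rise)/peak_factor.  ``forced_events`` as (time, amplitude)
    pairs overrides the Poisson draw.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.sampling_rate))
    t_ms = np.arange(int(10 * p.decay_tau * p.sampling_rate / 1000.0)) \
        / p.sampling_rate * 1000.0
    kern = -biexp_kernel(t_ms, p.rise_tau, p.decay_tau)
    t_peak = (p.rise_tau * p.decay_tau / (p.decay_tau - p.rise_tau)
              * np.log(p.decay_tau / p.rise_tau))
    peak_factor = np.exp(-t_peak / p.decay_tau) - np.exp(-t_peak / p.rise_tau)
    kernel_area_per_pa = (p.decay_tau - p.rise_tau) / peak_factor  # ms per pA

    if forced_events is not None:
        times = np.array([e[0] for e in forced_events], dtype=float)
        amps = np.array([e[1] for e in forced_events], dtype=float)
    else:
        n_ev = rng.poisson(p.event_rate * p.duration)
        times = np.sort(rng.uniform(0, p.duration, size=n_ev))
        amps = rng.lognormal(p.amp_log_mean, p.amp_log_sd, size=times.size)
    trace = rng.normal(0, p.noise_sd, size=n) if p.noise_sd > 0 else np.zeros(n)
    for t0, a in zip(times, amps):
        i0 = int(np.ceil(t0 * p.sampling_rate))
        if i0 >= n:
            continue
        seg = min(kern.size, n - i0)
        trace[i0:i0 + seg] += a * kern[:seg]
    truth = pd.DataFrame({
        "time_s": times,
        "amplitude_pA": amps,
        "area_pA_ms": amps * kernel_area_per_pa,
    })
    return trace, truth


# ---------------------------------------------------------------------------
# c-Fos image stacks

@dataclass(frozen=True)
class CfosImageParams:
    """Parameters of the c-Fos-like blob-image generator.

    Cells are non-overlapping ellipses of equivalent radius drawn from
    ``radius_range`` and eccentricity from ``eccentricity_range``, rendered
    at ``intensity`` over a background of Gaussian noise across ``n_planes``
    z-planes (brightest at the stack midpoint).
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 30
    radius_range: tuple[float, float] = (4.0, 9.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    intensity: float = 200.0
    background_noise_sd: float = 0.0
    n_planes: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive(self, ["intensity", "n_planes"])
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        if not 0 < self.radius_range[0] <= self.radius_range[1]:
            raise ValueError("radius_range must be positive and ordered")
        if not 0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1:
            raise ValueError("eccentricity_range must lie in [0, 1)")


class PlacementError(RuntimeError):
    """Raised when overlap-free blob placement fails."""


def _render_ellipse(shape, cy, cx, a, b, theta) -> np.ndarray:
    """Boolean mask of an ellipse (semi-axes a >= b, rotation theta)."""
    from skimage.draw import ellipse
    rr, cc = ellipse(cy, cx, a, b, shape=shape, rotation=theta)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def simulate_cfos_stack(p: CfosImageParams,
                        size_range=cfos_counting.DEFAULT_SIZE_RANGE,
                        circularity_range=cfos_counting.DEFAULT_CIRCULARITY_RANGE,
                        max_tries: int = 10000, blob_specs=None):
    """Simulate a (c-Fos stack, DAPI stack) pair with per-blob ground truth.

    Returns ``(cfos_stack, dapi_stack, truth)`` where ``truth`` is a dict
    with the per-blob measurement table and ``n_qualifying``: the number of
    blobs whose rendered area and capped circularity fall inside the
    counting module's filter ranges (measured independently per blob on its
    isolated rendering).  ``blob_specs`` (list of (cy, cx, a, b, theta))
    overrides random placement for deterministic fixtures.
    """
    rng = np.random.default_rng(p.seed)
    H, W = p.image_shape
    specs = []
    if blob_specs is not None:
        specs = list(blob_specs)
    else:
        margin = p.radius_range[1] + 2
        centers: list[tuple[float, float, float]] = []
        tries = 0
        while len(specs) < p.n_cells:
            tries += 1
            if tries > max_tries:
                raise PlacementError(
                    f"placed only {len(specs)}/{p.n_cells} non-overlapping "
                    f"cells after {max_tries} tries")
            r = rng.uniform(*p.radius_range)
            e = rng.uniform(*p.eccentricity_range)
            # equivalent-area ellipse: a*b = r^2, b/a = sqrt(1-e^2)
            ratio = np.sqrt(1 - e ** 2)
            a = r / np.sqrt(ratio)
            b = r * np.sqrt(ratio)
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            if any(np.hypot(cy - y0, cx - x0) < a + r0 + 2
                   for y0, x0, r0 in centers):
                continue
            theta = rng.uniform(0, np.pi)
            centers.append((cy, cx, a))
            specs.append((cy, cx, a, b, theta))

    union = np.zeros((H, W), dtype=float)
    blob_rows = []
    for i, (cy, cx, a, b, theta) in enumerate(specs):
        m = _render_ellipse((H, W), cy, cx, a, b, theta)
        union[m] = p.intensity
        meas = cfos_counting.measure_blobs(m)
        if len(meas) != 1:
            area, circ = 0.0, np.inf
        else:
            area = float(meas["area"].iloc[0])
            circ = float(meas["circularity"].iloc[0])
        blob_rows.append({
            "blob": i, "area": area, "circularity": circ,
            "qualifies": cfos_counting.passes_filters(
                area, circ, size_range, circularity_range),
        })
    blobs = pd.DataFrame(blob_rows,
                         columns=["blob", "area", "circularity", "qualifies"])
    # z-profile: blobs brightest at the stack midpoint
    zc = (p.n_planes - 1) / 2.0
    zw = max(p.n_planes / 2.0, 1.0)
    cfos = np.empty((p.n_planes, H, W), dtype=float)
    for z in range(p.n_planes):
        wz = np.exp(-((z - zc) / zw) ** 2)
        plane = union * wz
        if p.background_noise_sd > 0:
            plane = plane + rng.normal(0, p.background_noise_sd, size=(H, W))
        cfos[z] = np.clip(plane, 0, None)
    dapi = np.clip(cfos * 0.6 + (rng.normal(0, p.background_noise_sd, cfos.shape)
                                 if p.background_noise_sd > 0 else 0.0), 0, None)
    truth = {"n_qualifying": int(blobs["qualifies"].sum()) if len(blobs) else 0,
             "blobs": blobs}
    return cfos, dapi, truth
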