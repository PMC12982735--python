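"""Synthetic DNA-PAINT binding-kinetics and localization data.

Specific binding is simulated as a continuous-time alternating renewal
process per docking strand: exponential dark intervals (mean ``mean_dark_s``)
alternating with exponential bright intervals (mean ``mean_bright_s``),
optionally truncated by an exponential strand-depletion time (photodamage)
and optionally fragmented by photophysical blinking of the dye within a
binding event. A cluster's trace is the union of its strands' on-intervals;
a camera frame is active when its exposure window overlaps any on-interval.

Non-specific background has no physical generative model here; it is an
explicit synthetic stand-in (geometric apparent-event counts, lognormal
inter-event times) chosen to mimic the empirical character of negative
controls: most clusters show very few events, and the event-rich ones are
strongly non-exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import exptest, kinetics
from .datatypes import LocalizationTable, RegionMask


@dataclass
class KineticsConfig:
    """Specific-binding simulation parameters (times in seconds)."""

    n_clusters: int = 5000
    strands_per_cluster: int = 10
    mean_bright_s: float = 1.0
    mean_dark_s: float = 1000.0
    acquisition_s: float = 10_000.0
    frame_duration_s: float = 0.2
    strand_lifetime_s: float = math.inf  # inf = no depletion
    blink_on_s: Optional[float] = None  # photophysical blinking disabled
    blink_off_s: Optional[float] = None
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.acquisition_s / self.frame_duration_s))


@dataclass
class NoiseConfig:
    """Synthetic non-specific cluster parameters."""

    n_clusters: int = 1000
    mean_events: float = 3.0  # geometric, support >= 1
    sigma_log: float = 1.5  # lognormal inter-event log-sd
    median_interval_s: float = 60.0  # lognormal scale (test is scale-invariant)
    spot_sigma_nm: float = 10.0
    precision_nm: float = 10.0
    frame_duration_s: float = 0.2
    acquisition_s: float = 10_000.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.acquisition_s / self.frame_duration_s))


@dataclass
class GroundTruth:
    """Per-localization and per-cluster truth for simulated tables."""

    loc_cluster_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    loc_mark_id: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    cluster_class: dict[int, str] = field(default_factory=dict)
    strand_depletion_s: dict[int, np.ndarray] = field(default_factory=dict)


def _strand_on_intervals(
    rng: np.random.Generator,
    mean_dark_s: float,
    mean_bright_s: float,
    t_end: float,
) -> list[tuple[float, float]]:
    """Alternating renewal on-intervals, truncated at t_end."""
    out: list[tuple[float, float]] = []
    t = 0.0
    block = max(16, int(2 * t_end / (mean_dark_s + mean_bright_s)) + 8)
    while t < t_end:
        darks = rng.exponential(mean_dark_s, block)
        brights = rng.exponential(mean_bright_s, block)
        for d, b in zip(darks, brights):
            t += d
            if t >= t_end:
                t = t_end
                break
            out.append((t, min(t + b, t_end)))
            t += b
            if t >= t_end:
                t = t_end
                break
    return out


def _blink_fragments(
    rng: np.random.Generator,
    interval: tuple[float, float],
    blink_on_s: float,
    blink_off_s: float,
) -> list[tuple[float, float]]:
    """Chop one bright interval into photophysical on-segments."""
    a, b = interval
    out = []
    t = a
    while t < b:
        on = rng.exponential(blink_on_s)
        out.append((t, min(t + on, b)))
        t += on + rng.exponential(blink_off_s)
    return out


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _intervals_to_frames(
    intervals: list[tuple[float, float]], frame_duration_s: float, n_frames: int
) -> np.ndarray:
    """Frames whose exposure window overlaps any on-interval."""
    chunks = []
    for a, b in intervals:
        if b <= a:
            continue
        f0 = int(a // frame_duration_s)
        f1 = int(np.ceil(b / frame_duration_s)) - 1
        f0 = max(f0, 0)
        f1 = min(max(f1, f0), n_frames - 1)
        if f1 >= f0:
            chunks.append(np.arange(f0, f1 + 1, dtype=np.int64))
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def simulate_cluster_trace(
    config: KineticsConfig,
    cluster_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Active frames of one simulated cluster plus per-strand depletion times.

    Each strand runs independently; depletion truncates a strand mid-event
    (photodamage destroys the docking strand regardless of binding state).
    Overlapping bright intervals from different strands merge into one blink.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, cluster_index])
        )
    intervals: list[tuple[float, float]] = []
    depletion = np.full(config.strands_per_cluster, np.inf)
    for s in range(config.strands_per_cluster):
        if math.isfinite(config.strand_lifetime_s):
            depletion[s] = rng.exponential(config.strand_lifetime_s)
        t_end = min(config.acquisition_s, depletion[s])
        strand = _strand_on_intervals(
            rng, config.mean_dark_s, config.mean_bright_s, t_end
        )
        if config.blink_on_s is not None and config.blink_off_s is not None:
            frags: list[tuple[float, float]] = []
            for iv in strand:
                frags.extend(
                    _blink_fragments(rng, iv, config.blink_on_s, config.blink_off_s)
                )
            strand = frags
        intervals.extend(strand)
    frames = _intervals_to_frames(
        _merge_intervals(intervals), config.frame_duration_s, config.n_frames
    )
    return frames, depletion


def depletion_experiment(
    scenario: str,
    seed: int = 0,
    n_clusters: int = 5000,
    alpha: float = 0.01,
    max_gap_s: float = 1.0,
    method: str = "bootstrap",
    B: int = 10_000,
    boundary: str = "both",
) -> float:
    """Fraction of simulated clusters rejected under docking-strand depletion.

    "typical": strand lifetime 80,000 s (~10% of strands depleted over the
    10,000 s acquisition); "extreme": lifetime 10,000 s (~60% depleted);
    "none": no depletion (pure null, rejection ~ alpha). 5000 clusters of 10
    strands, bright 1 s, per-strand dark 1000 s, 5 Hz frames, 1 s blink
    linking, Anderson-Darling test at ``alpha``.

    The dark-time sample of each cluster includes the two acquisition-edge
    intervals (``boundary="both"``): depletion manifests as a systematically
    long trailing dark interval, and without the edge intervals the test is
    roughly half as sensitive to the extreme depletion scenario.
    """
    lifetimes = {"typical": 80_000.0, "extreme": 10_000.0, "none": math.inf}
    if scenario not in lifetimes:
        raise ValueError(f"unknown scenario {scenario!r}")
    cfg = KineticsConfig(
        n_clusters=n_clusters, strand_lifetime_s=lifetimes[scenario], seed=seed
    )
    gap = kinetics.max_gap_frames_from_seconds(max_gap_s, cfg.frame_duration_s)
    a2_list, n_list = [], []
    n_untestable = 0
    for k in range(cfg.n_clusters):
        frames, _ = simulate_cluster_trace(cfg, k)
        train = kinetics.link_events(frames, gap, frame_duration_s=cfg.frame_duration_s)
        if train.n_events < 5:  # fewer than 4 dark times: not testable
            n_untestable += 1
            continue
        dt = kinetics.dark_times(train, boundary=boundary, n_frames=cfg.n_frames)
        a2_list.append(exptest.ad_statistic(dt))
        n_list.append(len(dt))
    p = exptest.ad_pvalues(
        np.array(a2_list), np.array(n_list), method=method, B=B, seed=seed
    )
    return float(np.sum(p < alpha) / cfg.n_clusters)


def retention_experiment(
    seed: int = 0,
    n_clusters: int = 5000,
    min_events: int = 8,
    required_events: int = 12,
    alpha: float = 0.01,
    method: str = "bootstrap",
    B: int = 10_000,
) -> float:
    """Fraction of specific clusters (>= required_events events) retained.

    Pure exponential kinetics (no depletion, no blinking) through the full
    trace pipeline and classifier; measures the filter's false-rejection
    cost on real signal, which is ~alpha by construction of the test.
    """
    cfg = KineticsConfig(n_clusters=n_clusters, seed=seed)
    gap = kinetics.max_gap_frames_from_seconds(1.0, cfg.frame_duration_s)
    a2_list, n_list, nev = [], [], []
    for k in range(cfg.n_clusters):
        frames, _ = simulate_cluster_trace(cfg, k)
        train = kinetics.link_events(frames, gap, frame_duration_s=cfg.frame_duration_s)
        if train.n_events < required_events:
            continue
        dt = kinetics.dark_times(train)
        a2_list.append(exptest.ad_statistic(dt))
        n_list.append(len(dt))
        nev.append(train.n_events)
    p = exptest.ad_pvalues(
        np.array(a2_list), np.array(n_list), method=method, B=B, seed=seed
    )
    specific = (np.array(nev) >= min_events) & ~(p < alpha)
    return float(specific.mean())


def _noise_cluster_draws(
    rng: np.random.Generator, cfg: NoiseConfig, n: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Event counts (geometric, mean cfg.mean_events) and inter-event times."""
    counts = rng.geometric(1.0 / cfg.mean_events, size=n)
    mu = math.log(cfg.median_interval_s)
    times = [
        rng.lognormal(mean=mu, sigma=cfg.sigma_log, size=c - 1) if c > 1
        else np.empty(0)
        for c in counts
    ]
    return counts, times


def noise_rejection_experiment(
    seed: int = 0,
    n_clusters: int = 10_000,
    mean_events: float = 3.0,
    sigma_log: float = 1.5,
    min_events: int = 8,
    alpha: float = 0.01,
    method: str = "bootstrap",
    B: int = 10_000,
) -> float:
    """Fraction of synthetic noise clusters rejected by threshold + AD test.

    Event counts are geometric (mean ``mean_events``, support >= 1) and
    inter-event times lognormal with log-sd ``sigma_log`` (scale arbitrary:
    the test is scale-invariant). Clusters below ``min_events`` are rejected
    outright; the rest are tested at level ``alpha``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cfg = NoiseConfig(n_clusters=n_clusters, mean_events=mean_events,
                      sigma_log=sigma_log, seed=seed)
    counts, times = _noise_cluster_draws(rng, cfg, n_clusters)
    rejected = counts < min_events
    test_idx = np.flatnonzero(~rejected)
    a2 = np.array([exptest.ad_statistic(times[i]) for i in test_idx])
    ns = np.array([times[i].size for i in test_idx])
    if test_idx.size:
        p = exptest.ad_pvalues(a2, ns, method=method, B=B, seed=seed)
        rejected[test_idx] |= p < alpha
    return float(rejected.mean())


def simulate_nanorulers(
    n_rulers: int,
    kinetics_config: Optional[KineticsConfig] = None,
    mark_spacing_nm: float = 80.0,
    marks: int = 3,
    sigma_loc_nm: float = 10.0,
    field_pitch_nm: float = 600.0,
    seed: int = 0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Synthetic nanoruler field: linear arrays of binding-site marks.

    Rulers sit on a coarse grid (pitch ``field_pitch_nm``, jittered) with
    random in-plane orientation so they never overlap; each mark runs an
    independent binding-kinetics trace and every active frame emits one
    localization at the mark centre plus isotropic Gaussian noise of
    ``sigma_loc_nm`` (which is also the stored precision).
    """
    if kinetics_config is None:
        # ~40 events per mark: single strand, 4000 s at 5 Hz
        kinetics_config = KineticsConfig(
            n_clusters=n_rulers, strands_per_cluster=1, mean_bright_s=0.5,
            mean_dark_s=100.0, acquisition_s=4000.0, seed=seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    side = int(np.ceil(np.sqrt(n_rulers)))
    xs, ys, fr, cl, mk = [], [], [], [], []
    truth = GroundTruth()
    for r in range(n_rulers):
        gx, gy = r % side, r // side
        cx = (gx + 0.5) * field_pitch_nm + rng.uniform(-50, 50)
        cy = (gy + 0.5) * field_pitch_nm + rng.uniform(-50, 50)
        theta = rng.uniform(0, np.pi)
        ux, uy = np.cos(theta), np.sin(theta)
        for m in range(marks):
            off = (m - (marks - 1) / 2.0) * mark_spacing_nm
            mx, my = cx + off * ux, cy + off * uy
            frames, _ = simulate_cluster_trace(
                kinetics_config, cluster_index=r * marks + m, rng=rng
            )
            k = frames.size
            xs.append(mx + rng.normal(0, sigma_loc_nm, k))
            ys.append(my + rng.normal(0, sigma_loc_nm, k))
            fr.append(frames)
            cl.append(np.full(k, r, dtype=np.int64))
            mk.append(np.full(k, m, dtype=np.int64))
        truth.cluster_class[r] = "specific"
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    f = np.concatenate(fr) if fr else np.empty(0, np.int64)
    table = LocalizationTable(
        x_nm=x, y_nm=y, frame=f,
        precision_nm=np.full(x.size, sigma_loc_nm),
        frame_duration_s=kinetics_config.frame_duration_s,
        n_frames=kinetics_config.n_frames,
    ).validate()
    truth.loc_cluster_id = np.concatenate(cl) if cl else np.empty(0, np.int64)
    truth.loc_mark_id = np.concatenate(mk) if mk else np.empty(0, np.int64)
    return table, truth


def simulate_noise_clusters(
    config: NoiseConfig,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    extent_nm: tuple[float, float] = (10_000.0, 10_000.0),
    rng: Optional[np.random.Generator] = None,
    first_cluster_id: int = 0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Field of synthetic non-specific clusters (single-frame blinks).

    Events are spread over the acquisition with lognormal inter-event times
    rescaled to fit when necessary; each event emits one localization at the
    cluster centre plus Gaussian spread ``spot_sigma_nm``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    counts, times = _noise_cluster_draws(rng, config, config.n_clusters)
    xs, ys, fr, cl = [], [], [], []
    truth = GroundTruth()
    for i in range(config.n_clusters):
        cid = first_cluster_id + i
        t0 = rng.uniform(0, config.acquisition_s * 0.1)
        t = t0 + np.concatenate([[0.0], np.cumsum(times[i])])
        span = t[-1] - t[0]
        if span > 0.9 * config.acquisition_s:
            t = t0 + (t - t0) * (0.9 * config.acquisition_s / span)
        frames = np.unique((t / config.frame_duration_s).astype(np.int64))
        frames = frames[frames < config.n_frames]
        k = frames.size
        cx = origin_nm[0] + rng.uniform(0, extent_nm[0])
        cy = origin_nm[1] + rng.uniform(0, extent_nm[1])
        xs.append(cx + rng.normal(0, config.spot_sigma_nm, k))
        ys.append(cy + rng.normal(0, config.spot_sigma_nm, k))
        fr.append(frames)
        cl.append(np.full(k, cid, dtype=np.int64))
        truth.cluster_class[cid] = "noise"
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    f = np.concatenate(fr) if fr else np.empty(0, np.int64)
    table = LocalizationTable(
        x_nm=x, y_nm=y, frame=f,
        precision_nm=np.full(x.size, config.precision_nm),
        frame_duration_s=config.frame_duration_s,
        n_frames=config.n_frames,
    ).validate()
    truth.loc_cluster_id = np.concatenate(cl) if cl else np.empty(0, np.int64)
    truth.loc_mark_id = np.full(x.size, -1, dtype=np.int64)
    return table, truth


def simulate_scene(
    n_specific: int = 200,
    n_noise: int = 800,
    specific_config: Optional[KineticsConfig] = None,
    noise_config: Optional[NoiseConfig] = None,
    pitch_nm: float = 400.0,
    sigma_loc_nm: float = 10.0,
    seed: int = 0,
) -> tuple[LocalizationTable, GroundTruth, RegionMask, RegionMask]:
    """Two-zone field: noise everywhere, specific clusters only on the right.

    Mimics a mosaic sample with a background-dominated region next to a
    signal region. Returns the merged table, ground truth and binary masks
    for the signal (right) and background (left) halves.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    if specific_config is None:
        specific_config = KineticsConfig(
            n_clusters=n_specific, strands_per_cluster=2, mean_bright_s=0.5,
            mean_dark_s=250.0, acquisition_s=4000.0, seed=seed,
        )
    if noise_config is None:
        noise_config = NoiseConfig(
            n_clusters=n_noise, acquisition_s=specific_config.acquisition_s,
            frame_duration_s=specific_config.frame_duration_s, seed=seed,
        )
    # field geometry: left half noise-only, right half mixed
    n_cells = n_specific + n_noise
    side = int(np.ceil(np.sqrt(max(n_cells, 1))))
    width = side * pitch_nm
    height = side * pitch_nm

    xs, ys, fr, cl = [], [], [], []
    truth = GroundTruth()
    # specific clusters on a jittered grid restricted to the right half
    half = width / 2.0
    s_side = int(np.ceil(np.sqrt(max(n_specific, 1))))
    for i in range(n_specific):
        gx, gy = i % s_side, i // s_side
        cx = half + (gx + 0.5) * (half / s_side) + rng.uniform(-40, 40)
        cy = (gy + 0.5) * (height / s_side) + rng.uniform(-40, 40)
        frames, _ = simulate_cluster_trace(specific_config, i, rng=rng)
        k = frames.size
        xs.append(cx + rng.normal(0, sigma_loc_nm, k))
        ys.append(cy + rng.normal(0, sigma_loc_nm, k))
        fr.append(frames)
        cl.append(np.full(k, i, dtype=np.int64))
        truth.cluster_class[i] = "specific"
    noise_table, noise_truth = simulate_noise_clusters(
        noise_config, origin_nm=(0.0, 0.0), extent_nm=(width, height),
        rng=rng, first_cluster_id=n_specific,
    )
    x = np.concatenate(xs + [noise_table.x_nm])
    y = np.concatenate(ys + [noise_table.y_nm])
    f = np.concatenate(fr + [noise_table.frame]).astype(np.int64)
    c = np.concatenate(cl + [noise_truth.loc_cluster_id])
    table = LocalizationTable(
        x_nm=x, y_nm=y, frame=f,
        precision_nm=np.full(x.size, sigma_loc_nm),
        frame_duration_s=specific_config.frame_duration_s,
        n_frames=max(specific_config.n_frames, noise_config.n_frames),
    ).validate()
    truth.cluster_class.update(noise_truth.cluster_class)
    truth.loc_cluster_id = c
    truth.loc_mark_id = np.full(x.size, -1, dtype=np.int64)

    mask_px = 100.0
    nx = int(np.ceil(width / mask_px))
    ny = int(np.ceil(height / mask_px))
    grid_x = (np.arange(nx) + 0.5) * mask_px
    right = np.tile(grid_x >= half, (ny, 1))
    signal_mask = RegionMask(right, mask_px, (0.0, 0.0), "signal")
    background_mask = RegionMask(~right, mask_px, (0.0, 0.0), "background")
    return table, truth, signal_mask, background_mask
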