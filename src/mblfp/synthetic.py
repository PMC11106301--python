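"""Synthetic multi-mouse cohort generator with planted ground truth.

Emulates a multi-animal prefrontal LFP session well enough to exercise the
whole analysis chain end to end:

* per-second locomotive states from a Markov chain, gated in the group
  condition by a shared huddle process (huddled seconds inactive-enriched,
  non-huddled seconds active-enriched);
* huddle episodes with a strict minimum persistence and a configurable size
  distribution;
* state/context/huddle-dependent low-band (0-12 Hz) and high-band
  (31-150 Hz) log-amplitudes, so the high-to-low power ratio (HLR) carries
  the planted ordering inactive < active-still < active and
  huddled ~ single < non-huddled;
* a shared cohort-level AR(1) modulator (weight ``coupling_strength``)
  planting instantaneous interbrain HLR correlation;
* directed leader->follower influence as an AR(1)-coupled latent on the
  per-second log-band-power driver, so Granger causality at the 1 Hz HLR
  timescale can recover the planted edge set.

Waveforms are synthesised per 1-s segment as band-limited filtered noise
(FIR band definitions matching the analysis bands) riding on 1/f background
plus a white floor, with raised-cosine crossfades between segments.  A fast
path (:func:`simulate_hlr_series`) produces the per-second HLR series
directly from the same latent amplitudes, skipping waveform synthesis, for
statistical calibration experiments that need hundreds of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import (
    AnnotationTable,
    LfpTrace,
    SessionManifest,
    LOCOMOTIVE_STATES,
    write_annotations,
    write_manifest,
    write_trace,
)
from .spectral import HlrSeries

__all__ = [
    "HuddleParams",
    "NoiseParams",
    "CohortSimConfig",
    "GroundTruth",
    "CohortBundle",
    "simulate_behavior",
    "simulate_drivers",
    "simulate_hlr_series",
    "simulate_lfp",
    "simulate_cohort",
    "write_bundle",
]

STATE_INDEX = {s: i for i, s in enumerate(LOCOMOTIVE_STATES)}


@dataclass(frozen=True)
class HuddleParams:
    """Cohort-level huddle formation/breakup process.

    Gaps between huddles are exponential with mean ``1/formation_rate`` s;
    episode durations are exponential with mean ``1/breakup_rate`` s,
    truncated below at ``min_persistence_s + 1`` so every generated episode
    satisfies the strict >10 s rule.  ``size_probs`` gives the episode-size
    distribution (members drawn uniformly among subjects).
    """

    formation_rate: float = 1.0 / 120.0
    breakup_rate: float = 1.0 / 600.0
    min_persistence_s: int = 10
    size_probs: tuple[tuple[int, float], ...] = ((4, 0.7), (3, 0.2), (2, 0.1))


@dataclass(frozen=True)
class NoiseParams:
    """Background noise of the synthetic trace, in ADC counts."""

    one_over_f_exponent: float = 1.0
    background_scale: float = 20.0
    white_floor: float = 5.0


def _default_transition() -> np.ndarray:
    # rows: from inactive / active_still / active; persistent but mixing
    return np.array(
        [
            [0.97, 0.02, 0.01],
            [0.03, 0.93, 0.04],
            [0.01, 0.04, 0.95],
        ]
    )


def _huddled_transition() -> np.ndarray:
    # inactive-enriched: huddled mice mostly rest, occasionally groom/shift
    return np.array(
        [
            [0.99, 0.008, 0.002],
            [0.08, 0.90, 0.02],
            [0.05, 0.10, 0.85],
        ]
    )


def _non_huddled_transition() -> np.ndarray:
    # active-enriched: non-huddled mice in the group are mostly moving
    return np.array(
        [
            [0.90, 0.06, 0.04],
            [0.01, 0.91, 0.08],
            [0.004, 0.026, 0.97],
        ]
    )


def _default_band_gains() -> dict[tuple[str, str], tuple[float, float]]:
    """(state, huddle_status) -> (ln low-amp gain, ln high-amp gain).

    Built from an HLR offset d+o applied antisymmetrically: low amplitude
    falls and high amplitude rises with mobility, reproducing the
    two-cluster low/high power scatter.  Statuses: ``single`` (single
    condition), ``huddled`` / ``non_huddled`` (group condition); huddled is
    close to single, non-huddled is elevated.
    """
    state_delta = {"inactive": -0.8, "active_still": 0.0, "active": 0.8}
    status_offset = {"single": 0.0, "huddled": 0.05, "non_huddled": 0.35}
    gains = {}
    for state, d in state_delta.items():
        for status, o in status_offset.items():
            gains[(state, status)] = (-0.5 * (d + o), 0.5 * (d + o))
    return gains


@dataclass
class CohortSimConfig:
    """Everything that defines one simulated session.

    ``coupling_strength`` weights a shared cohort-level AR(1) modulator in
    the group condition (0 = independent brains).  ``leader_map`` maps
    ``(leader_id, follower_id)`` to ``(lag_s, weight)``: the follower's HLR
    driver receives ``weight`` times the leader's driver lagged by
    ``lag_s`` seconds, and the follower adopts the leader's lagged
    locomotive state with probability ``weight`` outside huddled seconds.
    """

    n_subjects: int = 4
    duration_s: int = 10_800
    fs: float = 1024.0
    condition: str = "group"
    cohort_id: str = "c01"
    seed: int = 0
    state_transition: np.ndarray = field(default_factory=_default_transition)
    huddled_transition: np.ndarray = field(default_factory=_huddled_transition)
    non_huddled_transition: np.ndarray = field(default_factory=_non_huddled_transition)
    huddle: HuddleParams = field(default_factory=HuddleParams)
    band_gains: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_band_gains
    )
    coupling_strength: float = 0.5
    leader_map: dict[tuple[str, str], tuple[int, float]] = field(default_factory=dict)
    driver_rho: float = 0.8
    driver_sigma: float = 0.15
    band_sigma: float = 0.10
    amp_low: float = 300.0
    amp_high: float = 80.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    bit_width: int = 16

    def __post_init__(self) -> None:
        if self.duration_s < 60:
            raise ValueError("duration_s must be >= 60")
        for name in ("state_transition", "huddled_transition", "non_huddled_transition"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (3, 3) or np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError(f"{name} must be a 3x3 row-stochastic matrix")
            setattr(self, name, m)
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        for (lead, fol), (lag, w) in self.leader_map.items():
            if lag < 1:
                raise ValueError(f"leader lag must be >= 1 s ({lead}->{fol})")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"influence weight must lie in [0, 1] ({lead}->{fol})")

    @property
    def subjects(self) -> list[str]:
        return [f"m{i + 1}" for i in range(self.n_subjects)]


@dataclass
class GroundTruth:
    """Planted latent structure of one simulated session."""

    states: pd.DataFrame  # subject_id, second, locomotive_state, huddle_group_id
    huddle_members: dict[str, frozenset[str]]  # episode id -> member set
    drivers: dict[str, np.ndarray]  # subject -> effective per-second HLR driver
    modulator: np.ndarray
    leader_edges: list[tuple[str, str]]
    coupling_strength: float

    def driver_correlation(self, a: str, b: str) -> float:
        """True pairwise correlation of the effective HLR drivers."""
        return float(np.corrcoef(self.drivers[a], self.drivers[b])[0, 1])


@dataclass
class CohortBundle:
    manifest: SessionManifest
    annotations: AnnotationTable
    traces: list[LfpTrace]
    ground_truth: GroundTruth
    hlr_true: list[HlrSeries]


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _simulate_huddles(
    config: CohortSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, frozenset[str]], dict[str, tuple[int, int]]]:
    """Cohort-level huddle schedule.

    Returns (per-second episode label array of object dtype with None when
    no huddle, episode member sets, episode spans).
    """
    n = config.duration_s
    labels = np.full(n, None, dtype=object)
    members: dict[str, frozenset[str]] = {}
    spans: dict[str, tuple[int, int]] = {}
    if config.condition != "group" or config.huddle.formation_rate <= 0:
        return labels, members, spans
    hp = config.huddle
    sizes = np.array([s for s, _ in hp.size_probs])
    probs = np.array([p for _, p in hp.size_probs], dtype=float)
    probs /= probs.sum()
    t = 0
    k = 0
    while t < n:
        gap = 0.0 if hp.formation_rate == np.inf else rng.exponential(1.0 / hp.formation_rate)
        t += int(np.floor(gap))
        if t >= n:
            break
        dur = np.inf if hp.breakup_rate == 0 else rng.exponential(1.0 / hp.breakup_rate)
        dur = max(int(np.ceil(dur)) if np.isfinite(dur) else n, hp.min_persistence_s + 1)
        end = min(t + dur, n)
        size = min(int(rng.choice(sizes, p=probs)), config.n_subjects)
        size = max(size, 2) if config.n_subjects >= 2 else size
        mem = frozenset(rng.choice(config.subjects, size=size, replace=False))
        eid = f"h{k:03d}"
        labels[t:end] = eid
        members[eid] = mem
        spans[eid] = (t, end - 1)
        k += 1
        t = end
    return labels, members, spans


def simulate_behavior(
    config: CohortSimConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationTable, dict[str, frozenset[str]]]:
    """Per-second locomotive states and huddle labels for every subject.

    Group condition: a shared huddle process gates each subject's Markov
    chain (inactive-enriched transitions while huddled, active-enriched
    while in the group but not huddled).  Single condition: every subject
    evolves independently under ``state_transition``.  Followers named in
    ``leader_map`` adopt their leader's lagged state with probability equal
    to the influence weight, outside huddled seconds.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.duration_s
    subjects = config.subjects
    labels, members, _ = _simulate_huddles(config, rng)

    huddled = {
        sid: np.array(
            [labels[t] is not None and sid in members[labels[t]] for t in range(n)]
        )
        for sid in subjects
    }
    # followers listed after leaders so a lag-1 adoption reads finished rows
    edges = [(l, f, lag, w) for (l, f), (lag, w) in config.leader_map.items()]
    states = {sid: np.zeros(n, dtype=int) for sid in subjects}
    init = rng.integers(0, 3, size=len(subjects))
    u = rng.random((len(subjects), n))
    adopt_u = rng.random((len(subjects), n))
    cum = {
        "base": np.cumsum(config.state_transition, axis=1),
        "huddled": np.cumsum(config.huddled_transition, axis=1),
        "non_huddled": np.cumsum(config.non_huddled_transition, axis=1),
    }
    # t=0: one Markov step from a uniformly drawn predecessor, so the first
    # second already follows the state-conditional dynamics
    for j, sid in enumerate(subjects):
        if config.condition == "group":
            key0 = "huddled" if huddled[sid][0] else "non_huddled"
        else:
            key0 = "base"
        states[sid][0] = int(np.searchsorted(cum[key0][init[j]], u[j, 0], side="right"))
    for t in range(1, n):
        for j, sid in enumerate(subjects):
            if config.condition == "group":
                key = "huddled" if huddled[sid][t] else "non_huddled"
            else:
                key = "base"
            row = cum[key][states[sid][t - 1]]
            states[sid][t] = int(np.searchsorted(row, u[j, t], side="right"))
        for lead, fol, lag, w in edges:
            if t - lag < 0:
                continue
            jf = subjects.index(fol)
            if not huddled[fol][t] and adopt_u[jf, t] < w:
                states[fol][t] = states[lead][t - lag]

    frames = []
    for sid in subjects:
        hud = np.where(huddled[sid], labels, None)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "second": np.arange(n),
                    "locomotive_state": np.array(LOCOMOTIVE_STATES)[states[sid]],
                    "huddle_group_id": pd.array(
                        [h if h is not None else pd.NA for h in hud], dtype="string"
                    ),
                }
            )
        )
    table = AnnotationTable(df=pd.concat(frames, ignore_index=True), condition=config.condition)
    return table, members


# ---------------------------------------------------------------------------
# latent drivers
# ---------------------------------------------------------------------------

def simulate_drivers(
    config: CohortSimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-second HLR driver latents with leader coupling plus shared modulator.

    Each subject's driver follows an AR(1) with autocorrelation
    ``driver_rho``; followers additionally receive ``weight`` times the
    leader's driver at the configured lag.  The effective driver adds
    ``coupling_strength`` times a cohort-level AR(1) modulator (group
    condition only).
    """
    n = config.duration_s
    subjects = config.subjects
    eps = rng.normal(0.0, config.driver_sigma, size=(len(subjects), n))
    m_eps = rng.normal(0.0, config.driver_sigma, size=n)
    d = np.zeros((len(subjects), n))
    m = np.zeros(n)
    idx = {sid: j for j, sid in enumerate(subjects)}
    edges = [
        (idx[l], idx[f], lag, w) for (l, f), (lag, w) in config.leader_map.items()
    ]
    rho = config.driver_rho
    for t in range(1, n):
        d[:, t] = rho * d[:, t - 1] + eps[:, t]
        m[t] = rho * m[t - 1] + m_eps[t]
        for jl, jf, lag, w in edges:
            if t - lag >= 0:
                d[jf, t] += w * d[jl, t - lag]
    c = config.coupling_strength if config.condition == "group" else 0.0
    eff = {sid: d[idx[sid]] + c * m for sid in subjects}
    return eff, m


def _per_second_amplitudes(
    config: CohortSimConfig,
    table: AnnotationTable,
    drivers: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Low/high band amplitude (ADC counts) per second per subject."""
    out = {}
    for sid in config.subjects:
        states = table.states(sid)
        if config.condition == "group":
            status = np.where(table.huddled_flags(sid), "huddled", "non_huddled")
        else:
            status = np.full(len(states), "single")
        g_low = np.empty(len(states))
        g_high = np.empty(len(states))
        for (state, stat), (gl, gh) in config.band_gains.items():
            m = (states == state) & (status == stat)
            g_low[m] = gl
            g_high[m] = gh
        e = drivers[sid][: len(states)]
        jit = rng.normal(0.0, config.band_sigma, size=(2, len(states)))
        amp_low = config.amp_low * np.exp(g_low - 0.5 * e + jit[0])
        amp_high = config.amp_high * np.exp(g_high + 0.5 * e + jit[1])
        out[sid] = (amp_low, amp_high)
    return out


def _hlr_from_amps(
    sid: str, config: CohortSimConfig, amp_low: np.ndarray, amp_high: np.ndarray
) -> HlrSeries:
    valid = amp_low > 0
    vals = np.full(amp_low.shape, np.nan)
    np.divide(amp_high, amp_low, out=vals, where=valid)
    return HlrSeries(
        subject_id=sid,
        cohort_id=config.cohort_id,
        condition=config.condition,
        values=vals**2,
        valid=valid,
    )


def simulate_hlr_series(
    config: CohortSimConfig,
) -> tuple[list[HlrSeries], GroundTruth]:
    """Fast path: per-second HLR directly from the latent amplitudes.

    Produces the HLR each animal's spectral analysis would measure, up to a
    band-shape constant that cancels in every correlation: HLR is
    proportional to (high amplitude / low amplitude) squared.  Used for
    calibration experiments needing many replicates; the waveform path is
    checked against it separately.
    """
    rng = np.random.default_rng(config.seed)
    table, members = simulate_behavior(config, rng)
    drivers, modulator = simulate_drivers(config, rng)
    amps = _per_second_amplitudes(config, table, drivers, rng)
    gt = GroundTruth(
        states=table.df,
        huddle_members=members,
        drivers=drivers,
        modulator=modulator,
        leader_edges=list(config.leader_map),
        coupling_strength=config.coupling_strength,
    )
    series = [
        _hlr_from_amps(sid, config, *amps[sid]) for sid in config.subjects
    ]
    return series, gt


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance FIR-band-limited white noise."""
    lo, hi = band
    numtaps = 4097  # ~4 s at 1024 Hz; sharp enough for a 0-12 Hz band
    if lo <= 0:
        taps = signal.firwin(numtaps, hi, fs=fs)
    else:
        taps = signal.firwin(numtaps, [lo, hi], fs=fs, pass_zero=False)
    x = signal.fftconvolve(rng.standard_normal(n), taps, mode="same")
    return x / x.std()


def _one_over_f_noise(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f^exponent background via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _smooth_envelope(amps: np.ndarray, fs: float, fade_s: float = 0.05) -> np.ndarray:
    """Per-sample amplitude envelope with raised-cosine segment crossfades."""
    env = np.repeat(amps, int(fs))
    k = max(int(fade_s * fs), 2)
    win = np.hanning(k)
    win /= win.sum()
    return signal.fftconvolve(env, win, mode="same")


def simulate_lfp(
    table: AnnotationTable,
    config: CohortSimConfig,
    drivers: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> list[LfpTrace]:
    """Synthesise integer LFP traces from the per-second latent amplitudes.

    Each trace is low-band plus high-band filtered noise under smoothed
    per-second amplitude envelopes, riding on 1/f background and a white
    floor, rounded to signed ``bit_width``-bit ADC counts.
    """
    if sorted(table.subjects) != sorted(config.subjects):
        raise ValueError("annotation table does not match the configured subjects")
    n_sec = table.n_seconds
    if n_sec != config.duration_s:
        raise ValueError("annotation table does not span the configured duration")
    fs = config.fs
    n = int(n_sec * fs)
    amps = _per_second_amplitudes(config, table, drivers, rng)
    lim = (1 << (config.bit_width - 1)) - 1
    traces = []
    for sid in config.subjects:
        amp_low, amp_high = amps[sid]
        low = _bandlimited_noise(n, fs, (0.0, 12.0), rng)
        high = _bandlimited_noise(n, fs, (31.0, 150.0), rng)
        x = _smooth_envelope(amp_low, fs) * low
        x += _smooth_envelope(amp_high, fs) * high
        del low, high
        if config.noise.background_scale > 0:
            x += config.noise.background_scale * _one_over_f_noise(
                n, config.noise.one_over_f_exponent, rng
            )
        if config.noise.white_floor > 0:
            x += config.noise.white_floor * rng.standard_normal(n)
        samples = np.clip(np.round(x), -lim - 1, lim).astype(np.int32)
        traces.append(
            LfpTrace(
                subject_id=sid,
                cohort_id=config.cohort_id,
                condition=config.condition,
                fs=fs,
                samples=samples,
                bit_width=config.bit_width,
            )
        )
    return traces


def simulate_cohort(config: CohortSimConfig) -> CohortBundle:
    """Full session bundle: manifest + annotations + traces + ground truth.

    Deterministic given ``config.seed``; the same seed yields bit-identical
    bundles.
    """
    rng = np.random.default_rng(config.seed)
    table, members = simulate_behavior(config, rng)
    drivers, modulator = simulate_drivers(config, rng)
    amp_rng_state = rng.bit_generator.state  # amplitudes reused by both paths
    amps_rng = np.random.default_rng()
    amps_rng.bit_generator.state = amp_rng_state
    traces = simulate_lfp(table, config, drivers, rng)
    gt = GroundTruth(
        states=table.df,
        huddle_members=members,
        drivers=drivers,
        modulator=modulator,
        leader_edges=list(config.leader_map),
        coupling_strength=config.coupling_strength,
    )
    amps = _per_second_amplitudes(config, table, drivers, amps_rng)
    hlr_true = [
        _hlr_from_amps(sid, config, *amps[sid]) for sid in config.subjects
    ]
    manifest = SessionManifest(
        cohort_id=config.cohort_id,
        condition=config.condition,
        subjects=config.subjects,
        files={},
        duration_s=float(config.duration_s),
        fs=config.fs,
        bit_width=config.bit_width,
    )
    return CohortBundle(
        manifest=manifest,
        annotations=table,
        traces=traces,
        ground_truth=gt,
        hlr_true=hlr_true,
    )


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write a bundle to disk: hex traces, annotation CSV, manifest, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for trace in bundle.traces:
        p = out / f"{trace.subject_id}.hex"
        write_trace(trace, p)
        files[trace.subject_id] = [p.name]
    manifest = replace(bundle.manifest, files=files)
    write_manifest(manifest, out / "manifest.yaml")
    write_annotations(bundle.annotations, out / "annotations.csv")
    gt = bundle.ground_truth
    truth = {
        "leader_edges": [list(e) for e in gt.leader_edges],
        "coupling_strength": gt.coupling_strength,
        "huddle_members": {k: sorted(v) for k, v in gt.huddle_members.items()},
        "driver_correlation": {
            f"{a}|{b}": gt.driver_correlation(a, b)
            for i, a in enumerate(sorted(gt.drivers))
            for b in sorted(gt.drivers)[i + 1 :]
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return out
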