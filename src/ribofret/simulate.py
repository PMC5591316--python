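"""Synthetic data generators: fluorescence traces with known two-state
kinetics and photophysics, SHAPE peak-area tables with planted protections,
and node trajectories with a planted correlation structure.

Every generator is seed-deterministic and returns the planted ground truth
alongside the data, so each downstream estimator can be tested as a
parameter-recovery problem.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NodeTrajectory
from .types import (
    CH3,
    DOCKED,
    DYES,
    FLIPPED,
    Condition,
    GroundTruth,
    RawTrace,
    alternating_excitation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KineticScheme",
    "PhotophysicsParams",
    "simulate_complex_trace",
    "simulate_binding_experiment",
    "generate_shape_peak_table",
    "generate_node_trajectory",
]

_S_IDX = {DOCKED: 0, FLIPPED: 1}
_S_NAME = (DOCKED, FLIPPED)


@dataclass
class KineticScheme:
    """Two-state (docked/flipped) Markov scheme with optional ligand binding.

    ``state_efficiencies`` maps state -> (E57, E35, E37).  ``rates_pre`` and
    ``rates_post`` give the conformational exchange rates (per second) before
    and after protein binding, keys ``dock_to_flip`` / ``flip_to_dock``.
    ``k_on`` is the pseudo-first-order binding rate, ``k_off`` the unbinding
    rate; ``state_dependent_binding`` optionally multiplies ``k_on`` per
    state (e.g. 0 on the flipped state forbids binding there).
    """

    state_efficiencies: dict[str, tuple[float, float, float]]
    rates_pre: dict[str, float]
    rates_post: dict[str, float] | None = None
    k_on: float = 0.0
    k_off: float = 0.0
    state_dependent_binding: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for state in (DOCKED, FLIPPED):
            if state not in self.state_efficiencies:
                raise ValueError(f"missing efficiencies for state {state!r}")
            e57, e35, e37 = self.state_efficiencies[state]
            for e in (e57, e35, e37):
                if not (0.0 <= e <= 1.0) or not math.isfinite(e):
                    raise ValueError("efficiencies must lie in [0, 1]")
            if e35 + e37 > 1.0 + 1e-12:
                raise ValueError("E35 + E37 must be <= 1 per state")
        if self.rates_post is None:
            self.rates_post = dict(self.rates_pre)
        for rates in (self.rates_pre, self.rates_post):
            for key in ("dock_to_flip", "flip_to_dock"):
                r = rates.get(key, None)
                if r is None or not math.isfinite(r) or r < 0:
                    raise ValueError(f"rate {key} must be finite and >= 0")
        for k in (self.k_on, self.k_off):
            if not math.isfinite(k) or k < 0:
                raise ValueError("binding rates must be finite and >= 0")
        if self.state_dependent_binding is not None:
            for state, m in self.state_dependent_binding.items():
                if state not in _S_IDX or m < 0 or not math.isfinite(m):
                    raise ValueError("invalid state_dependent_binding entry")

    def _pair(self, rates: dict[str, float]) -> tuple[float, float]:
        return rates["dock_to_flip"], rates["flip_to_dock"]

    def rate_matrix(self, bound: bool) -> np.ndarray:
        """Generator matrix (states ordered docked, flipped); rows sum to 0."""
        kdf, kfd = self._pair(self.rates_post if bound else self.rates_pre)
        return np.array([[-kdf, kdf], [kfd, -kfd]])

    @property
    def rate_matrix_pre(self) -> np.ndarray:
        return self.rate_matrix(bound=False)

    @property
    def rate_matrix_post(self) -> np.ndarray:
        return self.rate_matrix(bound=True)

    def stationary_flipped(self, bound: bool = False) -> float:
        """Analytic stationary flipped occupancy k_df / (k_df + k_fd)."""
        kdf, kfd = self._pair(self.rates_post if bound else self.rates_pre)
        if kdf + kfd == 0:
            return 0.0
        return kdf / (kdf + kfd)

    def bind_rate(self, state_idx: int) -> float:
        mult = 1.0
        if self.state_dependent_binding is not None:
            mult = self.state_dependent_binding.get(_S_NAME[state_idx], 1.0)
        return self.k_on * mult


@dataclass
class PhotophysicsParams:
    """Camera/dye model: brightness, background, leakage, detection, noise.

    ``gamma`` holds relative detection x quantum-yield factors per dye
    (Cy3, Cy5, Cy7); the Cy7 default below 1 encodes its less efficient
    detection.  ``leakage`` is the spectral mixing matrix ``L`` such that
    observed mean counts are ``L @ (gamma * photons) + background``.
    ``noise_model`` is ``"poisson"`` (photon statistics, default) or
    ``("gaussian", sigma)``.
    """

    frame_duration: float = 0.05
    brightness: float = 500.0
    background: np.ndarray = field(default_factory=lambda: np.full(3, 20.0))
    leakage: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 0.0, 0.0], [0.05, 1.0, 0.0], [0.01, 0.08, 1.0]]
        )
    )
    gamma: tuple[float, float, float] = (1.0, 1.0, 0.6)
    bleach_rates: dict[str, float] = field(
        default_factory=lambda: {d: 0.0 for d in DYES}
    )
    noise_model: str | tuple[str, float] = "poisson"

    def __post_init__(self) -> None:
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        self.background = np.asarray(self.background, dtype=float).reshape(3)
        self.leakage = np.asarray(self.leakage, dtype=float).reshape(3, 3)
        off = self.leakage[~np.eye(3, dtype=bool)]
        if ((off < 0) | (off >= 1)).any():
            raise ValueError("leakage fractions must lie in [0, 1)")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("gamma factors must be > 0")
        for dye in DYES:
            rate = self.bleach_rates.get(dye, 0.0)
            if rate < 0 or not math.isfinite(rate):
                raise ValueError(f"bleach rate for {dye} must be >= 0")
            self.bleach_rates.setdefault(dye, 0.0)
        if isinstance(self.noise_model, tuple):
            kind, sigma = self.noise_model
            if kind != "gaussian" or sigma < 0:
                raise ValueError("noise_model tuple must be ('gaussian', sigma)")
        elif self.noise_model not in ("poisson", "none"):
            raise ValueError("noise_model must be 'poisson', 'none' or gaussian")


def _exp_draw(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


def _sample_path(
    rng: np.random.Generator,
    scheme: KineticScheme,
    t_end: float,
    *,
    binding_enabled: bool,
    t_inject: float = 0.0,
    max_events: int | None = None,
) -> tuple[list[tuple[int, float, float]], list[tuple[float, float | None]]]:
    """Exact continuous-time path of (conformation, bound) via competing
    exponential clocks; binding can only occur after ``t_inject``.

    Returns state segments ``(state_idx, t0, t1)`` and binding events
    ``(t_on, t_off | None)``.
    """
    s = 1 if rng.random() < scheme.stationary_flipped(bound=False) else 0
    bound = False
    t = 0.0
    segs: list[tuple[int, float, float]] = []
    events: list[tuple[float, float | None]] = []
    seg_start = 0.0
    n_events = 0
    while t < t_end:
        kdf, kfd = scheme._pair(scheme.rates_post if bound else scheme.rates_pre)
        k_state = kdf if s == 0 else kfd
        t_state = t + _exp_draw(rng, k_state)
        if bound:
            t_switch = t + _exp_draw(rng, scheme.k_off)
        elif (
            binding_enabled
            and (max_events is None or n_events < max_events)
            and scheme.bind_rate(s) > 0
        ):
            t_switch = max(t, t_inject) + _exp_draw(rng, scheme.bind_rate(s))
        else:
            t_switch = math.inf
        t_next = min(t_state, t_switch, t_end)
        if t_next >= t_end:
            t = t_end
            break
        if t_state <= t_switch:
            segs.append((s, seg_start, t_state))
            seg_start = t_state
            s = 1 - s
        else:
            if bound:
                events[-1] = (events[-1][0], t_switch)
                bound = False
            else:
                events.append((t_switch, None))
                bound = True
                n_events += 1
        t = t_next
    segs.append((s, seg_start, t_end))
    return segs, events


def _state_per_frame(
    segs: list[tuple[int, float, float]], frame_mid: np.ndarray
) -> np.ndarray:
    bounds = np.array([t1 for _, _, t1 in segs])
    states = np.array([s for s, _, _ in segs])
    idx = np.searchsorted(bounds, frame_mid, side="right")
    idx = np.minimum(idx, len(states) - 1)
    return states[idx]


def _interval_mask(
    events: list[tuple[float, float | None]], frame_mid: np.ndarray, t_end: float
) -> np.ndarray:
    mask = np.zeros(frame_mid.shape, dtype=bool)
    for t_on, t_off in events:
        mask |= (frame_mid >= t_on) & (frame_mid < (t_end if t_off is None else t_off))
    return mask


def _render_trace(
    rng: np.random.Generator,
    scheme: KineticScheme,
    photo: PhotophysicsParams,
    segs: list[tuple[int, float, float]],
    events: list[tuple[float, float | None]],
    n_frames: int,
    *,
    cy3_always: bool,
    t_inject: float = 0.0,
    spike_pairs: np.ndarray | None = None,
    condition: Condition | None = None,
    trace_id: str = "",
) -> tuple[RawTrace, GroundTruth]:
    dt = photo.frame_duration
    t_end = n_frames * dt
    frame_mid = (np.arange(n_frames) + 0.5) * dt
    state = _state_per_frame(segs, frame_mid)

    cy3_on = (
        np.ones(n_frames, dtype=bool)
        if cy3_always
        else _interval_mask(events, frame_mid, t_end)
    )

    # single irreversible photobleaching step per dye; the Cy3 clock starts
    # when the dye first appears in the evanescent field
    t3_start = 0.0 if cy3_always else (events[0][0] if events else math.inf)
    bleach_t = {}
    for dye, start in (("cy3", t3_start), ("cy5", 0.0), ("cy7", 0.0)):
        bleach_t[dye] = start + _exp_draw(rng, photo.bleach_rates[dye])
    alive3 = frame_mid < bleach_t["cy3"]
    alive5 = frame_mid < bleach_t["cy5"]
    alive7 = frame_mid < bleach_t["cy7"]

    eff = np.array(
        [scheme.state_efficiencies[DOCKED], scheme.state_efficiencies[FLIPPED]]
    )
    e57 = eff[state, 0] * alive5 * alive7
    e35 = eff[state, 1] * alive5
    e37 = eff[state, 2] * alive7

    B = photo.brightness
    photons = np.zeros((n_frames, 3))
    green = np.zeros(n_frames, dtype=bool)
    green[0::2] = True
    g_act = green & cy3_on & alive3
    photons[g_act, 0] = B * (1.0 - e35[g_act] - e37[g_act])
    photons[g_act, 1] = B * e35[g_act] * (1.0 - e57[g_act])
    photons[g_act, 2] = B * (e37[g_act] + e35[g_act] * e57[g_act])
    r_act = ~green & alive5
    photons[r_act, 1] = B * (1.0 - e57[r_act])
    photons[r_act, 2] = B * e57[r_act]

    if spike_pairs is not None and len(spike_pairs):
        # nonproductive encounters: brief Cy3-only bursts with no FRET
        photons[2 * spike_pairs, 0] += B

    g = np.asarray(photo.gamma)
    mean = (photons * g) @ photo.leakage.T + photo.background

    if photo.noise_model == "poisson":
        counts = rng.poisson(mean).astype(float)
    elif photo.noise_model == "none":
        counts = mean
    else:
        counts = mean + rng.normal(0.0, photo.noise_model[1], size=mean.shape)

    trace = RawTrace(
        intensities=counts,
        excitation=alternating_excitation(n_frames),
        frame_duration=dt,
        condition=condition,
        trace_id=trace_id,
    )

    # ground-truth segments at frame resolution (same midpoint discretization)
    change = np.nonzero(np.diff(state))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n_frames]))
    gt_segs = [(_S_NAME[state[s]], int(s), int(e)) for s, e in zip(starts, ends)]

    def t2frame(t: float) -> int:
        return int(np.searchsorted(frame_mid, t))

    gt_events = [
        (t2frame(on), None if off is None or off >= t_end else t2frame(off))
        for on, off in events
        if on < t_end
    ]
    bleach_frames = {
        dye: (t2frame(bt) if bt < t_end else None) for dye, bt in bleach_t.items()
    }
    gt = GroundTruth(
        state_segments=gt_segs,
        binding_events=gt_events,
        binding_times=[(on, off) for on, off in events if on < t_end],
        bleach_frames=bleach_frames,
        t_inject=t_inject,
    )
    return trace, gt


def simulate_complex_trace(
    scheme: KineticScheme,
    photo: PhotophysicsParams,
    n_frames: int,
    seed: int | np.random.Generator,
    condition: Condition | None = None,
    trace_id: str = "",
) -> tuple[RawTrace, GroundTruth]:
    """One preassembled complex: all three dyes present from frame 0, the
    conformation exchanging under ``rates_pre``.  Deterministic per seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t_end = n_frames * photo.frame_duration
    segs, events = _sample_path(rng, scheme, t_end, binding_enabled=False)
    return _render_trace(
        rng,
        scheme,
        photo,
        segs,
        events,
        n_frames,
        cy3_always=True,
        condition=condition,
        trace_id=trace_id,
    )


def simulate_binding_experiment(
    scheme: KineticScheme,
    photo: PhotophysicsParams,
    n_traces: int,
    n_frames: int,
    seed: int,
    *,
    t_inject: float = 0.0,
    max_events: int | None = None,
    spike_rate: float = 0.0,
    condition: Condition | None = None,
) -> list[tuple[RawTrace, GroundTruth]]:
    """Real-time injection experiment: each trace starts with the RNA complex
    (Cy5/Cy7) but without Cy3; a binding event raises the Cy3 signal and
    switches the conformational rates from ``rates_pre`` to ``rates_post``.

    ``t_inject`` is the delivery dead time before binding can occur;
    ``max_events`` caps productive bindings per trace; ``spike_rate`` (per
    second, during unbound stretches) plants 1-3-frame-pair nonproductive
    Cy3 spikes.
    """
    if scheme.k_on <= 0:
        raise ValueError("simulate_binding_experiment requires k_on > 0")
    if n_traces == 0:
        logger.warning("simulate_binding_experiment called with n_traces = 0")
        return []
    master = np.random.default_rng(seed)
    out = []
    t_end = n_frames * photo.frame_duration
    for i, rng in enumerate(master.spawn(n_traces)):
        segs, events = _sample_path(
            rng,
            scheme,
            t_end,
            binding_enabled=True,
            t_inject=t_inject,
            max_events=max_events,
        )
        spike_pairs = None
        if spike_rate > 0:
            frame_mid = (np.arange(n_frames) + 0.5) * photo.frame_duration
            unbound_pairs = np.nonzero(
                ~_interval_mask(events, frame_mid, t_end)[0::2]
            )[0]
            n_spikes = rng.poisson(spike_rate * t_end)
            picks = []
            for p in rng.choice(
                unbound_pairs, size=min(n_spikes, len(unbound_pairs)), replace=False
            ):
                picks.extend(range(p, min(p + int(rng.integers(1, 4)), n_frames // 2)))
            spike_pairs = np.unique(picks).astype(int) if picks else None
        out.append(
            _render_trace(
                rng,
                scheme,
                photo,
                segs,
                events,
                n_frames,
                cy3_always=False,
                t_inject=t_inject,
                spike_pairs=spike_pairs,
                condition=condition,
                trace_id=f"trace{i:05d}",
            )
        )
    return out


def generate_shape_peak_table(
    n_nt: int,
    protection: dict[int, float] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    base_mean: float = 30.0,
    base_sigma: float = 0.8,
    lane_noise_sd: float = 0.05,
    background_mean: float = 5.0,
    planted_base: float = 60.0,
) -> pd.DataFrame:
    """Synthetic SHAPE capillary peak-area tables for +/- protein conditions.

    Per-nucleotide baseline reactivities are log-normal; planted
    ``protection`` maps nucleotide -> log10 ratio (negative = protected) and
    multiplies the +protein lane by ``10**log_ratio`` before multiplicative
    lane noise.  Planted nucleotides are given a well-above-baseline area
    (``planted_base``) since log ratios are only quantifiable where the
    unprotected signal sits well above the reactivity floor.  Matched
    background lanes are drawn with a smaller mean.

    Returns a tidy frame with columns nucleotide / condition / lane / area.
    """
    if n_nt < 10:
        raise ValueError("n_nt must be >= 10")
    protection = dict(protection or {})
    for nt, lr in protection.items():
        if not math.isfinite(lr):
            raise ValueError(f"planted log-ratio for nt {nt} is not finite")
        if not (1 <= nt <= n_nt):
            raise ValueError(f"planted nucleotide {nt} outside 1..{n_nt}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nts = np.arange(1, n_nt + 1)
    signal = rng.lognormal(math.log(base_mean), base_sigma, n_nt)
    ratio = np.ones(n_nt)
    for nt, lr in protection.items():
        signal[nt - 1] = planted_base
        ratio[nt - 1] = 10.0**lr

    def lane_noise() -> np.ndarray:
        return np.exp(rng.normal(0.0, lane_noise_sd, n_nt))

    rows = []
    for cond, r in (("minusS16", np.ones(n_nt)), ("plusS16", ratio)):
        # the planted ratio acts on the net signal above the lane background,
        # which the matched background lane measures independently
        bg_true = rng.lognormal(math.log(background_mean), 0.5, n_nt)
        mod = (signal * r + bg_true) * lane_noise()
        bg = bg_true * lane_noise()
        rows.append(
            pd.DataFrame(
                {"nucleotide": nts, "condition": cond, "lane": "modified", "area": mod}
            )
        )
        rows.append(
            pd.DataFrame(
                {"nucleotide": nts, "condition": cond, "lane": "background", "area": bg}
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_node_trajectory(
    positions: np.ndarray,
    correlation: np.ndarray,
    n_frames: int,
    amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    masses: np.ndarray | None = None,
    kinds: list[str] | None = None,
    ids: list | None = None,
) -> NodeTrajectory:
    """Correlated Gaussian node motions around fixed mean positions.

    Per-frame displacements of the x, y and z coordinates are independent
    zero-mean Gaussian draws sharing the target inter-node ``correlation``
    matrix, scaled by ``amplitude`` (same length units as ``positions``).
    Sample displacement correlations converge to the target as frames grow.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must have shape (n_nodes, 3)")
    n_nodes = positions.shape[0]
    corr = np.asarray(correlation, dtype=float)
    if corr.shape != (n_nodes, n_nodes):
        raise ValueError("correlation shape must match the node count")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    evals, evecs = np.linalg.eigh(corr)
    if evals.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(eigenvalue {evals.min():.3g})"
        )
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    z = rng.standard_normal((n_frames, 3, n_nodes))
    disp = z @ root.T  # (n_frames, 3, n_nodes), correlated across nodes
    coords = positions[None, :, :] + amplitude * disp.transpose(0, 2, 1)
    return NodeTrajectory(
        ids=ids if ids is not None else list(range(n_nodes)),
        kinds=kinds if kinds is not None else ["amino_acid"] * n_nodes,
        masses=masses if masses is not None else np.ones(n_nodes),
        coords=coords,
    )
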