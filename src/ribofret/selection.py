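"""Complex selection and two-state analysis.

Analyzable complexes are selected for 1:1:1 labeling stoichiometry (a
single terminal photobleaching step per dye) and for site-specific protein
binding; the donor-acceptor efficiency signal is then idealized into
docked/flipped states by thresholding, and pooled FRET histograms are fit
with double Gaussians to obtain population fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel
from scipy.signal import find_peaks

from .fret import FretSeries
from .types import CH3, CH5, CH7, DOCKED, FLIPPED, RawTrace

__all__ = [
    "StepEvent",
    "StatePath",
    "Histogram",
    "GaussianMixtureFit",
    "Verdict",
    "detect_steps",
    "stoichiometry_filter",
    "site_specific_filter",
    "idealize",
    "fret_histogram",
    "fit_double_gaussian",
]


@dataclass(frozen=True)
class StepEvent:
    frame: int
    channel: str
    direction: str  # "up" | "down"
    magnitude: float


@dataclass
class Verdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class StatePath:
    """Two-state idealization: contiguous alternating (state, start, end)
    segments over frame pairs (end exclusive)."""

    segments: list[tuple[str, int, int]]
    threshold: float
    min_dwell: int
    dt: float = 0.1  # seconds per sample (one frame pair)

    def __post_init__(self) -> None:
        prev = None
        for state, start, end in self.segments:
            if end <= start:
                raise ValueError("empty segment")
            if prev is not None:
                if start != prev[2]:
                    raise ValueError("segments must be contiguous")
                if state == prev[0]:
                    raise ValueError("segments must alternate states")
            prev = (state, start, end)

    @property
    def start(self) -> int:
        return self.segments[0][1]

    @property
    def end(self) -> int:
        return self.segments[-1][2]

    def segment_at(self, frame: int) -> tuple[str, int, int]:
        for seg in self.segments:
            if seg[1] <= frame < seg[2]:
                return seg
        raise IndexError(f"frame {frame} outside path [{self.start}, {self.end})")

    def state_at(self, frame: int) -> str:
        return self.segment_at(frame)[0]

    def occupancy(self, state: str) -> float:
        total = self.end - self.start
        n = sum(e - s for st, s, e in self.segments if st == state)
        return n / total

    def dwells(self, state: str, interior_only: bool = True) -> np.ndarray:
        """Dwell durations in seconds; ``interior_only`` drops the first and
        last segments (censored by the record)."""
        segs = self.segments[1:-1] if interior_only else self.segments
        return np.array([(e - s) * self.dt for st, s, e in segs if st == state])


def _robust_noise_sd(x: np.ndarray) -> float:
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d))) / (0.6744897501960817 * math.sqrt(2.0))


def _best_split(x: np.ndarray, min_size: int):
    """Least-squares single-changepoint search; returns (k, mag) or None."""
    n = len(x)
    if n < 2 * min_size:
        return None
    c = np.cumsum(x)
    ks = np.arange(min_size, n - min_size + 1)
    lmean = c[ks - 1] / ks
    rmean = (c[-1] - c[ks - 1]) / (n - ks)
    # maximizing the between-segment sum of squares == minimizing SSE
    gain = ks * lmean**2 + (n - ks) * rmean**2
    i = int(np.argmax(gain))
    return int(ks[i]), float(rmean[i] - lmean[i])


def detect_steps(
    series, sensitivity: float = 3.0, min_size: int = 2, channel: str = ""
) -> list[StepEvent]:
    """Step (changepoint) detection by recursive binary segmentation.

    Candidate changepoints minimize the piecewise-constant least-squares
    cost; steps whose magnitude falls below ``sensitivity`` times the robust
    noise SD (median absolute successive difference) are suppressed.  The
    reported frame is the first frame after the change.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series must have length >= 10")
    sd = _robust_noise_sd(x)
    thresh = max(sensitivity * sd, 1e-9 * max(1.0, np.abs(x).max()))
    boundaries: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        res = _best_split(x[lo:hi], min_size)
        if res is None:
            continue
        k, mag = res
        if abs(mag) <= thresh:
            continue
        boundaries.append(lo + k)
        stack.append((lo, lo + k))
        stack.append((lo + k, hi))
    boundaries.sort()
    # prune boundaries whose final adjacent-segment contrast fell below the
    # threshold after further splitting
    while True:
        edges = [0, *boundaries, len(x)]
        means = [x[edges[i] : edges[i + 1]].mean() for i in range(len(edges) - 1)]
        deltas = [means[i + 1] - means[i] for i in range(len(means) - 1)]
        weak = [i for i, d in enumerate(deltas) if abs(d) <= thresh]
        if not weak:
            break
        boundaries.pop(weak[int(np.argmin([abs(deltas[i]) for i in weak]))])
    edges = [0, *boundaries, len(x)]
    means = [x[edges[i] : edges[i + 1]].mean() for i in range(len(edges) - 1)]
    return [
        StepEvent(
            frame=boundaries[i],
            channel=channel,
            direction="up" if means[i + 1] > means[i] else "down",
            magnitude=abs(means[i + 1] - means[i]),
        )
        for i in range(len(boundaries))
    ]


def _presence_profile(x: np.ndarray, sensitivity: float = 3.0):
    """Segment a channel series into present/absent levels.

    Returns (n_up, n_down, final_present) where transitions are between the
    background level (the lowest segment) and any clearly elevated level, or
    None when the channel never rises above noise ("flat").
    """
    steps = detect_steps(x, sensitivity=sensitivity)
    edges = [0, *[s.frame for s in steps], len(x)]
    levels = np.array([x[edges[i] : edges[i + 1]].mean() for i in range(len(edges) - 1)])
    sd = _robust_noise_sd(x)
    bg = levels.min()
    amp = levels.max() - bg
    if amp < max(4.0 * sd, 1e-9):
        return None
    present = levels > bg + max(4.0 * sd, 0.25 * amp)
    n_up = int(np.sum(~present[:-1] & present[1:]))
    n_down = int(np.sum(present[:-1] & ~present[1:]))
    return n_up, n_down, bool(present[-1]), edges, present


def _dye_series(trace: RawTrace) -> dict[str, np.ndarray]:
    """Per-dye presence series: Cy3 from green ch3; Cy5 from the total red
    signal (state-invariant while Cy5 is alive); Cy7 from red ch7."""
    g = trace.green_mask
    r = trace.red_mask
    return {
        "cy3": trace.intensities[g, CH3],
        "cy5": trace.intensities[r, CH5] + trace.intensities[r, CH7],
        "cy7": trace.intensities[r, CH7],
    }


def stoichiometry_filter(
    trace: RawTrace, sensitivity: float = 3.0, background=None
) -> Verdict:
    """1:1:1 stoichiometry check: each dye must show exactly one terminal
    down-step to background (single-step photobleaching or unbinding) and at
    most one arrival up-step, with no extra comparable steps.

    ``background`` (optional per-channel mean counts) lets a flat channel be
    classified as present-but-unbleached rather than dark.
    """
    reasons = []
    bg_level = None
    if background is not None:
        bg = np.asarray(background, dtype=float).reshape(3)
        bg_level = {"cy3": bg[CH3], "cy5": bg[CH5] + bg[CH7], "cy7": bg[CH7]}
    for dye, series in _dye_series(trace).items():
        ch = {"cy3": "ch3", "cy5": "ch5", "cy7": "ch7"}[dye]
        prof = _presence_profile(series, sensitivity)
        if prof is None:
            sd = _robust_noise_sd(series)
            if bg_level is not None and series.mean() > bg_level[dye] + 4.0 * sd:
                reasons.append(f"{ch}: no terminal bleach")
            else:
                reasons.append(f"{ch}: no signal")
            continue
        n_up, n_down, final_present, edges, present = prof
        if n_down == 0 or final_present:
            reasons.append(f"{ch}: no terminal bleach")
        if n_down > 1:
            reasons.append(f"{ch}: multiple steps")
        if n_up > 1:
            reasons.append(f"{ch}: multiple steps")
        if dye == "cy3":
            # the directly excited Cy3 intensity is stoichiometry-
            # proportional: intermediate plateaus (a second comparable
            # up or down step) indicate multiple binders.  The acceptor
            # channels fluctuate with the FRET state and are judged on
            # presence/terminal bleach only.
            levels = np.array(
                [series[edges[i] : edges[i + 1]].mean() for i in range(len(edges) - 1)]
            )
            amp = levels.max() - levels.min()
            deltas = np.diff(levels)
            sig = np.abs(deltas) > 0.25 * amp
            if (sig & (deltas > 0)).sum() > 1 or (sig & (deltas < 0)).sum() > 1:
                reasons.append(f"{ch}: multiple steps")
    # deduplicate, preserving order
    reasons = list(dict.fromkeys(reasons))
    return Verdict(passed=not reasons, reasons=reasons)


def bound_interval(trace: RawTrace, sensitivity: float = 3.0):
    """First contiguous frame-pair interval in which Cy3 is present, or None."""
    s3 = _dye_series(trace)["cy3"]
    prof = _presence_profile(s3, sensitivity)
    if prof is None:
        return None
    _, _, _, edges, present = prof
    for i in np.nonzero(present)[0]:
        return edges[i], edges[i + 1]
    return None


def site_specific_filter(
    trace: RawTrace,
    fret: FretSeries,
    mode: str = "fret_s16",
    e3_threshold: float = 0.2,
    sensitivity: float = 3.0,
) -> Verdict:
    """Site-specific binding check.

    ``fret_s16`` mode requires the mean total transfer out of Cy3
    (``e3_total``) during the bound interval to exceed ``e3_threshold`` —
    energy transfer to Cy5/Cy7 evidences binding at the specific site.
    ``colocalize`` mode requires only temporal overlap of the Cy3 signal
    with Cy5/Cy7 presence (used when the binding site is too far from the
    labels for measurable transfer).
    """
    if mode not in ("fret_s16", "colocalize"):
        raise ValueError(f"unknown mode {mode!r}")
    interval = bound_interval(trace, sensitivity)
    if interval is None:
        return Verdict(False, ["no bound interval"])
    lo, hi = interval
    series = _dye_series(trace)
    red_present = (
        _presence_profile(series["cy5"], sensitivity) is not None
        or series["cy5"][lo:hi].mean() > 4 * _robust_noise_sd(series["cy5"])
    )
    if mode == "colocalize":
        if red_present:
            return Verdict(True)
        return Verdict(False, ["no Cy5/Cy7 co-localization"])
    e3 = fret.green_values("e3_total")[lo:hi]
    valid = np.isfinite(e3)
    if not valid.any():
        return Verdict(False, ["no valid frames in bound interval"])
    mean_e3 = float(e3[valid].mean())
    if mean_e3 > e3_threshold:
        return Verdict(True)
    return Verdict(False, [f"mean E3_total {mean_e3:.3f} <= {e3_threshold}"])


def idealize(
    e57_series,
    threshold: float = 0.35,
    min_dwell_frames: int = 2,
    valid=None,
    dt: float = 0.1,
) -> StatePath:
    """Threshold idealization of the donor-acceptor efficiency signal.

    Frames with ``E < threshold`` are flipped, others docked.  Runs shorter
    than ``min_dwell_frames`` are merged into the flanking state (shortest
    offending run first; an edge run merges into its single neighbor),
    suppressing shot-noise chatter.  Invalid frames inherit the state of the
    nearest valid frame.
    """
    e = np.asarray(e57_series, dtype=float)
    if valid is None:
        valid = np.isfinite(e)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(e)
    if valid.sum() < min_dwell_frames:
        raise ValueError("fewer valid frames than min_dwell_frames")
    idx_valid = np.nonzero(valid)[0]
    nearest = idx_valid[
        np.clip(
            np.searchsorted(idx_valid, np.arange(len(e))), 0, len(idx_valid) - 1
        )
    ]
    flipped = e[nearest] < threshold

    # run-length encode
    change = np.nonzero(np.diff(flipped))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(e)]))
    runs = [[bool(flipped[s]), int(s), int(e_)] for s, e_ in zip(starts, ends)]

    def coalesce(rs):
        out = []
        for r in rs:
            if out and out[-1][0] == r[0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    while len(runs) > 1:
        lengths = [r[2] - r[1] for r in runs]
        short = [i for i, L in enumerate(lengths) if L < min_dwell_frames]
        if not short:
            break
        i = min(short, key=lambda i: (lengths[i], i))
        runs[i][0] = not runs[i][0]  # absorb into the flanking state
        runs = coalesce(runs)

    segments = [
        (FLIPPED if f else DOCKED, s, e_) for f, s, e_ in runs
    ]
    return StatePath(
        segments=segments, threshold=threshold, min_dwell=min_dwell_frames, dt=dt
    )


@dataclass
class Histogram:
    counts: np.ndarray
    edges: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def fret_histogram(values, bins: int = 40, range=(-0.2, 1.2)) -> Histogram:
    """Counts-conserving FRET histogram: out-of-range values are clipped
    into the edge bins so the total equals the frame count."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = range
    width = (hi - lo) / bins
    v = np.clip(v, lo, hi - 1e-9 * width)
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    return Histogram(counts=counts.astype(float), edges=edges)


@dataclass
class GaussianMixtureFit:
    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    frac_low: float
    frac_high: float
    residual_norm: float
    collapsed: bool = False


class FitError(RuntimeError):
    def __init__(self, message, init=None, residuals=None):
        super().__init__(message)
        self.init = init
        self.residuals = residuals


def _init_means(hist: Histogram) -> tuple[float, float]:
    c = np.convolve(hist.counts, np.ones(3) / 3.0, mode="same")
    peaks, _ = find_peaks(c, prominence=0.05 * c.max())
    if len(peaks) >= 2:
        lo, hi = peaks.min(), peaks.max()  # widest-separated pair
        return float(hist.centers[lo]), float(hist.centers[hi])
    # single-mode fallback: quartiles of the binned distribution
    cum = np.cumsum(hist.counts) / hist.total
    q25 = float(hist.centers[np.searchsorted(cum, 0.25)])
    q75 = float(hist.centers[np.searchsorted(cum, 0.75)])
    return q25, q75


def fit_double_gaussian(hist: Histogram) -> GaussianMixtureFit:
    """Least-squares double-Gaussian fit of a binned FRET histogram.

    Initialization comes from the two most widely separated local maxima of
    the (lightly smoothed) counts.  The low- and high-mean components are
    ordered so ``mu_low < mu_high``; ``frac_low`` is the area of the
    low-mean component over the total area.  When the two fitted components
    are unresolved (mean separation below the larger sigma) the fit is
    collapsed to a single Gaussian and reported with ``collapsed=True`` and
    the full area assigned to that component.
    """
    if hist.total < 200:
        raise ValueError("need >= 200 pooled frames")
    x = hist.centers
    y = hist.counts
    mu1, mu2 = _init_means(hist)
    span = float(hist.edges[-1] - hist.edges[0])
    model = GaussianModel(prefix="g1_") + GaussianModel(prefix="g2_")
    params = model.make_params()
    width = float(hist.edges[1] - hist.edges[0])
    for pfx, mu in (("g1_", mu1), ("g2_", mu2)):
        params[f"{pfx}center"].set(value=mu, min=x[0] - 0.1, max=x[-1] + 0.1)
        params[f"{pfx}sigma"].set(value=0.05, min=width / 4, max=span / 2)
        amp = max(float(y[np.argmin(np.abs(x - mu))]), 1.0)
        params[f"{pfx}amplitude"].set(
            value=amp * 0.05 * math.sqrt(2 * math.pi), min=0.0
        )
    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError(
            "double-Gaussian fit did not converge",
            init={"mu1": mu1, "mu2": mu2},
            residuals=result.residual,
        )
    comps = sorted(
        (
            (
                result.params[f"{p}center"].value,
                result.params[f"{p}sigma"].value,
                result.params[f"{p}amplitude"].value,
            )
            for p in ("g1_", "g2_")
        ),
        key=lambda t: t[0],
    )
    (mlo, slo, alo), (mhi, shi, ahi) = comps
    resid = float(np.linalg.norm(result.residual))
    if (mhi - mlo) < max(slo, shi) or (alo + ahi) <= 0:
        single = GaussianModel()
        sp = single.make_params(
            center=float(np.average(x, weights=np.maximum(y, 0))),
            sigma=0.05,
            amplitude=float(y.sum() * width),
        )
        sp["sigma"].set(min=width / 4, max=span / 2)
        sp["amplitude"].set(min=0.0)
        sres = single.fit(y, sp, x=x)
        mu = float(sres.params["center"].value)
        sig = float(sres.params["sigma"].value)
        return GaussianMixtureFit(
            mu_low=mu,
            mu_high=mu,
            sigma_low=sig,
            sigma_high=sig,
            frac_low=0.0,
            frac_high=1.0,
            residual_norm=float(np.linalg.norm(sres.residual)),
            collapsed=True,
        )
    total = alo + ahi
    return GaussianMixtureFit(
        mu_low=float(mlo),
        mu_high=float(mhi),
        sigma_low=float(slo),
        sigma_high=float(shi),
        frac_low=float(alo / total),
        frac_high=float(ahi / total),
        residual_norm=resid,
    )
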