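"""Corrected three-color FRET efficiencies from alternating-excitation traces.

The package adopts a photon-conservation forward model for one donor
excitation (green frame).  With ``N`` photons absorbed by Cy3 and pairwise
efficiencies ``E35`` (Cy3->Cy5), ``E37`` (Cy3->Cy7) and ``E57`` (Cy5->Cy7),
the gamma-normalized expected channel fluxes are::

    F3 = N * (1 - E35 - E37)          # photons emitted by Cy3
    F5 = N * E35 * (1 - E57)          # transferred to Cy5, emitted there
    F7 = N * (E37 + E35 * E57)        # direct + cascaded transfer to Cy7

so that ``F3 + F5 + F7 = N`` (photon conservation).  The model is solved in
closed form by :func:`efficiencies_green`.  Red frames excite Cy5 directly
and yield ``E57`` through the ratio :func:`efficiency_red`.

"Gamma-normalized" means one absorbed photon produces one expected count in
whichever channel it exits; instrument detection differences (notably the
less efficient detection of Cy7) are removed beforehand by
:func:`correct_intensities` together with background subtraction and
spectral-leakage inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CH3, CH5, CH7, GREEN, RED, RawTrace

__all__ = [
    "CorrectionParams",
    "FretSeries",
    "correct_intensities",
    "efficiency_red",
    "efficiencies_green",
    "compute_fret_series",
]


@dataclass
class CorrectionParams:
    """Instrument correction parameters.

    Parameters
    ----------
    background
        Mean counts per channel, subtracted first.
    leakage
        3x3 spectral mixing matrix ``L``; observed counts are
        ``L @ true + background``.  Diagonal entries are 1, off-diagonal
        entries are spillover fractions in [0, 1).
    gamma_57
        Detection/quantum-yield ratio entering the red-excitation ratio
        estimator (1.0 once ``cy7_detection`` has equalized the channels).
    gamma_35
        Cy5-relative-to-Cy3 detection factor; green-frame ch5/ch7 fluxes are
        divided by it before the photon-conservation inversion.
    cy7_detection
        Multiplicative correction applied to ch7 after leakage inversion,
        compensating the less efficient detection of Cy7.
    """

    background: np.ndarray = field(default_factory=lambda: np.zeros(3))
    leakage: np.ndarray = field(default_factory=lambda: np.eye(3))
    gamma_57: float = 1.0
    gamma_35: float = 1.0
    cy7_detection: float = 1.0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float).reshape(3)
        self.leakage = np.asarray(self.leakage, dtype=float).reshape(3, 3)
        off = self.leakage[~np.eye(3, dtype=bool)]
        if ((off < 0) | (off >= 1)).any():
            raise ValueError("leakage fractions must lie in [0, 1)")
        if abs(np.linalg.det(self.leakage)) < 1e-12:
            raise ValueError("singular leakage matrix")
        if self.gamma_57 <= 0 or self.gamma_35 <= 0 or self.cy7_detection <= 0:
            raise ValueError("gamma factors must be > 0")

    @classmethod
    def from_photophysics(cls, photo) -> "CorrectionParams":
        """Exact inverse of a simulator's :class:`PhotophysicsParams`."""
        g3, g5, g7 = photo.gamma
        return cls(
            background=photo.background.copy(),
            leakage=photo.leakage.copy(),
            gamma_57=1.0,
            gamma_35=g5 / g3,
            cy7_detection=g5 / g7,
        )


def correct_intensities(trace: RawTrace, params: CorrectionParams) -> np.ndarray:
    """Background-subtracted, leakage-inverted, Cy7-rescaled channel fluxes.

    The order is fixed: background subtraction, then inverse leakage, then
    the ch7 detection rescaling.  Returns an ``(n_frames, 3)`` float array.
    """
    raw = trace.intensities - params.background
    flux = np.linalg.solve(params.leakage, raw.T).T
    flux[:, CH7] *= params.cy7_detection
    return flux


def efficiency_red(f5, f7, gamma_57: float = 1.0):
    """Cy5->Cy7 efficiency from red-excitation fluxes.

    ``E57 = F7 / (F7 + gamma_57 * F5)``.  Frames where the denominator is
    not positive are flagged invalid (NaN), never clipped.

    Returns
    -------
    (e57, valid) : ndarray pair
    """
    f5 = np.asarray(f5, dtype=float)
    f7 = np.asarray(f7, dtype=float)
    denom = f7 + gamma_57 * f5
    valid = denom > 0
    e57 = np.full(np.broadcast(f5, f7).shape, np.nan)
    e57[valid] = f7[valid] / denom[valid]
    return e57, valid


def efficiencies_green(f3, f5, f7, e57):
    """Invert the photon-conservation model on green-excitation fluxes.

    Inputs must be gamma-normalized (see module docstring).  ``e57`` is the
    Cy5->Cy7 efficiency interleaved from the nearest red frame.  Closed-form
    solution::

        N   = F3 + F5 + F7
        E35 = F5 / ((1 - E57) * N)
        E37 = F7 / N - E35 * E57

    Frames with ``N <= 0`` are invalid; frames with ``E57 ~ 1`` are
    indeterminate for ``E35`` and flagged invalid as well.

    Returns
    -------
    (e35, e37, n, valid)
    """
    f3 = np.asarray(f3, dtype=float)
    f5 = np.asarray(f5, dtype=float)
    f7 = np.asarray(f7, dtype=float)
    e57 = np.asarray(e57, dtype=float)
    n = f3 + f5 + f7
    valid = (n > 0) & np.isfinite(e57) & (e57 < 1.0 - 1e-9)
    e35 = np.full(n.shape, np.nan)
    e37 = np.full(n.shape, np.nan)
    e35[valid] = f5[valid] / ((1.0 - e57[valid]) * n[valid])
    e37[valid] = f7[valid] / n[valid] - e35[valid] * e57[valid]
    return e35, e37, n, valid


@dataclass
class FretSeries:
    """Per-frame corrected efficiencies of one trace.

    Red frames carry ``e57``; green frames carry ``e35``, ``e37``, the total
    transfer out of Cy3 ``e3_total = 1 - F3/N`` and the conserved flux
    ``n_flux = N``.  Entries not defined for a frame's excitation are NaN.
    Efficiencies are reported unclipped; ``valid`` flags frames whose
    denominators were usable.
    """

    frame: np.ndarray
    excitation: np.ndarray
    e57: np.ndarray
    e35: np.ndarray
    e37: np.ndarray
    e3_total: np.ndarray
    n_flux: np.ndarray
    valid: np.ndarray
    frame_duration: float = 0.05
    trace_id: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.frame) // 2

    @property
    def pair_duration(self) -> float:
        return 2.0 * self.frame_duration

    def e57_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame-pair ``(e57, valid)`` taken from each pair's red frame."""
        red = self.excitation == RED
        return (
            self.e57[red][: self.n_pairs],
            self.valid[red][: self.n_pairs],
        )

    def green_values(self, name: str) -> np.ndarray:
        """Per-pair values of a green-frame quantity (e35/e37/e3_total/n_flux)."""
        green = self.excitation == GREEN
        return getattr(self, name)[green][: self.n_pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "excitation": self.excitation,
                "e57": self.e57,
                "e35": self.e35,
                "e37": self.e37,
                "e3_total": self.e3_total,
                "n_flux": self.n_flux,
                "valid": self.valid,
            }
        )


def compute_fret_series(trace: RawTrace, params: CorrectionParams) -> FretSeries:
    """Full correction pipeline: raw trace -> per-frame efficiencies.

    Red-excitation frames yield ``E57``; each green frame is paired with the
    red frame of the same frame pair (nearest following red frame) to supply
    the ``E57`` needed by the cascade inversion.
    """
    flux = correct_intensities(trace, params)
    n = trace.n_frames
    green = trace.green_mask
    red = trace.red_mask

    e57 = np.full(n, np.nan)
    e35 = np.full(n, np.nan)
    e37 = np.full(n, np.nan)
    e3_total = np.full(n, np.nan)
    n_flux = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    e57_r, valid_r = efficiency_red(flux[red, CH5], flux[red, CH7], params.gamma_57)
    e57[red] = e57_r
    valid[red] = valid_r

    # nearest-frame interleaving: green frame i uses red frame i+1 (or i-1 at
    # the trace end)
    idx_green = np.nonzero(green)[0]
    partner = np.where(idx_green + 1 < n, idx_green + 1, idx_green - 1)
    usable = partner >= 0
    idx_green = idx_green[usable]
    partner = partner[usable]

    f3 = flux[idx_green, CH3]
    f5 = flux[idx_green, CH5] / params.gamma_35
    f7 = flux[idx_green, CH7] / params.gamma_35
    e35_g, e37_g, n_g, valid_g = efficiencies_green(f3, f5, f7, e57[partner])
    e35[idx_green] = e35_g
    e37[idx_green] = e37_g
    n_flux[idx_green] = n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        e3_total[idx_green] = np.where(n_g > 0, 1.0 - f3 / n_g, np.nan)
    valid[idx_green] = valid_g

    return FretSeries(
        frame=np.arange(n),
        excitation=trace.excitation.copy(),
        e57=e57,
        e35=e35,
        e37=e37,
        e3_total=e3_total,
        n_flux=n_flux,
        valid=valid,
        frame_duration=trace.frame_duration,
        trace_id=trace.trace_id,
    )
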