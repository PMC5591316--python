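"""Shared containers for three-color alternating-excitation trace data.

Conventions used throughout the package:

* camera frames are 0-based; even frames are green (532 nm, Cy3) excitation,
  odd frames are red (633 nm, Cy5) excitation, 50 ms each by default;
* a *frame pair* is one green + one red frame (0.1 s) and is the time unit
  for all kinetic quantities;
* detector channels are ordered (ch3, ch5, ch7) for the Cy3, Cy5 and Cy7
  emission bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GREEN = "G"
RED = "R"

CH3, CH5, CH7 = 0, 1, 2
CHANNELS = ("ch3", "ch5", "ch7")
DYES = ("cy3", "cy5", "cy7")

DOCKED = "docked"
FLIPPED = "flipped"
STATES = (DOCKED, FLIPPED)


def alternating_excitation(n_frames: int) -> np.ndarray:
    """Excitation labels for ``n_frames`` camera frames (even = green)."""
    exc = np.empty(n_frames, dtype="U1")
    exc[0::2] = GREEN
    exc[1::2] = RED
    return exc


@dataclass(frozen=True)
class Condition:
    """Experimental condition axes: Mg2+ and the protein complement.

    ``proteins`` maps protein name -> (concentration in nM, dye label), the
    dye label being one of ``"Cy3"``, ``"Cy5"``, ``"Cy7"`` or ``"none"``.
    """

    mg_mM: float = 20.0
    proteins: Mapping[str, tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mg_mM < 0:
            raise ValueError("mg_mM must be >= 0")
        for name, (conc, label) in self.proteins.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name}")
            if label not in ("Cy3", "Cy5", "Cy7", "none"):
                raise ValueError(f"unknown dye label {label!r} for {name}")


@dataclass
class RawTrace:
    """Per-frame three-channel intensities under alternating excitation.

    Parameters
    ----------
    intensities
        ``(n_frames, 3)`` array of detector counts, channels (ch3, ch5, ch7).
    excitation
        Length ``n_frames`` array of ``"G"``/``"R"`` labels; must alternate.
    frame_duration
        Camera frame duration in seconds (one excitation pulse).
    """

    intensities: np.ndarray
    excitation: np.ndarray | None = None
    frame_duration: float = 0.05
    condition: Condition | None = None
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != 3:
            raise ValueError("intensities must have shape (n_frames, 3)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        n = self.intensities.shape[0]
        if self.excitation is None:
            self.excitation = alternating_excitation(n)
        else:
            self.excitation = np.asarray(self.excitation, dtype="U1")
        if self.excitation.shape[0] != n:
            raise ValueError("excitation and intensities length mismatch")
        bad = ~np.isin(self.excitation, (GREEN, RED))
        if bad.any():
            raise ValueError(
                f"unknown excitation label {self.excitation[bad][0]!r}"
            )
        if n >= 2 and (self.excitation[:-1] == self.excitation[1:]).any():
            raise ValueError("excitation labels must alternate frame by frame")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_frames // 2

    @property
    def pair_duration(self) -> float:
        """Duration of one green+red frame pair in seconds."""
        return 2.0 * self.frame_duration

    @property
    def green_mask(self) -> np.ndarray:
        return self.excitation == GREEN

    @property
    def red_mask(self) -> np.ndarray:
        return self.excitation == RED


@dataclass
class GroundTruth:
    """Planted truth attached to a simulated trace (oracle for recovery tests).

    ``state_segments`` tile ``[0, n_frames)`` with ``(state, start, end)``
    runs (end exclusive, camera frames).  ``binding_events`` holds
    ``(association_frame, dissociation_frame | None)`` pairs; ``binding_times``
    the same in seconds.  ``bleach_frames`` maps dye -> frame index or None.
    """

    state_segments: Sequence[tuple[str, int, int]]
    binding_events: Sequence[tuple[int, int | None]] = field(default_factory=list)
    binding_times: Sequence[tuple[float, float | None]] = field(default_factory=list)
    bleach_frames: Mapping[str, int | None] = field(
        default_factory=lambda: {d: None for d in DYES}
    )
    t_inject: float = 0.0

    def __post_init__(self) -> None:
        prev_end = None
        for _, start, end in self.state_segments:
            if end <= start:
                raise ValueError("state segment with non-positive length")
            if prev_end is not None and start != prev_end:
                raise ValueError("state segments must tile the trace")
            prev_end = end
        for on, off in self.binding_events:
            # equal frames can occur when a sub-frame event is discretized
            if off is not None and off < on:
                raise ValueError("dissociation must follow association")

    @property
    def n_frames(self) -> int:
        return self.state_segments[-1][2] if self.state_segments else 0

    def state_per_frame(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype="U8")
        for state, start, end in self.state_segments:
            out[start:end] = state
        return out

    def occupancy(self, state: str) -> float:
        """Fraction of frames spent in ``state``."""
        n = self.n_frames
        frames = sum(e - s for st, s, e in self.state_segments if st == state)
        return frames / n if n else float("nan")

    def binding_pairs(self) -> list[tuple[int, int | None]]:
        """Binding events converted to frame-pair indices."""
        return [
            (on // 2, None if off is None else off // 2)
            for on, off in self.binding_events
        ]
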