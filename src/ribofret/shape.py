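"""SHAPE reactivity normalization and protection classification.

The pipeline starts from per-nucleotide capillary-electropherogram peak
areas (one modified and one background lane per condition).  Processing per
condition: background subtraction, scaling so the mean of the 92-97
percentile band equals 100, then flooring at a baseline reactivity of 2.5.
The +protein / -protein log10 reactivity ratio is finally classified into
protection categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "subtract_background",
    "percentile_band",
    "scale_percentile",
    "apply_floor",
    "log_ratio_classify",
    "reactivity_profile",
    "protection_calls",
]

FLOOR = 2.5
BAND = (92.0, 97.0)

CATEGORIES = ("strong_protect", "moderate_protect", "unchanged", "moderate_expose")


def subtract_background(modified: pd.Series, background: pd.Series) -> pd.Series:
    """Net peak areas: modified minus background lane, negatives set to 0.

    Both series are indexed by nucleotide; mismatched positions raise an
    error listing them.
    """
    diff = set(modified.index).symmetric_difference(background.index)
    if diff:
        raise ValueError(f"mismatched nucleotide positions: {sorted(diff)}")
    net = modified - background.reindex(modified.index)
    return net.clip(lower=0.0)


def percentile_band(values: pd.Series, band=BAND) -> pd.Series:
    """Values whose percentile rank (0-100 by sorted position, inclusive
    bounds) falls inside ``band``.  Ordinal ranking keeps the band populated
    for tied values (ties carry equal values, so the band mean is unaffected
    by how they are ordered)."""
    v = values.to_numpy(dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    ranks = 100.0 * (rankdata(v, method="ordinal") - 1.0) / (n - 1)
    mask = (ranks >= band[0]) & (ranks <= band[1])
    return values[mask]


def scale_percentile(net: pd.Series, band=BAND) -> pd.Series:
    """Scale peak areas so the mean of the 92-97 percentile band equals 100.

    Scale-invariant: multiplying the input by any positive constant leaves
    the output unchanged.
    """
    positive = net[net > 0]
    if len(positive) < 20:
        raise ValueError("need at least 20 positive peak areas")
    band_vals = percentile_band(net, band)
    m = band_vals.mean()
    if len(band_vals) == 0 or m <= 0:
        raise ValueError("empty or non-positive percentile band")
    return net * (100.0 / m)


def apply_floor(scaled: pd.Series, floor: float = FLOOR) -> pd.DataFrame:
    """Floor low reactivities: values strictly below ``floor`` are replaced
    by it and flagged.  Guarantees finite log ratios downstream."""
    if not np.isfinite(scaled.to_numpy(dtype=float)).all():
        raise ValueError("scaled reactivities must be finite")
    floored = scaled < floor
    rho = scaled.where(~floored, floor)
    return pd.DataFrame(
        {"nucleotide": scaled.index, "rho": rho.to_numpy(), "floored": floored.to_numpy()}
    ).set_index("nucleotide")


def _classify(lr: float) -> tuple[str, bool]:
    if lr < -1.5:
        return "strong_protect", True
    if lr <= -1.0:
        return "strong_protect", False
    if lr <= -0.5:
        return "moderate_protect", False
    if lr < 0.5:
        return "unchanged", False
    if lr <= 1.0:
        return "moderate_expose", False
    return "moderate_expose", True


def log_ratio_classify(plus: pd.DataFrame, minus: pd.DataFrame) -> pd.DataFrame:
    """Per-nucleotide protection calls from the +/- protein reactivities.

    ``log_ratio = log10(rho_plus / rho_minus)``; categories follow fixed
    bins: strong protection for log ratios in [-1.5, -1], moderate
    protection in (-1, -0.5], moderate exposure in [0.5, 1], otherwise
    unchanged.  Ratios beyond the outer bin edges are assigned to the
    nearest named class and flagged ``clamped``.
    """
    diff = set(plus.index).symmetric_difference(minus.index)
    if diff:
        raise ValueError(f"mismatched nucleotide positions: {sorted(diff)}")
    minus = minus.reindex(plus.index)
    lr = np.log10(plus["rho"].to_numpy() / minus["rho"].to_numpy())
    cats, clamped = zip(*(_classify(v) for v in lr))
    return pd.DataFrame(
        {
            "nucleotide": plus.index,
            "rho_plus": plus["rho"].to_numpy(),
            "rho_minus": minus["rho"].to_numpy(),
            "log_ratio": lr,
            "category": cats,
            "clamped": clamped,
        }
    ).set_index("nucleotide")


def reactivity_profile(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Full normalization for one condition of a tidy peak table
    (columns nucleotide / condition / lane / area): background subtraction,
    percentile scaling, flooring."""
    sub = table[table["condition"] == condition]
    mod = sub[sub["lane"] == "modified"].set_index("nucleotide")["area"]
    bg = sub[sub["lane"] == "background"].set_index("nucleotide")["area"]
    if mod.empty or bg.empty:
        raise ValueError(f"condition {condition!r} lacks modified/background lanes")
    return apply_floor(scale_percentile(subtract_background(mod, bg)))


def protection_calls(table: pd.DataFrame) -> pd.DataFrame:
    """End-to-end +/- protein comparison of a tidy peak table."""
    plus = reactivity_profile(table, "plusS16")
    minus = reactivity_profile(table, "minusS16")
    return log_ratio_classify(plus, minus)
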