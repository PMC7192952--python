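"""Windowed time-averaging of per-frame statistics.

Averages follow the equilibration convention of NPT water runs: by
default the window spans 250-1000 ps; when the trajectory is shorter,
the second half is used instead (with a warning), since short
heterogeneity runs carry no stated burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AveragingWindow", "SeriesSummary", "window_summary", "default_window"]

PS = 1000.0  # fs per ps


@dataclass(frozen=True)
class AveragingWindow:
    """Inclusive time window [t_start, t_end], in femtoseconds."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"need t_start < t_end, got [{self.t_start}, {self.t_end}]")


DEFAULT_WINDOW = AveragingWindow(250.0 * PS, 1000.0 * PS)


def default_window(t_min: float, t_max: float) -> AveragingWindow:
    """The 250-1000 ps equilibrated window when the trajectory covers
    it; otherwise the second half of the trajectory."""
    if t_min <= DEFAULT_WINDOW.t_start and t_max >= DEFAULT_WINDOW.t_end:
        return DEFAULT_WINDOW
    if t_max > t_min:
        w = AveragingWindow(t_min + (t_max - t_min) / 2.0, t_max)
    else:  # single-instant trajectory: a unit window around it
        w = AveragingWindow(t_min - 0.5, t_max + 0.5)
    warnings.warn(
        f"trajectory span [{t_min}, {t_max}] fs does not cover the default "
        f"250-1000 ps window; averaging over its second half instead",
        stacklevel=2,
    )
    return w


@dataclass
class SeriesSummary:
    mean: float
    std: float
    n_frames: int
    window: AveragingWindow


def window_summary(
    times: np.ndarray,
    values: np.ndarray,
    window: AveragingWindow,
    sample_std: bool = False,
) -> SeriesSummary:
    """Mean and (population, by default) standard deviation of the
    samples inside the window; window boundaries are inclusive."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times >= window.t_start) & (times <= window.t_end)
    if not mask.any():
        raise ValueError(
            f"no samples in window [{window.t_start}, {window.t_end}] fs; "
            f"series spans [{times.min() if len(times) else 'nan'}, "
            f"{times.max() if len(times) else 'nan'}] fs"
        )
    v = values[mask]
    ddof = 1 if (sample_std and len(v) > 1) else 0
    return SeriesSummary(
        mean=float(v.mean()),
        std=float(v.std(ddof=ddof)),
        n_frames=int(mask.sum()),
        window=window,
    )
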