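"""Assembly / disassembly rate constants from adhesion intensity traces.

A background-subtracted intensity trace I(t) is modeled as exponential in
its growth and decay phases, so the rate constant is the slope of
ln(I/I₀) (assembly) or ln(I₀/I) (disassembly) against time. Because real
traces are exponential only over part of their span, the fit window is
selected adaptively: every admissible window is fitted by ordinary least
squares and the window with the largest adjusted R² wins
(adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2) for a single regressor).

Conventions: natural logarithm; rates reported per minute; minimum window
of 10 samples (3.3 min at the 20 s frame interval — short enough for
nascent-adhesion phases, long enough that maximizing adjusted R² over
candidate windows cannot promote trend-free noise past the 0.3 filter); assembly windows anchor at the first time point (I₀ fixed
there) and extend to the intensity peak, disassembly windows anchor at the
last time point and start anywhere from the peak onward, with I₀ taken at
the window start. Windows containing non-positive intensities are skipped
(they invalidate the window, not the trace). A best adjusted R² below 0.3
flags the trace as noise-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R2_FILTER_THRESHOLD = 0.3
MIN_WINDOW = 10  # samples


@dataclass
class IntensityTrace:
    """Background-subtracted intensity of one adhesion over time."""

    track_id: int
    times: np.ndarray        # seconds, strictly increasing
    intensities: np.ndarray  # background-subtracted
    channel: str = "paxillin"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.intensities))


@dataclass
class KineticsFit:
    """A rate constant with its selected window and fit quality."""

    rate_constant: float        # per minute
    window: tuple[int, int]     # (start_index, end_index), inclusive
    adjusted_r2: float
    i0: float                   # intensity at the window reference point
    phase: str                  # assembly | disassembly
    passed_filter: bool
    track_id: int = -1
    channel: str = ""
    failed: bool = False


def adjusted_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept and adjusted R² of y on t (single regressor)."""
    n = t.size
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 0.0  # flat response: the regressor explains nothing
    else:
        r2 = 1 - ss_res / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), float(adj)


def _best_window(candidates):
    """Pick max adjusted R²; ties (within 1e-12) go to the longer window."""
    best = None
    for cand in candidates:
        if best is None:
            best = cand
            continue
        if cand.adjusted_r2 > best.adjusted_r2 + 1e-12:
            best = cand
        elif (abs(cand.adjusted_r2 - best.adjusted_r2) <= 1e-12
              and cand.window[1] - cand.window[0] > best.window[1] - best.window[0]):
            best = cand
    return best


def assembly_rate(trace: IntensityTrace,
                  r2_threshold: float = R2_FILTER_THRESHOLD,
                  min_window: int = MIN_WINDOW) -> KineticsFit:
    """Assembly rate constant (per minute) by adaptive-window log-linear fit.

    I₀ is the intensity at the first time point; candidate windows run from
    the start to every end index between the minimum window and the trace
    peak. The slope of ln(I/I₀) vs time (minutes) in the best-adjusted-R²
    window is the rate constant.
    """
    pk = trace.peak_index
    if pk + 1 < min_window:
        return _failed_fit(trace, "assembly")
    i0 = trace.intensities[0]
    t_min = (trace.times - trace.times[0]) / 60.0
    cands = []
    for j in range(min_window - 1, pk + 1):
        win_i = trace.intensities[:j + 1]
        if i0 <= 0 or np.any(win_i <= 0):
            continue
        y = np.log(win_i / i0)
        slope, _, adj = adjusted_r2(t_min[:j + 1], y)
        cands.append(KineticsFit(slope, (0, j), adj, float(i0), "assembly",
                                 adj >= r2_threshold, trace.track_id,
                                 trace.channel))
    best = _best_window(cands)
    return best if best is not None else _failed_fit(trace, "assembly")


def disassembly_rate(trace: IntensityTrace,
                     r2_threshold: float = R2_FILTER_THRESHOLD,
                     min_window: int = MIN_WINDOW) -> KineticsFit:
    """Disassembly rate constant (per minute), positive for decay.

    Windows end at the last time point; the start index is varied from the
    peak to the latest index leaving the minimum window. I₀ is the
    intensity at the start of each candidate window; the slope of
    ln(I₀/I) vs time in the best window is the rate constant.
    """
    pk = trace.peak_index
    n = trace.times.size
    if n < min_window:
        return _failed_fit(trace, "disassembly")
    t_min = trace.times / 60.0
    cands = []
    # if the peak sits too close to the end (e.g. a monotone rise), fall
    # back to the shortest admissible terminal window so a slope is still
    # reported (it will be negative and fail the R²/sign checks naturally)
    for i in range(min(pk, n - min_window), n - min_window + 1):
        win_i = trace.intensities[i:]
        i0 = win_i[0]
        if i0 <= 0 or np.any(win_i <= 0):
            continue
        y = np.log(i0 / win_i)
        slope, _, adj = adjusted_r2(t_min[i:], y)
        cands.append(KineticsFit(slope, (i, n - 1), adj, float(i0),
                                 "disassembly", adj >= r2_threshold,
                                 trace.track_id, trace.channel))
    best = _best_window(cands)
    return best if best is not None else _failed_fit(trace, "disassembly")


def _failed_fit(trace: IntensityTrace, phase: str) -> KineticsFit:
    return KineticsFit(float("nan"), (0, 0), float("-inf"), float("nan"),
                       phase, False, trace.track_id, trace.channel,
                       failed=True)


def filter_by_adjusted_r2(fits: list[KineticsFit],
                          threshold: float = R2_FILTER_THRESHOLD
                          ) -> list[KineticsFit]:
    """Keep fits whose best adjusted R² meets the noise-rejection threshold."""
    return [f for f in fits
            if not f.failed and f.adjusted_r2 >= threshold]
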