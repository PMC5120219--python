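"""Analysis of force/extension traces from pulling simulations.

The workflow mirrors how steered-MD pulling data is reduced: a 50 ps
running average removes local fluctuations, force is binned against
extension in 1 Å bins, the two elastic phases (soft unbending phase I,
stiff pre-unfolding phase II) are segmented by an exhaustive two-segment
least-squares breakpoint search, per-phase slopes give stiffnesses in
mN/m (1 pN/nm ≡ 1 mN/m), force peaks are detected by prominence, and
rupture events from distance monitors are matched to peaks in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .geometry import MetricSeries, running_average
from .io_formats import ForceTrace

__all__ = [
    "PhaseFit",
    "ForcePeak",
    "BinnedForce",
    "smooth_and_bin",
    "segment_phases_fit",
    "detect_force_peaks",
    "detect_ruptures",
    "correlate_events",
    "convert_spring_units",
]


@dataclass
class BinnedForce:
    """Per-extension-bin force statistics (bins with no samples are absent)."""

    extension: np.ndarray   # bin centers, nm
    mean: np.ndarray        # pN
    sd: np.ndarray          # pN
    count: np.ndarray
    bin_width: float        # nm


@dataclass
class PhaseFit:
    """Two-phase piecewise-linear fit of force vs extension."""

    breakpoint_extension: float | None   # nm; None for a single-phase fit
    k_phase1: float                      # mN/m
    k_phase2: float | None               # mN/m; None for single phase
    intercepts: tuple[float, float | None]
    stderr: tuple[float, float | None]
    r_squared: tuple[float, float | None]
    single_phase: bool = False


@dataclass
class ForcePeak:
    extension: float          # nm
    time: float               # ns
    height: float             # pN, force at the apex
    drop: float               # pN, apex minus following local minimum
    prominence: float = 0.0
    matched_rupture: float | None = None  # ns, filled by correlate_events

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")
        if self.drop < 0:
            raise ValueError("peak drop must be non-negative")


def smooth_and_bin(
    trace: ForceTrace,
    window_ps: float = 50.0,
    bin_width_a: float = 1.0,
) -> tuple[ForceTrace, BinnedForce]:
    """Centered running average of force over time plus binned statistics.

    ``window_ps`` is the averaging window (50 ps default); ``bin_width_a``
    the extension bin width in Å (1 Å default).  Bins containing no
    samples are absent from the output, never reported as zero.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    span_ps = (trace.time[-1] - trace.time[0]) * 1000.0
    if len(trace) > 1 and window_ps > span_ps:
        raise ValueError(f"window {window_ps} ps exceeds trace span {span_ps:.3g} ps")
    dt_ps = (span_ps / (len(trace) - 1)) if len(trace) > 1 else window_ps
    n = max(1, int(round(window_ps / dt_ps)))
    smoothed = ForceTrace(
        time=trace.time.copy(),
        extension=trace.extension.copy(),
        force=running_average(trace.force, n),
        mode=trace.mode,
        speed=trace.speed,
        spring_constant=trace.spring_constant,
        applied_force=trace.applied_force,
    )
    bw_nm = bin_width_a / 10.0
    idx = np.floor(trace.extension / bw_nm).astype(int)
    df = pd.DataFrame({"bin": idx, "force": trace.force})
    g = df.groupby("bin")["force"]
    stats = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=0), "count": g.size()})
    binned = BinnedForce(
        extension=(stats.index.to_numpy() + 0.5) * bw_nm,
        mean=stats["mean"].to_numpy(),
        sd=stats["sd"].to_numpy(),
        count=stats["count"].to_numpy(),
        bin_width=bw_nm,
    )
    return smoothed, binned


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """slope, intercept, SSE, slope stderr, R² of a simple linear fit."""
    n = len(x)
    A = np.column_stack([x, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    sxx = float(((x - x.mean()) ** 2).sum())
    se = math.sqrt(sse / max(n - 2, 1) / sxx) if sxx > 0 else float("inf")
    return float(coef[0]), float(coef[1]), sse, se, r2


def segment_phases_fit(
    extension: np.ndarray,
    force: np.ndarray,
    min_bins_per_phase: int = 4,
    improvement: float = 0.05,
) -> PhaseFit:
    """Two-phase piecewise-linear fit by exhaustive breakpoint search.

    Every candidate breakpoint with at least ``min_bins_per_phase`` bins on
    each side is scored by the summed SSE of two independent least-squares
    lines (the breakpoint bin is assigned to phase II); the minimizer wins.
    If no candidate is valid, or the best two-segment fit does not improve
    the single-line SSE by at least the ``improvement`` fraction, a
    single-phase result is returned with ``single_phase=True``.  Slopes
    are in pN/nm ≡ mN/m.
    """
    x = np.asarray(extension, dtype=float)
    y = np.asarray(force, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 bins, got {len(x)}")
    order = np.argsort(x)
    x, y = x[order], y[order]
    k1_all, b1_all, sse_all, se_all, r2_all = _ols(x, y)

    best = None
    for cut in range(min_bins_per_phase, len(x) - min_bins_per_phase + 1):
        xa, ya = x[:cut], y[:cut]
        xb, yb = x[cut:], y[cut:]
        k1, b1, s1, e1, r1 = _ols(xa, ya)
        k2, b2, s2, e2, r2 = _ols(xb, yb)
        total = s1 + s2
        if best is None or total < best[0]:
            best = (total, cut, (k1, b1, e1, r1), (k2, b2, e2, r2))
    sst = float(((y - y.mean()) ** 2).sum())
    already_linear = sse_all <= 1e-10 * max(sst, 1e-300)
    if best is None or already_linear or best[0] > (1.0 - improvement) * sse_all:
        return PhaseFit(
            breakpoint_extension=None,
            k_phase1=k1_all,
            k_phase2=None,
            intercepts=(b1_all, None),
            stderr=(se_all, None),
            r_squared=(r2_all, None),
            single_phase=True,
        )
    _, cut, (k1, b1, e1, r1), (k2, b2, e2, r2) = best
    return PhaseFit(
        breakpoint_extension=float(x[cut]),
        k_phase1=k1,
        k_phase2=k2,
        intercepts=(b1, b2),
        stderr=(e1, e2),
        r_squared=(r1, r2),
        single_phase=False,
    )


def detect_force_peaks(trace: ForceTrace, prominence: float = 50.0) -> list[ForcePeak]:
    """Local force maxima with at least ``prominence`` pN of prominence.

    Expects a smoothed trace.  The drop is the apex force minus the lowest
    force before the next peak (or the end of the trace).  A monotonic
    trace yields an empty list.
    """
    idx, props = signal.find_peaks(trace.force, prominence=prominence)
    peaks: list[ForcePeak] = []
    for j, i in enumerate(idx):
        nxt = idx[j + 1] if j + 1 < len(idx) else len(trace.force)
        following_min = float(trace.force[i:nxt].min())
        peaks.append(
            ForcePeak(
                extension=float(trace.extension[i]),
                time=float(trace.time[i]),
                height=float(trace.force[i]),
                drop=float(trace.force[i]) - following_min,
                prominence=float(props["prominences"][j]),
            )
        )
    return peaks


def detect_ruptures(
    series: MetricSeries,
    cutoff: float = 4.0,
    sustain_ns: float = 0.5,
) -> list[float]:
    """Rupture times (ns) on a heavy-atom distance monitor.

    A rupture is the first crossing of ``cutoff`` (Å, default 4.0) that
    stays above the cutoff for at least ``sustain_ns``; re-formation
    (dropping back below the cutoff) re-arms the detector.
    """
    t = series.times
    above = series.values > cutoff
    events: list[float] = []
    i = 0
    n = len(t)
    while i < n:
        if above[i] and (i == 0 or not above[i - 1]):
            j = i
            while j < n and above[j]:
                j += 1
            sustained_until = t[j - 1] if j == n else t[j]
            if sustained_until - t[i] >= sustain_ns:
                events.append(float(t[i]))
            i = j
        else:
            i += 1
    return events


def correlate_events(
    peaks: list[ForcePeak],
    rupture_times: list[float],
    tolerance_ns: float,
) -> dict:
    """Greedy nearest-in-time matching of force peaks to rupture events.

    Pairs are formed closest-first within ``tolerance_ns``; each peak and
    each rupture is used at most once.  Returns matched pairs plus the
    unmatched leftovers, and annotates matched peaks in place.
    """
    if tolerance_ns < 0:
        raise ValueError("tolerance must be non-negative")
    candidates = sorted(
        (
            (abs(p.time - rt), pi, ri)
            for pi, p in enumerate(peaks)
            for ri, rt in enumerate(rupture_times)
            if abs(p.time - rt) <= tolerance_ns
        )
    )
    used_p: set[int] = set()
    used_r: set[int] = set()
    matched: list[tuple[ForcePeak, float]] = []
    for _, pi, ri in candidates:
        if pi in used_p or ri in used_r:
            continue
        used_p.add(pi)
        used_r.add(ri)
        peaks[pi].matched_rupture = rupture_times[ri]
        matched.append((peaks[pi], rupture_times[ri]))
    return {
        "matched": matched,
        "unmatched_peaks": [p for i, p in enumerate(peaks) if i not in used_p],
        "unmatched_ruptures": [r for i, r in enumerate(rupture_times) if i not in used_r],
    }


# exact unit conversions to the base pN/nm (≡ mN/m);
# kcal = 4184 J and N_A = 6.02214076e23 are exact
_TO_PN_PER_NM = {
    "kcal_mol_A2": 4184.0 / 6.02214076e23 * 1.0e20 * 1.0e3,  # 694.786 pN/nm
    "pN_A": 10.0,
    "pN_nm": 1.0,
    "mN_m": 1.0,
    "N_m": 1000.0,
}


def convert_spring_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact dimensional conversion between spring-constant units.

    Units: ``kcal_mol_A2``, ``pN_A``, ``pN_nm``, ``mN_m``, ``N_m``.
    1 kcal mol⁻¹ Å⁻² = 69.479 pN/Å; 1 pN/nm = 1 mN/m.
    """
    try:
        f = _TO_PN_PER_NM[from_unit]
        t = _TO_PN_PER_NM[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown unit {exc.args[0]!r}; known: {sorted(_TO_PN_PER_NM)}"
        ) from None
    return value * f / t
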