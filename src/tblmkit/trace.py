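"""Capacitance and three-region conductance extraction from V-I ramp traces.

A stepped voltage ramp applied across a tethered bilayer produces a current
with two components: a constant capacitive charging current ``C * dV/dt`` and
a voltage-dependent conductive current through membrane pores.  The
conductive part is approximately piecewise linear in voltage — a low-voltage
ohmic region, a transition region, and a high-voltage ohmic region — so the
analysis here is (1) read the membrane capacitance off the ramp onset,
(2) subtract the capacitive pedestal, and (3) find the two breakpoints and
regional conductances by exhaustive two-breakpoint least squares on the
sampled voltage grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    ComparabilityError,
    DegenerateTraceError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "VITrace",
    "SegmentedVI",
    "SpecificQuantity",
    "EffectSummary",
    "estimate_capacitance",
    "segment_vi",
    "to_specific",
    "compare_conditions",
]

#: Relative SSE tolerance for breakpoint ties; see segment_vi docstring.
SSE_TIE_RTOL = 1e-10


@dataclass
class VITrace:
    """A sampled voltage-ramp current record.

    ``voltage`` must be non-decreasing on the rising limb; a symmetric
    falling limb (triangular ramp) may follow the maximum and is ignored by
    the analysis operations, which act on :meth:`rising_limb`.
    """

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    ramp_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        n = len(self.time)
        if not (len(self.voltage) == len(self.current) == n):
            raise ValidationError(
                "time/voltage/current: arrays must have equal length"
            )
        if n < 4:
            raise ValidationError("time: trace needs at least 4 samples")
        if not np.isfinite(self.ramp_rate) or self.ramp_rate <= 0:
            raise ValidationError("ramp_rate: must be finite and > 0")
        peak = int(np.argmax(self.voltage))
        rising = self.voltage[: peak + 1]
        if np.any(np.diff(rising) < 0):
            raise ValidationError(
                "voltage: must be non-decreasing on the rising limb"
            )

    def __len__(self) -> int:
        return len(self.time)

    def rising_limb(self) -> "VITrace":
        """The trace up to (and including) the voltage maximum."""
        peak = int(np.argmax(self.voltage))
        if peak == len(self.voltage) - 1:
            return self
        sl = slice(0, peak + 1)
        return VITrace(self.time[sl], self.voltage[sl], self.current[sl],
                       self.ramp_rate)


@dataclass
class SegmentedVI:
    """Three-region segmentation of a V-I trace.

    ``g_low``/``g_high`` are the fitted slopes (conductances, S) of the
    low- and high-voltage linear regions of the conductive current;
    ``breakpoints`` bound the transition region; ``fit_sse`` is the summed
    squared residual of the two linear fits (A^2).
    """

    capacitance: float
    breakpoints: tuple
    g_low: float
    g_high: float
    intercept_low: float
    intercept_high: float
    fit_sse: float
    ramp_rate: Optional[float] = None
    n_low: int = 0
    n_high: int = 0

    def __post_init__(self) -> None:
        v1, v2 = self.breakpoints
        if v1 > v2:
            raise ValidationError("breakpoints: require v1 <= v2")
        if not self.capacitance > 0:
            raise ValidationError("capacitance: must be > 0")
        if self.g_low < 0 or self.g_high < 0:
            warnings.warn(
                "fitted conductance is negative; physically a conductance is "
                ">= 0 — noise may dominate this trace",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SpecificQuantity:
    """A total electrical quantity and its per-area (specific) value."""

    total: float
    area: float
    specific: float
    unit: str = "S"

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError("area: must be > 0")


@dataclass(frozen=True)
class EffectSummary:
    """Signed differences (b - a) between two segmentations."""

    d_capacitance: float
    d_g_low: float
    d_g_high: float
    rel_capacitance: float
    rel_g_low: float
    rel_g_high: float


def estimate_capacitance(
    trace: VITrace,
    n_onset_steps: int = 1,
    g_estimate: float = 0.0,
) -> float:
    """Membrane capacitance from the capacitive onset current.

    The current at the start of the ramp is ``C * dV/dt`` plus a (by
    construction negligible) conductive term ``g * V``; the mean current over
    the first ``n_onset_steps`` samples, corrected by ``g_estimate * V``,
    divided by the ramp rate gives C.

    Parameters
    ----------
    n_onset_steps
        Number of leading samples to average, between 1 and 5.  The default
        of 1 suffices because each sample is already an average over the
        instrument's post-increment window.
    g_estimate
        Conductance used to remove the conductive contribution at the onset
        voltages; pass the low-region slope from a previous fit, or leave 0.
    """
    if not 1 <= n_onset_steps <= 5:
        raise ValidationError("n_onset_steps: must be between 1 and 5")
    limb = trace.rising_limb()
    v = limb.voltage[:n_onset_steps]
    i = limb.current[:n_onset_steps]
    onset = float(np.mean(i - g_estimate * v))
    if onset <= 0:
        raise DegenerateTraceError(
            "onset current is non-positive; no capacitive charging signal"
        )
    return onset / trace.ramp_rate


def transition_basis(v: np.ndarray, v1: float, v2: float):
    """Basis functions (f1, f2) of the three-region conductive model.

    The continuous model — slope g_low through the origin for V <= v1, slope
    g_high for V >= v2, C1 monotone Hermite cubic in between (endpoint value
    at v2 fixed by the mean slope) — is linear in the two conductances:
    I_cond(V) = g_low * f1(V) + g_high * f2(V).  These are those basis
    columns; for v1 == v2 the bridge degenerates to a kink.
    """
    v = np.asarray(v, dtype=float)
    if v2 > v1:
        h = v2 - v1
        t = np.clip((v - v1) / h, 0.0, 1.0)
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t * t * (3 - 2 * t)
        h11 = t * t * (t - 1)
        f1_mid = h00 * v1 + h10 * h + h01 * (v1 + 0.5 * h)
        f2_mid = (0.5 * h01 + h11) * h
        f1 = np.where(v <= v1, v,
                      np.where(v >= v2, v1 + 0.5 * h, f1_mid))
        f2 = np.where(v <= v1, 0.0,
                      np.where(v >= v2, 0.5 * h + (v - v2), f2_mid))
    else:
        f1 = np.minimum(v, v1)
        f2 = np.maximum(v - v1, 0.0)
    return f1, f2


def segment_vi(
    trace: VITrace,
    capacitance: Optional[float] = None,
    min_segment_points: int = 3,
) -> SegmentedVI:
    """Exhaustive two-breakpoint least-squares segmentation.

    The capacitive pedestal ``C * dV/dt`` is subtracted first (C estimated
    from the onset unless supplied).  Then, for every ordered breakpoint
    pair (v1, v2) on the sampled voltage grid with at least
    ``min_segment_points`` samples in each flanking region, the continuous
    three-region model — low-voltage line, C1 cubic transition, high-voltage
    line (see :func:`transition_basis`) — is fitted to *all* samples by
    ordinary least squares (the model is linear in the intercept and the two
    conductances once the pair is fixed).  The pair minimising the total
    squared residual wins; objectives within ``SSE_TIE_RTOL`` times the
    trace's total centered sum of squares are treated as tied, and ties go
    to the pair whose linear regions cover the most samples, then to the
    smallest v1.

    Fitting all samples (rather than the flanking segments alone) matters
    under noise: a flanking-only residual can always be shrunk by shrinking
    the segments, and it silently absorbs transition samples whose curvature
    is below the noise floor, biasing both slopes and breakpoints.  The full
    model is the maximum-likelihood fit and keeps noise-free recovery exact.
    Because the search is exhaustive on the data's own voltage grid it *is*
    the global optimum at the data's resolution.
    """
    limb = trace.rising_limb()
    n = len(limb)
    if n < 10:
        raise InsufficientDataError(
            f"segmentation needs >= 10 rising-limb samples, got {n}"
        )
    if np.any(np.diff(limb.voltage) <= 0):
        raise ValidationError(
            "voltage: rising limb must be strictly increasing for segmentation"
        )

    own_capacitance = capacitance is None
    cm = estimate_capacitance(trace) if own_capacitance else float(capacitance)

    v = limb.voltage
    for _refine in range(2):
        cond = limb.current - cm * trace.ramp_rate
        result = _search_breakpoints(v, cond, min_segment_points)
        if not own_capacitance or _refine == 1 or result[0] is None:
            break
        # second pass: remove the (small) conductive contamination at onset
        g_low = result[3]
        cm = estimate_capacitance(trace, g_estimate=max(g_low, 0.0))

    (i1, j2, c0, g_low, g_high, sse) = result
    if i1 is None:  # all-flat conductive trace
        vmed = float(np.median(v))
        return SegmentedVI(
            capacitance=cm, breakpoints=(vmed, vmed), g_low=0.0, g_high=0.0,
            intercept_low=float(np.mean(cond)),
            intercept_high=float(np.mean(cond)),
            fit_sse=0.0, ramp_rate=trace.ramp_rate, n_low=n, n_high=n,
        )
    v1, v2 = float(v[i1]), float(v[j2])
    h = v2 - v1
    # high-voltage line: y = c0 + g_low*(v1 + h/2) + g_high*(h/2 + V - v2)
    intercept_high = c0 + g_low * (v1 + 0.5 * h) + g_high * (0.5 * h - v2)
    return SegmentedVI(
        capacitance=cm,
        breakpoints=(v1, v2),
        g_low=float(g_low), g_high=float(g_high),
        intercept_low=float(c0), intercept_high=float(intercept_high),
        fit_sse=float(sse), ramp_rate=trace.ramp_rate,
        n_low=int(i1 + 1), n_high=int(n - j2),
    )


def _transition_basis_many(v: np.ndarray, v1: float, v2s: np.ndarray):
    """:func:`transition_basis` broadcast over many v2 values (rows)."""
    n, m = len(v), len(v2s)
    f1 = np.empty((m, n))
    f2 = np.empty((m, n))
    pos = v2s > v1
    if pos.any():
        h = (v2s[pos] - v1)[:, None]
        t = np.clip((v[None, :] - v1) / h, 0.0, 1.0)
        h00 = (1 + 2 * t) * (1 - t) ** 2
        h10 = t * (1 - t) ** 2
        h01 = t * t * (3 - 2 * t)
        h11 = t * t * (t - 1)
        f1_mid = h00 * v1 + h10 * h + h01 * (v1 + 0.5 * h)
        f2_mid = (0.5 * h01 + h11) * h
        low = v[None, :] <= v1
        high = v[None, :] >= v2s[pos][:, None]
        f1[pos] = np.where(low, v[None, :],
                           np.where(high, v1 + 0.5 * h, f1_mid))
        f2[pos] = np.where(low, 0.0,
                           np.where(high, 0.5 * h + (v[None, :]
                                                     - v2s[pos][:, None]),
                                    f2_mid))
    if (~pos).any():
        f1[~pos] = np.minimum(v, v1)[None, :]
        f2[~pos] = np.maximum(v - v1, 0.0)[None, :]
    return f1, f2


def _search_breakpoints(v: np.ndarray, y: np.ndarray, min_pts: int):
    """Core exhaustive search on strictly increasing voltages.

    Returns (i1, j2, c0, g_low, g_high, sse) with v1 = v[i1], v2 = v[j2] and
    (c0, g_low, g_high) the OLS coefficients of the full three-region model
    on all samples; or (None,) * 6 for an all-flat trace.
    """
    n = len(v)
    ycen = y - np.mean(y)
    syy_total = float(np.dot(ycen, ycen))
    if np.ptp(y) <= 1e-12 * max(np.max(np.abs(y)), 1e-300):
        return (None,) * 6

    sy = float(np.sum(y))
    syy = float(np.dot(y, y))
    i_vals = np.arange(min_pts - 1, n - min_pts + 1)   # index of v1

    sse_all, beta_all, ij_all = [], [], []
    for i1 in i_vals:
        v1 = v[i1]
        j_vals = np.arange(i1, n - min_pts + 1)        # index of v2
        f1, f2 = _transition_basis_many(v, v1, v[j_vals])
        # normal equations for X = [1, f1, f2], solved for all j at once
        a = np.empty((len(j_vals), 3, 3))
        b = np.empty((len(j_vals), 3))
        a[:, 0, 0] = n
        a[:, 0, 1] = a[:, 1, 0] = f1.sum(axis=1)
        a[:, 0, 2] = a[:, 2, 0] = f2.sum(axis=1)
        a[:, 1, 1] = np.einsum("kn,kn->k", f1, f1)
        a[:, 1, 2] = a[:, 2, 1] = np.einsum("kn,kn->k", f1, f2)
        a[:, 2, 2] = np.einsum("kn,kn->k", f2, f2)
        b[:, 0] = sy
        b[:, 1] = f1 @ y
        b[:, 2] = f2 @ y
        try:
            beta = np.linalg.solve(a, b[..., None])[..., 0]
        except np.linalg.LinAlgError:  # singular pair somewhere: go one by one
            beta = np.stack([np.linalg.lstsq(
                np.column_stack([np.ones(n), f1[k], f2[k]]), y, rcond=None
            )[0] for k in range(len(j_vals))])
        sse_all.append(np.maximum(syy - np.einsum("kp,kp->k", beta, b), 0.0))
        beta_all.append(beta)
        ij_all.append(np.column_stack([np.full_like(j_vals, i1), j_vals]))

    sse = np.concatenate(sse_all)
    beta = np.vstack(beta_all)
    ij = np.vstack(ij_all)

    tol = SSE_TIE_RTOL * syy_total
    tied = sse <= float(np.min(sse)) + tol
    coverage = (ij[:, 0] + 1) + (n - ij[:, 1])
    # among ties: widest coverage, then smallest v1 (i1), then smallest v2
    order = np.lexsort((ij[:, 1], ij[:, 0], -coverage))
    pick = order[tied[order]][0]
    i1, j2 = int(ij[pick, 0]), int(ij[pick, 1])
    return (i1, j2, float(beta[pick, 0]), float(beta[pick, 1]),
            float(beta[pick, 2]), float(sse[pick]))


def to_specific(total: float, area: float, unit: str = "S") -> SpecificQuantity:
    """Normalize a total conductance (S) or capacitance (F) by electrode area.

    >>> round(to_specific(24e-9, 2.1e-6, unit="F").specific, 4)
    0.0114
    """
    if not area > 0:
        raise ValidationError("area: must be > 0")
    return SpecificQuantity(total=float(total), area=float(area),
                            specific=float(total) / float(area), unit=unit)


def to_total(specific: float, area: float) -> float:
    """Inverse of :func:`to_specific` (exact)."""
    if not area > 0:
        raise ValidationError("area: must be > 0")
    return specific * area


def compare_conditions(a: SegmentedVI, b: SegmentedVI) -> EffectSummary:
    """Differences (b - a) in capacitance and regional conductances.

    Both segmentations must come from traces recorded under the same ramp
    protocol; a ramp-rate mismatch raises :class:`ComparabilityError`.
    Relative differences are with respect to ``a`` (NaN where a is 0).
    """
    if (a.ramp_rate is not None and b.ramp_rate is not None
            and not np.isclose(a.ramp_rate, b.ramp_rate, rtol=1e-9)):
        raise ComparabilityError(
            f"ramp_rate mismatch: {a.ramp_rate} vs {b.ramp_rate} V/s"
        )

    def rel(x, ref):
        return x / ref if ref != 0 else float("nan")

    return EffectSummary(
        d_capacitance=b.capacitance - a.capacitance,
        d_g_low=b.g_low - a.g_low,
        d_g_high=b.g_high - a.g_high,
        rel_capacitance=rel(b.capacitance - a.capacitance, a.capacitance),
        rel_g_low=rel(b.g_low - a.g_low, a.g_low),
        rel_g_high=rel(b.g_high - a.g_high, a.g_high),
    )
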