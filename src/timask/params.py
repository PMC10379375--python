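"""Phase segmentation of an averaged TI curve and the 14 TI parameters.

A TI curve is segmented into an increasing phase, an optional plateau
around the maximum, and a decreasing phase.  The 14 scalar descriptors
are:

========  =====================================================
Tstart    onset of sensation (s)
Tend      end of sensation (s)
Imax      maximum intensity (a.u.)
TsPl      plateau start (s)
TePl      plateau end (s)
DurPl     plateau duration (s)
DurInc    increasing-phase duration (s)
DurDec    decreasing-phase duration (s)
SIMInc    maximum slope in the increasing phase (a.u./s)
SIMDec    maximum decreasing-phase slope magnitude (a.u./s, positive)
AreaTse   total area under the curve (a.u.*s)
AreaInc   area under the increasing phase (a.u.*s)
AreaDec   area under the decreasing phase (a.u.*s)
AreaPl    area under the plateau phase (a.u.*s)
========  =====================================================

Onset/offset thresholds and the plateau criterion are not part of any
published standard (commercial TI software keeps them internal), so every
tunable here is an explicit, logged argument with a documented default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .errors import FlatCurveError, ParameterError, UsageError
from .io import PARAMETER_NAMES


@dataclass
class TIParameters:
    """The 14 named scalars extracted from one averaged TI curve."""

    Tstart: float
    Tend: float
    Imax: float
    TsPl: float
    TePl: float
    DurPl: float
    DurInc: float
    DurDec: float
    SIMInc: float
    SIMDec: float
    AreaTse: float
    AreaInc: float
    AreaDec: float
    AreaPl: float

    def __post_init__(self) -> None:
        for f in fields(self):
            setattr(self, f.name, float(getattr(self, f.name)))
        if not self.Tstart <= self.TsPl <= self.TePl <= self.Tend:
            raise ValueError(
                f"phase boundaries out of order: Tstart={self.Tstart}, "
                f"TsPl={self.TsPl}, TePl={self.TePl}, Tend={self.Tend}"
            )
        for name in ("DurPl", "DurInc", "DurDec", "AreaTse", "AreaInc", "AreaDec", "AreaPl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        parts = self.AreaInc + self.AreaPl + self.AreaDec
        if parts > 0 and not math.isclose(self.AreaTse, parts, rel_tol=1e-6):
            raise ValueError(f"AreaTse={self.AreaTse} != AreaInc+AreaPl+AreaDec={parts}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def detect_onset_offset(
    curve, eps_i: float = 1.0, min_dur_s: float = 2.0
) -> tuple[float, float]:
    """Detect the onset (Tstart) and offset (Tend) of sensation.

    Tstart is the first sampled time whose intensity exceeds ``eps_i`` and
    stays above it for at least ``min_dur_s``; Tend is the symmetric last
    such time scanning backwards.  The sustain requirement keeps isolated
    noise blips from opening or closing the sensation window.
    """
    if eps_i <= 0:
        raise ParameterError(f"eps_i must be > 0, got {eps_i}")
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.intensities, dtype=float)
    dt = t[1] - t[0]
    n_min = max(1, int(math.ceil(min_dur_s / dt)))
    above = y > eps_i
    if not above.any():
        raise FlatCurveError(
            f"curve {getattr(curve, 'material_id', '?')}: no sample exceeds eps_i={eps_i}"
        )
    # runs of consecutive above-threshold samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]  # [start, stop) pairs
    long_enough = (stops - starts) >= n_min
    if not long_enough.any():
        raise FlatCurveError(
            f"curve {getattr(curve, 'material_id', '?')}: no excursion above "
            f"eps_i={eps_i} is sustained for {min_dur_s} s"
        )
    first = starts[long_enough][0]
    last = stops[long_enough][-1] - 1
    return float(t[first]), float(t[last])


def detect_plateau(
    curve,
    Tstart: float,
    Tend: float,
    eps_pl: float = 0.002,
    min_plateau_s: float = 3.0,
) -> tuple[float, float]:
    """Find the plateau interval around the curve maximum.

    The plateau is the maximal contiguous interval containing the global
    argmax (earliest sample on ties) on which the intensity stays within a
    fraction ``eps_pl`` of Imax.  If that interval is shorter than
    ``min_plateau_s`` the plateau collapses to the single peak time, i.e.
    TsPl = TePl and the plateau duration/area are zero.
    """
    if not 0 < eps_pl < 1:
        raise ParameterError(f"eps_pl must lie in (0, 1), got {eps_pl}")
    if Tstart is None or Tend is None:
        raise UsageError("detect_plateau requires onset/offset; run detect_onset_offset first")
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.intensities, dtype=float)
    lo = int(np.searchsorted(t, Tstart, side="left"))
    hi = int(np.searchsorted(t, Tend, side="right"))
    win = y[lo:hi]
    imax = float(win.max())
    peak = lo + int(np.argmax(win))  # earliest argmax on ties
    near = y >= (1.0 - eps_pl) * imax
    a = peak
    while a > lo and near[a - 1]:
        a -= 1
    b = peak
    while b < hi - 1 and near[b + 1]:
        b += 1
    if t[b] - t[a] < min_plateau_s:
        return float(t[peak]), float(t[peak])
    return float(t[a]), float(t[b])


def phase_parameters(
    curve, Tstart: float, TsPl: float, TePl: float, Tend: float
) -> TIParameters:
    """Compute the 14 parameters between given phase boundaries.

    Boundaries must lie on the sampling grid.  Areas use the trapezoidal
    rule on [Tstart, TsPl], [TsPl, TePl] and [TePl, Tend]; AreaTse is their
    sum, so additivity holds exactly.  Slopes are consecutive-sample
    forward differences; SIMDec is reported as a positive magnitude.
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.intensities, dtype=float)
    dt = t[1] - t[0]

    def _idx(time: float) -> int:
        i = int(round((time - t[0]) / dt))
        if not 0 <= i < t.size or abs(t[i] - time) > 1e-6:
            raise ParameterError(f"boundary {time} s does not lie on the sampling grid")
        return i

    i0, i1, i2, i3 = _idx(Tstart), _idx(TsPl), _idx(TePl), _idx(Tend)
    if not i0 <= i1 <= i2 <= i3:
        raise ParameterError("phase boundaries must be ordered Tstart <= TsPl <= TePl <= Tend")
    imax = float(y[i0 : i3 + 1].max())
    diffs = np.diff(y) / dt
    inc = diffs[i0:i1]
    dec = diffs[i2:i3]
    sim_inc = float(inc.max()) if inc.size else 0.0
    neg = dec[dec < 0]
    sim_dec = float(-neg.min()) if neg.size else 0.0
    area_inc = float(np.trapezoid(y[i0 : i1 + 1], t[i0 : i1 + 1]))
    area_pl = float(np.trapezoid(y[i1 : i2 + 1], t[i1 : i2 + 1]))
    area_dec = float(np.trapezoid(y[i2 : i3 + 1], t[i2 : i3 + 1]))
    return TIParameters(
        Tstart=Tstart, Tend=Tend, Imax=imax, TsPl=TsPl, TePl=TePl,
        DurPl=TePl - TsPl, DurInc=TsPl - Tstart, DurDec=Tend - TePl,
        SIMInc=sim_inc, SIMDec=sim_dec,
        AreaTse=area_inc + area_pl + area_dec,
        AreaInc=area_inc, AreaDec=area_dec, AreaPl=area_pl,
    )


def extract(
    curve,
    *,
    eps_i: float = 1.0,
    min_dur_s: float = 2.0,
    eps_pl: float = 0.002,
    min_plateau_s: float = 3.0,
) -> TIParameters:
    """Segment ``curve`` and extract the 14 TI parameters."""
    tstart, tend = detect_onset_offset(curve, eps_i=eps_i, min_dur_s=min_dur_s)
    tspl, tepl = detect_plateau(curve, tstart, tend, eps_pl=eps_pl, min_plateau_s=min_plateau_s)
    return phase_parameters(curve, tstart, tspl, tepl, tend)


def quick_landmarks(
    curve,
    *,
    eps_i: float = 1.0,
    min_dur_s: float = 2.0,
    eps_pl: float = 0.002,
    min_plateau_s: float = 3.0,
) -> tuple[float, float, float]:
    """Cheap (Imax, TsPl, Tend) triple used for representative selection."""
    tstart, tend = detect_onset_offset(curve, eps_i=eps_i, min_dur_s=min_dur_s)
    tspl, _ = detect_plateau(curve, tstart, tend, eps_pl=eps_pl, min_plateau_s=min_plateau_s)
    t = np.asarray(curve.times)
    y = np.asarray(curve.intensities)
    lo = int(np.searchsorted(t, tstart))
    hi = int(np.searchsorted(t, tend, side="right"))
    return float(y[lo:hi].max()), tspl, tend
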