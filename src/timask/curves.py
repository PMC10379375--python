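"""Replicate-curve processing: smoothing, representative selection, averaging.

A raw panel produces several replicate TI curves per material (and
panelist).  The processing chain mirrors standard TI practice: smooth each
replicate, keep the most *intermediate* replicates (discarding outlying
runs), and average the survivors point-wise into a single curve per
material from which the TI parameters are read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ParameterError, ValidationError
from .io import TICurve


@dataclass
class AverageCurve:
    """Point-wise mean of selected replicate curves for one material."""

    material_id: str
    times: np.ndarray
    intensities: np.ndarray
    n_replicates_used: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.n_replicates_used < 1:
            raise ValidationError(f"{self.material_id}: n_replicates_used must be >= 1")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _shrinking_moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically at the ends."""
    n = y.size
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(y)))
    return (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)


def smooth(curve: TICurve, window_s: int = 5) -> TICurve:
    """Smooth a replicate curve with a centered moving average.

    ``window_s`` must be an odd number of samples (seconds at 1 Hz).  At the
    boundaries the window shrinks symmetrically so the output keeps the
    input grid; the result is clipped to [0, 100].
    """
    window_s = int(window_s)
    if window_s < 1 or window_s % 2 == 0:
        raise ParameterError(f"smoothing window must be an odd integer >= 1, got {window_s}")
    sm = np.clip(_shrinking_moving_average(curve.intensities, window_s), 0.0, 100.0)
    return TICurve(curve.material_id, curve.panelist_id, curve.replicate,
                   curve.times.copy(), sm)


def select_representatives(
    replicates: list[TICurve],
    n_keep: int = 3,
    *,
    smooth_window_s: int = 5,
    eps_i: float = 1.0,
    min_dur_s: float = 2.0,
    eps_pl: float = 0.002,
    min_plateau_s: float = 3.0,
    presmoothed: bool = False,
) -> list[TICurve]:
    """Keep the ``n_keep`` most intermediate replicates of one material.

    Each replicate is smoothed and summarized by three landmark parameters
    (Imax, TsPl, Tend).  For each landmark the replicates are mid-ranked and
    the absolute distance of each rank from the median rank is taken; the
    ``n_keep`` replicates with the smallest summed rank distance are kept
    (ties broken by lower replicate index).  The selection is returned in
    the original input order; the returned curves are the *unsmoothed*
    inputs.
    """
    from .params import quick_landmarks  # deferred: params is downstream of curves

    if n_keep < 1:
        raise ParameterError(f"n_keep must be >= 1, got {n_keep}")
    if len(replicates) < n_keep:
        mat = replicates[0].material_id if replicates else "<empty>"
        raise ValidationError(
            f"material {mat}: {len(replicates)} replicates but n_keep={n_keep}"
        )
    landmarks = np.empty((len(replicates), 3))
    for i, rep in enumerate(replicates):
        sm = rep if presmoothed else smooth(rep, smooth_window_s)
        landmarks[i] = quick_landmarks(
            sm, eps_i=eps_i, min_dur_s=min_dur_s,
            eps_pl=eps_pl, min_plateau_s=min_plateau_s,
        )
    total = np.zeros(len(replicates))
    for j in range(3):
        ranks = rankdata(landmarks[:, j], method="average")
        total += np.abs(ranks - np.median(ranks))
    rep_idx = np.array([r.replicate for r in replicates])
    order = np.lexsort((np.arange(len(replicates)), rep_idx, total))
    keep = sorted(order[:n_keep])
    return [replicates[i] for i in keep]


def average_curves(selected, material_id: str | None = None) -> AverageCurve:
    """Point-wise arithmetic mean of curves sharing a 1 Hz grid origin.

    Shorter curves are zero-extended to the longest end time: intensity
    after the flavor sensation has disappeared is by definition 0.
    """
    selected = list(selected)
    if not selected:
        raise ValidationError("average_curves: empty curve list")
    dt = selected[0].dt
    for c in selected:
        if abs(c.times[0]) > 1e-9 or abs(c.dt - dt) > 1e-9:
            raise ValidationError("average_curves: curves must share a common grid from 0 s")
    n = max(c.times.size for c in selected)
    acc = np.zeros(n)
    for c in selected:
        acc[: c.times.size] += c.intensities
    mat = material_id if material_id is not None else selected[0].material_id
    return AverageCurve(mat, np.arange(n) * dt, acc / len(selected), len(selected))
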