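"""Synthetic TI-panel generator with closed-form parameter oracles.

Each material is a *ramp + exponential decay* archetype: intensity rises
linearly from ``t_start`` to ``i_peak`` over ``dur_inc`` seconds, then
decays as ``i_peak * exp(-t/tau)`` until it falls below ``cutoff``, where
the sensation ends.  This is the simplest curve family that controls the
increase-phase and decrease-phase descriptors independently, and every TI
parameter of such an archetype has a closed form — the oracle used by the
extraction tests.

Type-dependent parameter ranges emulate the qualitative release behavior
of the three material classes: oil-type materials release slowly and
persist (long ramps, slow decay), essence-type materials release fast and
vanish quickly (short ramps, fast decay), flavor-type materials sit in
between.  Panel noise enters as a per-panelist intensity-scale factor,
per-replicate onset jitter, and per-sample Gaussian noise.  VAS ratings
are linked to the archetype's closed-form AreaDec: materials with more
decay-phase exposure mask the off-flavor better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .errors import ParameterError
from .io import MaterialInfo, TICurve, VASRecord
from .params import TIParameters

#: Archetype parameter ranges per material type (uniform draws).
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "oil": {"dur_inc": (12.0, 22.0), "tau": (30.0, 60.0)},
    "essence": {"dur_inc": (4.0, 8.0), "tau": (8.0, 15.0)},
    "flavor": {"dur_inc": (8.0, 14.0), "tau": (15.0, 30.0)},
}
#: Ranges shared by all types.
SHARED_RANGES: dict[str, tuple[float, float]] = {
    "t_start": (4.0, 8.0),
    "i_peak": (30.0, 90.0),
}
DEFAULT_CUTOFF = 1.0


@dataclass
class Archetype:
    """Noiseless ramp-decay model of one material's flavor release."""

    mtype: str
    t_start: float
    dur_inc: float
    i_peak: float
    tau: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        for name in ("t_start", "dur_inc", "i_peak", "tau", "cutoff"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"archetype {name} must be > 0")
        if self.i_peak > 100:
            raise ParameterError(f"i_peak must be <= 100, got {self.i_peak}")
        if self.cutoff >= self.i_peak:
            raise ParameterError("cutoff must be below i_peak")


@dataclass
class SyntheticConfig:
    """Study-scale design: counts, noise levels and the masking link.

    Defaults mirror a full panel study: 100 materials (33 essence / 33 oil
    / 34 flavor), 10 panelists, 6 replicate curves per material and
    panelist, one VAS rating per material and panelist.  The masking link
    maps a material's closed-form AreaDec to its true masking score
    ``clip(beta0 + beta1 * AreaDec, 0, 10)``; each panelist reports
    ``clip(10 - score + N(0, rating_sd), 0, 10)`` as beany intensity.
    """

    n_essence: int = 33
    n_oil: int = 33
    n_flavor: int = 34
    n_panelists: int = 10
    n_replicates: int = 6
    ranges: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RANGES.items()})
    shared_ranges: dict = field(default_factory=lambda: dict(SHARED_RANGES))
    cutoff: float = DEFAULT_CUTOFF
    panelist_scale_sd: float = 0.15
    time_jitter_sd: float = 1.0
    intensity_noise_sd: float = 3.0
    beta0: float = 2.0
    beta1: float = 0.003
    rating_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize range containers so configs round-trip through YAML/JSON
        self.ranges = {
            mt: {k: tuple(float(x) for x in v) for k, v in rg.items()}
            for mt, rg in self.ranges.items()
        }
        self.shared_ranges = {
            k: tuple(float(x) for x in v) for k, v in self.shared_ranges.items()
        }
        for name in ("n_essence", "n_oil", "n_flavor", "n_panelists", "n_replicates"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("panelist_scale_sd", "time_jitter_sd", "intensity_noise_sd", "rating_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class SyntheticStudy:
    """In-memory synthetic study plus the generating truth."""

    materials: list[MaterialInfo]
    curves: list[TICurve]
    vas: list[VASRecord]
    truth: pd.DataFrame  # material_id, mtype, 14 closed-form params, true_score

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tio.write_materials(self.materials, out / "materials.csv")
        tio.write_curves(self.curves, out / "curves.csv")
        tio.write_vas(self.vas, out / "vas.csv")
        self.truth.to_csv(out / "truth.csv", index=False)


def sample_archetype(
    mtype: str,
    rng: np.random.Generator,
    ranges: dict | None = None,
    shared_ranges: dict | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> Archetype:
    """Draw a material archetype from the type-specific uniform ranges."""
    ranges = ranges if ranges is not None else DEFAULT_RANGES
    shared = shared_ranges if shared_ranges is not None else SHARED_RANGES
    if mtype not in ranges:
        raise ParameterError(f"unknown mtype {mtype!r}; known: {sorted(ranges)}")
    t_start = rng.uniform(*shared["t_start"])
    i_peak = rng.uniform(*shared["i_peak"])
    dur_inc = rng.uniform(*ranges[mtype]["dur_inc"])
    tau = rng.uniform(*ranges[mtype]["tau"])
    return Archetype(mtype, t_start, dur_inc, i_peak, tau, cutoff)


def closed_form_params(a: Archetype) -> TIParameters:
    """Exact continuous-time TI parameters of a noiseless archetype.

    The ramp contributes ``AreaInc = i_peak * dur_inc / 2`` and maximum
    slope ``i_peak / dur_inc``; the truncated exponential decay lasts
    ``tau * ln(i_peak / cutoff)`` seconds, has initial slope magnitude
    ``i_peak / tau`` and area ``tau * (i_peak - cutoff)``.  There is no
    plateau: the curve peaks at a single instant.
    """
    t_peak = a.t_start + a.dur_inc
    dur_dec = a.tau * math.log(a.i_peak / a.cutoff)
    area_inc = 0.5 * a.i_peak * a.dur_inc
    area_dec = a.tau * (a.i_peak - a.cutoff)
    return TIParameters(
        Tstart=a.t_start, Tend=t_peak + dur_dec, Imax=a.i_peak,
        TsPl=t_peak, TePl=t_peak, DurPl=0.0,
        DurInc=a.dur_inc, DurDec=dur_dec,
        SIMInc=a.i_peak / a.dur_inc, SIMDec=a.i_peak / a.tau,
        AreaTse=area_inc + area_dec, AreaInc=area_inc, AreaDec=area_dec, AreaPl=0.0,
    )


def render_curve(
    a: Archetype,
    panelist_scale: float = 1.0,
    time_jitter: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    material_id: str = "synthetic",
    panelist_id: str = "p01",
    replicate: int = 1,
    trailing_zeros_s: int = 3,
) -> TICurve:
    """Sample one noisy replicate of an archetype at 1 Hz.

    ``panelist_scale`` multiplies the peak intensity, ``time_jitter``
    shifts the onset (s), and Gaussian noise of sd ``noise_sd`` is added
    wherever the underlying model is non-zero (a panelist does not move
    the cursor before the sensation starts or after it ends).  The result
    is clipped to [0, 100].
    """
    if noise_sd > 0 and rng is None:
        raise ParameterError("render_curve needs an rng when noise_sd > 0")
    t0 = max(0.0, a.t_start + time_jitter)
    peak = float(np.clip(panelist_scale * a.i_peak, 0.0, 100.0))
    if peak <= a.cutoff:
        peak = a.cutoff * 1.5  # a barely-perceived sample still produces a curve
    t_peak = t0 + a.dur_inc
    t_end = t_peak + a.tau * math.log(peak / a.cutoff)
    times = np.arange(0.0, math.ceil(t_end) + trailing_zeros_s + 1.0)
    y = np.zeros_like(times)
    ramp = (times >= t0) & (times <= t_peak)
    y[ramp] = (times[ramp] - t0) / a.dur_inc * peak
    decay = times > t_peak
    y[decay] = peak * np.exp(-(times[decay] - t_peak) / a.tau)
    y[y < a.cutoff] = 0.0
    if noise_sd > 0:
        nz = y > 0
        y[nz] += rng.normal(0.0, noise_sd, size=int(nz.sum()))
    y = np.clip(y, 0.0, 100.0)
    return TICurve(material_id, panelist_id, replicate, times, y)


def generate_vas(
    a: Archetype,
    n_panelists: int,
    rng: np.random.Generator,
    beta0: float = 2.0,
    beta1: float = 0.003,
    rating_sd: float = 1.0,
    material_id: str = "synthetic",
    panelist_ids: list[str] | None = None,
) -> list[VASRecord]:
    """Panel VAS ratings with masking linked to the archetype's AreaDec."""
    area_dec = closed_form_params(a).AreaDec
    true_score = float(np.clip(beta0 + beta1 * area_dec, 0.0, 10.0))
    if panelist_ids is None:
        panelist_ids = [f"p{i + 1:02d}" for i in range(n_panelists)]
    noise = rng.normal(0.0, rating_sd, size=n_panelists) if rating_sd > 0 else np.zeros(n_panelists)
    return [
        VASRecord(material_id, pid, float(np.clip(10.0 - true_score + e, 0.0, 10.0)))
        for pid, e in zip(panelist_ids, noise)
    ]


def true_masking_score(a: Archetype, beta0: float = 2.0, beta1: float = 0.003) -> float:
    return float(np.clip(beta0 + beta1 * closed_form_params(a).AreaDec, 0.0, 10.0))


def generate_study(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticStudy:
    """Generate a fully seeded synthetic study.

    One archetype per material, one scale factor per panelist (a panelist
    uses the intensity scale consistently across materials), one onset
    jitter per replicate, per-sample intensity noise, and one VAS rating
    per material and panelist.  ``truth`` records each material's
    closed-form parameters and true masking score for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    plan = (
        [("essence", i) for i in range(cfg.n_essence)]
        + [("oil", i) for i in range(cfg.n_oil)]
        + [("flavor", i) for i in range(cfg.n_flavor)]
    )
    panelist_ids = [f"p{i + 1:02d}" for i in range(cfg.n_panelists)]
    scales = np.maximum(0.2, 1.0 + rng.normal(0.0, cfg.panelist_scale_sd, size=cfg.n_panelists))

    materials: list[MaterialInfo] = []
    curves: list[TICurve] = []
    vas: list[VASRecord] = []
    truth_rows = []
    for mtype, i in plan:
        mat_id = f"{mtype[:3]}{i + 1:03d}"
        arch = sample_archetype(mtype, rng, cfg.ranges, cfg.shared_ranges, cfg.cutoff)
        materials.append(MaterialInfo(mat_id, f"synthetic {mtype} {i + 1}", mtype, "synthetic"))
        cf = closed_form_params(arch)
        truth_rows.append(
            {"material_id": mat_id, "mtype": mtype, **cf.as_dict(),
             "true_score": true_masking_score(arch, cfg.beta0, cfg.beta1)}
        )
        for p_idx, pid in enumerate(panelist_ids):
            for rep in range(1, cfg.n_replicates + 1):
                jitter = rng.normal(0.0, cfg.time_jitter_sd) if cfg.time_jitter_sd > 0 else 0.0
                curves.append(
                    render_curve(
                        arch, panelist_scale=float(scales[p_idx]), time_jitter=jitter,
                        noise_sd=cfg.intensity_noise_sd, rng=rng,
                        material_id=mat_id, panelist_id=pid, replicate=rep,
                    )
                )
        vas.extend(
            generate_vas(arch, cfg.n_panelists, rng, cfg.beta0, cfg.beta1,
                         cfg.rating_sd, material_id=mat_id, panelist_ids=panelist_ids)
        )
    truth = pd.DataFrame(truth_rows)
    return SyntheticStudy(materials, curves, vas, truth)
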