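"""Beany-flavor masking scores from VAS ratings.

Each panelist rates the residual beany intensity of a sample on a 0-10
scale (100 mm VAS / 10).  A material's masking score is ``10 - median
beany intensity``: 10 means the off-flavor was completely suppressed, 0
means it came through as strongly as the plain control.  Medians are
taken over all ratings of a material with panelists pooled; scores are
reported to one decimal but kept at full precision internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .io import VASRecord


@dataclass
class MaskingResult:
    """Median beany intensity and masking score for one material."""

    material_id: str
    median_intensity: float
    masking_score: float
    n_ratings: int


def median_intensity(records: Sequence[VASRecord]) -> float:
    """Sample median of a material's ratings (midpoint rule for even counts)."""
    records = list(records)
    if not records:
        raise ValidationError("median_intensity: no VAS records supplied")
    mats = {r.material_id for r in records}
    if len(mats) > 1:
        raise ValidationError(f"median_intensity: records span several materials {sorted(mats)}")
    return float(np.median([r.beany_intensity for r in records]))


def masking_score(median: float) -> float:
    """10-point masking score: ``10 - median`` beany intensity."""
    if not 0.0 <= median <= 10.0:
        raise ParameterError(f"median intensity must lie in [0, 10], got {median}")
    return 10.0 - float(median)


def score_materials(records: Iterable[VASRecord]) -> list[MaskingResult]:
    """Per-material masking results, sorted by material_id."""
    by_mat: dict[str, list[VASRecord]] = {}
    for r in records:
        by_mat.setdefault(r.material_id, []).append(r)
    out = []
    for mat in sorted(by_mat):
        med = median_intensity(by_mat[mat])
        out.append(MaskingResult(mat, med, masking_score(med), len(by_mat[mat])))
    return out


def rank_materials(
    results: Sequence[MaskingResult], k: int
) -> tuple[list[MaskingResult], list[MaskingResult]]:
    """Top-k and bottom-k materials by masking score.

    Sorting is by descending score with ties broken by material_id.  When a
    score tie straddles the k boundary, *all* tied materials are included,
    so either list may hold more than ``k`` entries.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    results = list(results)
    if 2 * k > len(results):
        raise ParameterError(f"k={k} too large for {len(results)} materials (need 2k <= n)")

    def _take(ordered: list[MaskingResult]) -> list[MaskingResult]:
        cut = ordered[k - 1].masking_score
        out = list(ordered[:k])
        for r in ordered[k:]:
            if r.masking_score == cut:
                out.append(r)
            else:
                break
        return out

    top_sorted = sorted(results, key=lambda r: (-r.masking_score, r.material_id))
    bot_sorted = sorted(results, key=lambda r: (r.masking_score, r.material_id))
    return _take(top_sorted), _take(bot_sorted)
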