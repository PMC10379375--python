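"""Parameter-matrix statistics: standardization, correlation pruning and
the Mann-Whitney U comparison between top and bottom masking groups.

Highly collinear TI parameters carry no independent information, so the
materials x parameters matrix is pruned before group testing and
classification: columns whose pairwise Pearson ``|r|`` reaches a threshold
(default 0.98) are grouped and a single representative per group is kept.
No plateau phase was ever observed for these materials, so the two plateau
columns are dropped up front when they are identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ParameterError, ValidationError
from .io import PARAMETER_NAMES
from .masking import MaskingResult, rank_materials

#: Representatives the correlation grouping keeps, in priority order:
#: DurInc stands for the increase-phase timing group {TsPl, TePl, DurInc},
#: DurDec for {DurDec, Tend}, AreaDec for {AreaDec, AreaTse}.
CANONICAL_REPRESENTATIVES = ("DurInc", "DurDec", "AreaDec")


@dataclass
class ParameterMatrix:
    """Materials x TI-parameters matrix with a standardization flag."""

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValidationError(f"parameter matrix has missing values in {bad}")
        unknown = [c for c in self.data.columns if c not in PARAMETER_NAMES]
        if unknown:
            raise ValidationError(f"unknown parameter columns {unknown}")
        if self.standardized:
            mu = self.data.mean(axis=0).to_numpy()
            var = self.data.var(axis=0, ddof=0).to_numpy()
            if np.abs(mu).max() > 1e-9 or np.abs(var - 1).max() > 1e-6:
                raise ValidationError("standardized flag set but columns are not mean-0/var-1")

    @property
    def material_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.data.columns)

    def select(self, columns: Sequence[str]) -> "ParameterMatrix":
        return ParameterMatrix(self.data[list(columns)].copy(), standardized=self.standardized)


@dataclass
class GroupComparison:
    """One parameter's top-vs-bottom Mann-Whitney comparison."""

    parameter: str
    U: float
    p_two_tailed: float
    median_top: float
    median_bottom: float
    significant: bool
    method: str = "exact"


@dataclass
class Exclusion:
    """One pruned column with the reason and triggering correlation."""

    column: str
    reason: str
    r: float | None = None
    kept: str | None = None


class MWUResult(NamedTuple):
    U: float
    p: float
    method: str


def _check_constant(df: pd.DataFrame) -> None:
    std = df.std(axis=0, ddof=0)
    constant = std.index[std.to_numpy() == 0].tolist()
    if constant:
        raise ValidationError(f"constant column(s): {constant}")


def pearson_corr_matrix(matrix: ParameterMatrix) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the parameter columns."""
    df = matrix.data
    if len(df) < 3:
        raise ParameterError(f"need >= 3 materials for correlations, got {len(df)}")
    _check_constant(df)
    r = np.corrcoef(df.to_numpy(), rowvar=False)
    return pd.DataFrame(r, index=df.columns, columns=df.columns)


def standardize(matrix: ParameterMatrix) -> ParameterMatrix:
    """Center each column and scale to unit population variance (divisor n)."""
    df = matrix.data
    _check_constant(df)
    z = (df - df.mean(axis=0)) / df.std(axis=0, ddof=0)
    return ParameterMatrix(z, standardized=True)


def mann_whitney_u(a, b, method: str = "auto") -> MWUResult:
    """Two-tailed Mann-Whitney U test with midrank ties.

    Returns ``U = min(U_a, U_b)``.  With ``method="auto"`` the p-value is
    exact (full null distribution) for tie-free samples with n+m <= 24 and
    a tie/continuity-corrected normal approximation otherwise; ``"exact"``
    and ``"asymptotic"`` force a path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError(f"each group needs >= 2 values (got {a.size} and {b.size})")
    if method not in ("auto", "exact", "asymptotic"):
        raise ParameterError(f"unknown method {method!r}")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = "exact" if (not has_ties and a.size + b.size <= 24) else "asymptotic"
    if method == "exact" and has_ties:
        raise ParameterError("exact p-values require tie-free data")
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return MWUResult(u, min(float(res.pvalue), 1.0), method)


def prune_correlated(
    matrix: ParameterMatrix,
    r_threshold: float = 0.98,
    mode: str = "canonical",
) -> tuple[list[str], list[Exclusion]]:
    """Drop redundant TI parameters; return retained names and a report.

    Columns with pairwise ``|r| >= r_threshold`` form groups (connected
    components); one representative per group is kept.  ``mode="canonical"``
    prefers the field-standard representatives (DurInc, DurDec, AreaDec)
    and falls back to the highest-variance column; ``mode="auto"`` always
    keeps the highest-variance column, ties broken by the canonical
    parameter order.  Identically-zero plateau columns (no material ever
    reached a plateau) and any other constant column are dropped first.
    """
    if mode not in ("canonical", "auto"):
        raise ParameterError(f"unknown prune mode {mode!r}; use 'canonical' or 'auto'")
    missing = [c for c in PARAMETER_NAMES if c not in matrix.data.columns]
    if missing:
        raise ValidationError(f"prune_correlated expects all 14 parameter columns; missing {missing}")
    df = matrix.data[list(PARAMETER_NAMES)]
    exclusions: list[Exclusion] = []
    cols = list(PARAMETER_NAMES)

    if (df["DurPl"] == 0).all():
        for col in ("DurPl", "AreaPl"):
            exclusions.append(Exclusion(col, "no material reached a plateau (all zero)"))
            cols.remove(col)
    for col in list(cols):
        if df[col].std(ddof=0) == 0:
            exclusions.append(Exclusion(col, "constant column"))
            cols.remove(col)

    sub = df[cols]
    r = np.corrcoef(sub.to_numpy(), rowvar=False)
    adj = np.abs(r) >= r_threshold
    # connected components of the |r| >= threshold graph
    comp = -np.ones(len(cols), dtype=int)
    n_comp = 0
    for i in range(len(cols)):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = n_comp
        while stack:
            j = stack.pop()
            for nb in np.flatnonzero(adj[j]):
                if comp[nb] < 0:
                    comp[nb] = n_comp
                    stack.append(nb)
        n_comp += 1

    variances = sub.var(axis=0, ddof=0)
    retained: list[str] = []
    for c in range(n_comp):
        members = [cols[i] for i in np.flatnonzero(comp == c)]
        if len(members) == 1:
            retained.append(members[0])
            continue
        keep = None
        if mode == "canonical":
            for rep in CANONICAL_REPRESENTATIVES:
                if rep in members:
                    keep = rep
                    break
        if keep is None:  # mode "auto", or no preferred representative in group
            keep = max(members, key=lambda m: (variances[m], -cols.index(m)))
        retained.append(keep)
        for m in members:
            if m != keep:
                rr = float(r[cols.index(m), cols.index(keep)])
                exclusions.append(
                    Exclusion(m, f"correlated with {keep} (|r| >= {r_threshold})", rr, keep)
                )
    retained.sort(key=cols.index)
    return retained, exclusions


def compare_top_bottom(
    params: ParameterMatrix,
    masking: Sequence[MaskingResult],
    k: int = 10,
    parameters: Sequence[str] | None = None,
    alpha: float = 0.05,
    method: str = "auto",
) -> list[GroupComparison]:
    """Mann-Whitney comparison of each parameter between masking extremes.

    Groups are the top-k and bottom-k materials by masking score (boundary
    ties included).  Significance is flagged per parameter at ``alpha``,
    two-tailed, with no multiplicity correction.
    """
    ids = set(params.material_ids)
    mask_ids = {m.material_id for m in masking}
    if ids != mask_ids:
        raise ValidationError(
            "parameter matrix and masking results cover different materials; "
            f"e.g. {sorted(ids ^ mask_ids)[:5]}"
        )
    top, bottom = rank_materials(masking, k)
    top_ids = [m.material_id for m in top]
    bot_ids = [m.material_id for m in bottom]
    names = list(parameters) if parameters is not None else params.parameter_names
    out = []
    for name in names:
        col = params.data[name]
        a = col.loc[top_ids].to_numpy()
        b = col.loc[bot_ids].to_numpy()
        u, p, used = mann_whitney_u(a, b, method=method)
        out.append(
            GroupComparison(
                parameter=name, U=u, p_two_tailed=p,
                median_top=float(np.median(a)), median_bottom=float(np.median(b)),
                significant=bool(p < alpha), method=used,
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.parameter, c.U, c.p_two_tailed, c.median_top, c.median_bottom,
             c.significant, c.method)
            for c in comparisons
        ],
        columns=["parameter", "U", "p_two_tailed", "median_top", "median_bottom",
                 "significant", "method"],
    )
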