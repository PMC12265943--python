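"""Abundance-threshold screens over a miRNA x tissue matrix.

Four screens, all strict-inequality predicates on absolute abundance
(molecules per 10 pg total RNA, replicate means):

* single-tissue-specific: above the on-threshold in exactly one tissue and
  below the off-threshold in all others (defaults 1700 / 340, the abundance
  needed for productive cleavage of a highly expressed transgene and a
  five-fold safety margin below it);
* multi-tissue: above the on-threshold in at most k tissues, below the
  off-threshold elsewhere;
* specific pairs: two miRNAs co-expressed above the on-threshold in exactly
  one common tissue, with at least one partner below the off-threshold in
  every other tissue;
* detargeting: above a floor (default 1000) in every tissue except one and
  below a ceiling (default 300) in the spared tissue, so a transgene with
  that miRNA's sites is silenced everywhere but the spared tissue.

An optional tissue -> group mapping collapses correlated columns (e.g. eight
brain regions into "brain"): a group is "on" when its maximum member is, and
"off" only when every member is; the detargeting floor requires every member
region above it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the specificity screens (molecules per 10 pg)."""

    on_threshold: float = 1700.0
    off_threshold: float = 340.0
    max_on_tissues: int = 1
    detarget_on: float = 1000.0
    detarget_off: float = 300.0

    def __post_init__(self) -> None:
        if min(self.on_threshold, self.off_threshold, self.detarget_on, self.detarget_off) <= 0:
            raise ValueError("thresholds must be positive")
        if self.off_threshold >= self.on_threshold:
            raise ValueError("off_threshold must be below on_threshold")
        if self.detarget_off >= self.detarget_on:
            raise ValueError("detarget_off must be below detarget_on")
        if self.max_on_tissues < 1:
            raise ValueError("max_on_tissues must be >= 1")


def _group_members(matrix: pd.DataFrame, groups: dict[str, str] | None) -> dict[str, list[str]]:
    if groups is None:
        return {t: [t] for t in matrix.columns}
    unknown = set(groups) - set(matrix.columns)
    if unknown:
        raise ValueError(f"grouping references unknown tissues: {sorted(unknown)}")
    members: dict[str, list[str]] = {}
    for t in matrix.columns:
        members.setdefault(groups.get(t, t), []).append(t)
    return members


def _grouped_levels(matrix: pd.DataFrame, groups: dict[str, str] | None):
    """Per-group max and min level matrices (identity when no grouping)."""
    members = _group_members(matrix, groups)
    gmax = pd.DataFrame({g: matrix[cols].max(axis=1) for g, cols in members.items()})
    gmin = pd.DataFrame({g: matrix[cols].min(axis=1) for g, cols in members.items()})
    return gmax, gmin


def tissue_specific(
    matrix: pd.DataFrame,
    criteria: ScreenCriteria | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """miRNAs above the on-threshold in exactly ``max_on_tissues`` tissues
    and below the off-threshold in all others (strict inequalities).
    """
    c = criteria or ScreenCriteria()
    if matrix.empty:
        raise ValueError("matrix must be nonempty")
    gmax, _ = _grouped_levels(matrix, groups)
    on = gmax > c.on_threshold
    off_ok = gmax < c.off_threshold
    rows = []
    for mirna in gmax.index:
        on_tissues = list(gmax.columns[on.loc[mirna]])
        if len(on_tissues) != c.max_on_tissues:
            continue
        others = [t for t in gmax.columns if t not in on_tissues]
        if not all(off_ok.loc[mirna, t] for t in others):
            continue
        rows.append(
            {
                "mirna": mirna,
                "on_tissues": ",".join(on_tissues),
                "on_levels": ",".join(f"{gmax.loc[mirna, t]:g}" for t in on_tissues),
                "max_off_level": float(gmax.loc[mirna, others].max()) if others else 0.0,
                "screen": "single",
            }
        )
    return pd.DataFrame(rows, columns=["mirna", "on_tissues", "on_levels", "max_off_level", "screen"])


def multi_tissue(
    matrix: pd.DataFrame,
    criteria: ScreenCriteria | None = None,
    k: int = 3,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """miRNAs above the on-threshold in 1..k tissues and below off elsewhere."""
    c = criteria or ScreenCriteria()
    gmax, _ = _grouped_levels(matrix, groups)
    if not 1 <= k <= gmax.shape[1]:
        raise ValueError("k must be between 1 and the number of tissues")
    on = gmax > c.on_threshold
    off_ok = gmax < c.off_threshold
    rows = []
    for mirna in gmax.index:
        on_tissues = list(gmax.columns[on.loc[mirna]])
        if not 1 <= len(on_tissues) <= k:
            continue
        others = [t for t in gmax.columns if t not in on_tissues]
        if not all(off_ok.loc[mirna, t] for t in others):
            continue
        rows.append(
            {
                "mirna": mirna,
                "on_tissues": ",".join(on_tissues),
                "on_levels": ",".join(f"{gmax.loc[mirna, t]:g}" for t in on_tissues),
                "max_off_level": float(gmax.loc[mirna, others].max()) if others else 0.0,
                "screen": f"multi_{k}",
            }
        )
    return pd.DataFrame(rows, columns=["mirna", "on_tissues", "on_levels", "max_off_level", "screen"])


def specific_pairs(
    matrix: pd.DataFrame,
    criteria: ScreenCriteria | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Unordered miRNA pairs co-expressed above threshold in exactly one tissue.

    A pair qualifies when both members exceed the on-threshold in exactly one
    shared tissue, and in every other tissue at least one member is below the
    off-threshold (that member's absence silences a dual-site transgene there).
    """
    c = criteria or ScreenCriteria()
    if len(matrix.index) < 2:
        return pd.DataFrame(columns=["mirna_a", "mirna_b", "tissue"])
    gmax, _ = _grouped_levels(matrix, groups)
    on = (gmax > c.on_threshold).to_numpy()
    below_off = (gmax < c.off_threshold).to_numpy()
    ids = list(gmax.index)
    tissues = list(gmax.columns)
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        co_on = on[i] & on[j]
        if co_on.sum() != 1:
            continue
        t_idx = int(np.flatnonzero(co_on)[0])
        others = [t for t in range(len(tissues)) if t != t_idx]
        if all(below_off[i, t] or below_off[j, t] for t in others):
            rows.append({"mirna_a": ids[i], "mirna_b": ids[j], "tissue": tissues[t_idx]})
    return pd.DataFrame(rows, columns=["mirna_a", "mirna_b", "tissue"])


def detargeting_candidates(
    matrix: pd.DataFrame,
    criteria: ScreenCriteria | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """miRNAs high everywhere except one spared tissue.

    For each tissue t, a candidate exceeds ``detarget_on`` in every other
    tissue (every member region when grouped) and sits below ``detarget_off``
    in t.  Reported as (miRNA, spared tissue).
    """
    c = criteria or ScreenCriteria()
    if matrix.empty:
        raise ValueError("matrix must be nonempty")
    gmax, gmin = _grouped_levels(matrix, groups)
    high = (gmin > c.detarget_on).to_numpy()
    low = (gmax < c.detarget_off).to_numpy()
    rows = []
    tissues = list(gmax.columns)
    for r, mirna in enumerate(gmax.index):
        for t, tissue in enumerate(tissues):
            if low[r, t] and all(high[r, u] for u in range(len(tissues)) if u != t):
                rows.append(
                    {
                        "mirna": mirna,
                        "spared_tissue": tissue,
                        "spared_level": float(gmax.iloc[r, t]),
                        "min_on_level": float(np.delete(gmin.iloc[r].to_numpy(), t).min()),
                        "screen": "detarget",
                    }
                )
    return pd.DataFrame(rows, columns=["mirna", "spared_tissue", "spared_level", "min_on_level", "screen"])


def collapse_families(matrix: pd.DataFrame, family_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Sum isomiR rows into miRNA families.

    ``family_of`` maps row ids to family names; when omitted, the family is
    the row id up to the first ``.`` (the convention ``name.offset`` for
    isomiR rows).
    """
    if family_of is None:
        family_of = {r: str(r).split(".")[0] for r in matrix.index}
    fam = matrix.index.map(lambda r: family_of.get(r, r))
    out = matrix.groupby(fam).sum()
    out.index.name = matrix.index.name
    return out
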