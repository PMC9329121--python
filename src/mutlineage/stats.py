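"""Mann-Whitney U comparisons and Benjamini-Hochberg FDR correction."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "mann_whitney_u", "bh_fdr", "compare_groups", "comparisons_to_tsv"]

_TAILS = {"one_greater": "greater", "one_less": "less", "two": "two-sided"}


@dataclass
class GroupComparison:
    label: str
    n_a: int
    n_b: int
    tail: str
    u_statistic: float
    p_value: float
    q_value: float | None = None


def _has_ties(a: Sequence[float], b: Sequence[float]) -> bool:
    pooled = list(a) + list(b)
    return len(set(pooled)) != len(pooled)


def mann_whitney_u(a: Sequence[float], b: Sequence[float], tail: str = "two") -> tuple[float, float]:
    """Mann-Whitney U test of a against b.

    Exact permutation p-value when min(len(a), len(b)) <= 8 and there are no
    ties; otherwise the normal approximation with midrank tie correction.
    ``tail`` is one of "one_greater" (a > b), "one_less" (a < b), "two".
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {sorted(_TAILS)}, got {tail!r}")
    exact = min(len(a), len(b)) <= 8 and not _has_ties(a, b)
    res = sps.mannwhitneyu(
        a, b, alternative=_TAILS[tail], method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def compare_groups(
    groups: dict[str, tuple[Sequence[float], Sequence[float]]],
    tail: str = "two",
) -> list[GroupComparison]:
    """Run one family of Mann-Whitney comparisons with BH correction.

    The caller declares the correction family by passing all its
    comparisons in one call; q-values are computed across exactly that set.
    """
    comps = []
    for label, (a, b) in groups.items():
        u, p = mann_whitney_u(a, b, tail)
        comps.append(GroupComparison(label, len(a), len(b), tail, u, p))
    qs = bh_fdr([c.p_value for c in comps])
    for comp, qv in zip(comps, qs):
        comp.q_value = qv
    return comps


def comparisons_to_tsv(comparisons: Sequence[GroupComparison], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "comparison": c.label,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "tail": c.tail,
                "U": c.u_statistic,
                "p": c.p_value,
                "q": c.q_value,
            }
            for c in comparisons
        ]
    ).to_csv(path, sep="\t", index=False)
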