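"""Group comparison statistics: one-way ANOVA, Tukey HSD, compact letter display.

Reproduces the lettered-table reporting style: per-group mean ± SD, a
one-way ANOVA, and Tukey-adjusted pairwise comparisons summarized as
letters where two groups share a letter iff their adjusted p-value is at
or above alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

__all__ = [
    "GroupData",
    "TukeyOutcome",
    "DegenerateDataWarning",
    "one_way_anova",
    "tukey_letters",
]


class DegenerateDataWarning(UserWarning):
    """Raised when all within-group variance is zero and F is undefined."""


@dataclass
class GroupData:
    """Replicate observations keyed by group label.

    Requires at least two groups; inference additionally requires at least
    two replicates per group.  Values must be numeric and finite.
    """

    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        clean: dict[str, np.ndarray] = {}
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"group {label!r} has no observations")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {label!r} contains non-finite values")
            clean[str(label)] = arr
        self.groups = clean

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_col: str, value_col: str) -> "GroupData":
        return cls(
            groups={
                str(g): sub[value_col].to_numpy(dtype=float)
                for g, sub in frame.groupby(group_col, sort=True)
            }
        )

    def require_replication(self) -> None:
        for label, arr in self.groups.items():
            if arr.size < 2:
                raise ValueError(f"group {label!r} needs >= 2 replicates for inference")

    def labels(self) -> list[str]:
        return list(self.groups)

    def means(self) -> dict[str, float]:
        return {g: float(v.mean()) for g, v in self.groups.items()}

    def summary(self) -> pd.DataFrame:
        """Per-group n, mean and SD (ddof=1), in insertion order."""
        rows = [
            {
                "group": g,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
            for g, v in self.groups.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class TukeyOutcome:
    """Tukey HSD pairwise table plus the compact letter display."""

    pairwise: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj
    letters: dict[str, str]
    alpha: float


def _sums_of_squares(data: GroupData) -> tuple[float, float, int, int]:
    values = list(data.groups.values())
    all_obs = np.concatenate(values)
    grand = all_obs.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in values)
    df_between = len(values) - 1
    df_within = all_obs.size - len(values)
    return float(ss_between), float(ss_within), df_between, df_within


def one_way_anova(data: GroupData) -> tuple[float, float]:
    """Classical between/within one-way ANOVA.

    Returns ``(F, p)``.  When every group has zero internal variance the F
    statistic is undefined; a :class:`DegenerateDataWarning` is emitted and
    the result is ``(inf, 0.0)`` if the group means differ, else
    ``(nan, 1.0)``.
    """
    data.require_replication()
    ss_b, ss_w, df_b, df_w = _sums_of_squares(data)
    if ss_w == 0.0:
        warnings.warn(
            "zero within-group variance in every group; F is undefined",
            DegenerateDataWarning,
            stacklevel=2,
        )
        if ss_b > 0.0:
            return float("inf"), 0.0
        return float("nan"), 1.0
    f_stat = (ss_b / df_b) / (ss_w / df_w)
    p_value = float(_scipy_stats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p_value


def _tukey_p_matrix(data: GroupData) -> np.ndarray:
    """Tukey HSD adjusted p-values (Tukey-Kramer when unbalanced)."""
    labels = data.labels()
    k = len(labels)
    _, ss_w, _, df_w = _sums_of_squares(data)
    pmat = np.ones((k, k), dtype=float)
    if ss_w == 0.0:
        # No residual variance: any mean difference is infinitely separated.
        means = data.means()
        for i in range(k):
            for j in range(i + 1, k):
                p = 1.0 if means[labels[i]] == means[labels[j]] else 0.0
                pmat[i, j] = pmat[j, i] = p
        return pmat
    mse = ss_w / df_w
    for i in range(k):
        vi = data.groups[labels[i]]
        for j in range(i + 1, k):
            vj = data.groups[labels[j]]
            se = np.sqrt(mse / 2.0 * (1.0 / vi.size + 1.0 / vj.size))
            q = abs(vi.mean() - vj.mean()) / se
            p = float(_scipy_stats.studentized_range.sf(q, k, df_w))
            pmat[i, j] = pmat[j, i] = min(1.0, p)
    return pmat


def _insert_absorb_letters(
    labels: list[str], significant: np.ndarray, order: list[int]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``significant[i, j]`` flags pairs that must NOT share a letter.
    ``order`` lists group indices by descending mean so that 'a' lands on
    the highest-mean group.
    """
    columns: list[set[int]] = [set(range(len(labels)))]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if not significant[i, j]:
                continue
            new_columns: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_columns.append(col - {i})
                    new_columns.append(col - {j})
                else:
                    new_columns.append(col)
            # absorb: drop columns that are subsets of another column
            columns = []
            for col in new_columns:
                if any(col < other for other in new_columns):
                    continue
                if col not in columns:
                    columns.append(col)
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for pos, col in enumerate(columns):
        letter = alphabet[pos % 26] * (pos // 26 + 1)
        for g in sorted(col, key=lambda g: rank[g]):
            letters[labels[g]] += letter
    return letters


def tukey_letters(data: GroupData, alpha: float = 0.05) -> TukeyOutcome:
    """Tukey HSD comparisons with a compact letter display.

    Letters are ordered by descending group mean ('a' marks the highest
    mean).  The display satisfies the biconditional exactly: two groups
    share at least one letter iff their adjusted p-value is >= ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    data.require_replication()
    labels = data.labels()
    _, ss_w, _, _ = _sums_of_squares(data)
    if ss_w == 0.0:
        warnings.warn(
            "zero within-group variance in every group; comparisons are degenerate",
            DegenerateDataWarning,
            stacklevel=2,
        )
    pmat = _tukey_p_matrix(data)
    significant = pmat < alpha
    means = data.means()
    order = sorted(range(len(labels)), key=lambda i: -means[labels[i]])
    letters = _insert_absorb_letters(labels, significant, order)

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": means[labels[i]] - means[labels[j]],
                    "p_adj": pmat[i, j],
                }
            )
    return TukeyOutcome(pairwise=pd.DataFrame(rows), letters=letters, alpha=alpha)
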