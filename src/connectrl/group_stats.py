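"""Region-wise two-group comparison of controllability profiles.

For each region the two cohorts are compared with a two-sample t-test
(Student's pooled-variance by default, Welch optional) and a Mann-Whitney U
test; t-test p-values are corrected for multiple comparisons across regions
with the Benjamini-Hochberg step-up procedure. The per-region table mirrors
the conventional biomarker layout: group means, their difference
(group A minus group B), t, U, raw and FDR-adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .controllability import ControllabilityProfile

__all__ = [
    "RegionComparison",
    "ComparisonTable",
    "two_sample_t",
    "mann_whitney",
    "bh_fdr",
    "compare_groups",
    "top_k",
]


@dataclass(frozen=True)
class RegionComparison:
    region_id: int          # 1-based atlas index
    region_name: str
    mean_a: float
    mean_b: float
    diff: float             # mean_a - mean_b
    t_value: float
    p_t: float
    u_value: float
    p_u: float
    p_fdr: float


@dataclass(frozen=True)
class ComparisonTable:
    rows: list[RegionComparison]
    n_a: int
    n_b: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ID": [r.region_id for r in self.rows],
                "Name": [r.region_name for r in self.rows],
                "Ave_control_HC": [r.mean_a for r in self.rows],
                "Ave_control_MDD": [r.mean_b for r in self.rows],
                "HC-MDD": [r.diff for r in self.rows],
                "p_t": [r.p_t for r in self.rows],
                "T": [r.t_value for r in self.rows],
                "U": [r.u_value for r in self.rows],
                "p_u": [r.p_u for r in self.rows],
                "p_FDR": [r.p_fdr for r in self.rows],
            }
        )

    def significant(self, on: str = "p_t") -> list[RegionComparison]:
        return [r for r in self.rows if getattr(r, on) < self.alpha]

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p.

    Student's pooled-variance flavor by default (df = n_a + n_b - 2);
    ``equal_var=False`` gives the Welch variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) with midrank ties.

    Two-sided p from the normal approximation with tie and continuity
    correction, appropriate for the cohort sizes this table targets.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty for a U test")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    profiles: list[ControllabilityProfile],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> ComparisonTable:
    """Region-by-region comparison of group 0 (A) versus group 1 (B)."""
    if not profiles:
        raise ValueError("no profiles given")
    labels = profiles[0].region_labels
    for p in profiles[1:]:
        if p.region_labels != labels:
            bad = next(
                (a, b) for a, b in zip(labels, p.region_labels) if a != b
            ) if len(p.region_labels) == len(labels) else (len(labels), len(p.region_labels))
            raise ValueError(f"region labels of subject {p.subject_id} do not match: {bad}")
    group_a = np.array([p.values for p in profiles if p.group_label == 0])
    group_b = np.array([p.values for p in profiles if p.group_label == 1])
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")

    rows: list[RegionComparison] = []
    p_ts = np.empty(len(labels))
    for j, name in enumerate(labels):
        t, p_t = two_sample_t(group_a[:, j], group_b[:, j], equal_var=equal_var)
        u, p_u = mann_whitney(group_a[:, j], group_b[:, j])
        mean_a = float(group_a[:, j].mean())
        mean_b = float(group_b[:, j].mean())
        p_ts[j] = p_t
        rows.append(
            RegionComparison(
                region_id=j + 1,
                region_name=name,
                mean_a=mean_a,
                mean_b=mean_b,
                diff=mean_a - mean_b,
                t_value=t,
                p_t=p_t,
                u_value=u,
                p_u=p_u,
                p_fdr=np.nan,
            )
        )
    adjusted = bh_fdr(p_ts)
    rows = [
        RegionComparison(**{**r.__dict__, "p_fdr": float(q)})
        for r, q in zip(rows, adjusted)
    ]
    return ComparisonTable(rows=rows, n_a=group_a.shape[0], n_b=group_b.shape[0], alpha=alpha)


def top_k(table: ComparisonTable, k: int, direction: str) -> list[str]:
    """The k regions with the largest group effect in one direction.

    ``"elevated-in-B"`` ranks by most negative diff (group B above group A),
    returned in increasing diff order; ``"decreased-in-B"`` by most positive
    diff, in decreasing order. Ties break by ascending region_id.
    """
    if not 1 <= k <= len(table.rows):
        raise ValueError(f"k must lie in [1, {len(table.rows)}]")
    if direction == "elevated-in-B":
        ordered = sorted(table.rows, key=lambda r: (r.diff, r.region_id))
    elif direction == "decreased-in-B":
        ordered = sorted(table.rows, key=lambda r: (-r.diff, r.region_id))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return [r.region_name for r in ordered[:k]]
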