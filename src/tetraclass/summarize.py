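"""Survey summaries of complexity calls.

Aggregates per-cross complexity calls into the outputs of a species-wide
survey: the overall and per-condition complexity spectrum (percentages of
monogenic / oligogenic / complex calls, undetermined excluded), the Shannon
entropy of the complexity classes across the crosses of each parent (a
proxy for the expressivity of that parent's large-effect variants), and a
one-sided phenotype comparison between carrier groups of a candidate
variant with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ComplexityCall

__all__ = [
    "SpectrumSummary",
    "EntropyValue",
    "CALLED_LEVELS",
    "complexity_spectrum",
    "spectrum_table",
    "parent_entropy",
    "parent_entropy_table",
    "compare_variant_groups",
]

CALLED_LEVELS = ("monogenic", "oligogenic", "complex")

SCOPES = ("overall", "per_condition", "per_parent_condition")


@dataclass
class SpectrumSummary:
    scope: str
    counts: dict
    percentages: dict
    n_called: int


@dataclass
class EntropyValue:
    parent_id: str
    condition: str
    H: float
    n_crosses: int


def _calls_frame(calls: Sequence[ComplexityCall]) -> pd.DataFrame:
    if not calls:
        raise ValueError("no calls given")
    return pd.DataFrame(
        {
            "cross_id": [c.cross_id for c in calls],
            "condition": [c.condition for c in calls],
            "level": [c.level for c in calls],
        }
    )


def _split_parents(df: pd.DataFrame) -> pd.DataFrame:
    """Two parent-id columns from ``"P1xP2"`` cross ids (NaN when absent)."""
    parts = df["cross_id"].str.split("x", n=1, expand=True)
    if parts.shape[1] < 2:
        parts[1] = pd.NA
    return parts


def _spectrum(levels: pd.Series) -> SpectrumSummary | None:
    called = levels[levels.isin(CALLED_LEVELS)]
    if called.empty:
        return None
    counts = {lv: int((called == lv).sum()) for lv in CALLED_LEVELS}
    n = len(called)
    return SpectrumSummary(
        scope="", counts=counts,
        percentages={lv: 100.0 * c / n for lv, c in counts.items()},
        n_called=n,
    )


def complexity_spectrum(
    calls: Sequence[ComplexityCall], scope: str = "overall"
):
    """Counts and percentages per complexity level at the requested scope.

    Undetermined calls are excluded from the denominator.  ``overall``
    returns a single :class:`SpectrumSummary`; the grouped scopes return a
    DataFrame with one row per group (parents are read from the cross id,
    ``"P1xP2"``; each cross contributes to both of its parents).
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    df = _calls_frame(calls)
    if scope == "overall":
        summary = _spectrum(df["level"])
        if summary is None:
            raise ValueError("all calls are undetermined")
        summary.scope = "overall"
        return summary
    if scope == "per_condition":
        groups = [((cond,), grp) for cond, grp in df.groupby("condition")]
        keys = ["condition"]
    else:
        parents = _split_parents(df)
        long = pd.concat(
            [df.assign(parent_id=parents[0]), df.assign(parent_id=parents[1])]
        )
        groups = [
            (key, grp) for key, grp in long.groupby(["parent_id", "condition"])
        ]
        keys = ["parent_id", "condition"]
    rows = []
    for key, grp in groups:
        s = _spectrum(grp["level"])
        if s is None:
            continue
        rows.append(
            (*key, *(s.counts[lv] for lv in CALLED_LEVELS),
             *(s.percentages[lv] for lv in CALLED_LEVELS), s.n_called)
        )
    return pd.DataFrame(
        rows,
        columns=keys
        + [f"n_{lv}" for lv in CALLED_LEVELS]
        + [f"pct_{lv}" for lv in CALLED_LEVELS]
        + ["n_called"],
    )


def spectrum_table(calls: Sequence[ComplexityCall]) -> pd.DataFrame:
    """Per-condition spectrum table (serialization-friendly)."""
    return complexity_spectrum(calls, scope="per_condition")


def parent_entropy(
    calls: Sequence[ComplexityCall], parent_id: str, condition: str
) -> EntropyValue:
    """Shannon entropy (bits) of complexity classes across a parent's crosses.

    H = -sum_c f_c log2 f_c over the observed class frequencies of the
    called crosses involving ``parent_id`` under ``condition``; 0 when all
    crosses share one class, log2(3) at the uniform three-class mix.
    """
    df = _calls_frame(calls)
    parents = _split_parents(df)
    mask = (
        ((parents[0] == parent_id) | (parents[1] == parent_id))
        & (df["condition"] == condition)
        & df["level"].isin(CALLED_LEVELS)
    )
    sub = df[mask]
    if sub.empty:
        return EntropyValue(parent_id, condition, float("nan"), 0)
    counts = sub["level"].value_counts().to_numpy(dtype=float)
    h = float(stats.entropy(counts, base=2))
    return EntropyValue(parent_id, condition, h, int(len(sub)))


def parent_entropy_table(calls: Sequence[ComplexityCall]) -> pd.DataFrame:
    """Entropy for every parent x condition present in the calls."""
    df = _calls_frame(calls)
    parents = _split_parents(df)
    all_parents = sorted(
        {p for p in set(parents[0]) | set(parents[1]) if pd.notna(p)}
    )
    rows = []
    for cond in sorted(set(df["condition"])):
        for pid in all_parents:
            ev = parent_entropy(calls, pid, cond)
            if ev.n_crosses:
                rows.append((pid, cond, ev.H, ev.n_crosses))
    return pd.DataFrame(rows, columns=["parent_id", "condition", "H", "n_crosses"])


def compare_variant_groups(
    phenotypes_group_a, phenotypes_group_b, n_tests: int = 1
) -> tuple[float, bool]:
    """One-sided Welch t-test that group A grows less, Bonferroni-adjusted.

    Used to test whether natural isolates carrying a candidate deleterious
    variant (group A) have lower growth than isolates carrying the
    alternative allele (group B), correcting for the ``n_tests`` candidate
    variants examined in the same gene.  Returns
    ``(adjusted_p, significant_at_0.05)``.
    """
    a = np.asarray(phenotypes_group_a, dtype=float)
    b = np.asarray(phenotypes_group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate groups: zero variance in both")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    p_adj = min(1.0, float(res.pvalue) * n_tests)
    return p_adj, p_adj < 0.05
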