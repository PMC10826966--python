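"""From raw colony sizes to growth-ratio phenotypes and tetrad panels.

High-throughput phenotyping measures each colony's size before and after a
24 h incubation on a treatment medium and on an untreated reference medium.
Processing follows the standard colony-growth workflow:

1.  colonies with insufficient baseline growth (reference endpoint size
    below 200 pixels) are removed across all conditions;
2.  growth = size_24h - size_0h, clamped at zero;
3.  growth ratio = growth on the treatment / growth on the reference
    (replicate-matched when possible), undefined when reference growth is 0;
4.  duplicate colonies of the same strain are averaged.

The resulting per-strain growth ratios are regrouped into
:class:`~tetraclass.simulate.TetradPanel` objects, one per cross and
treatment condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import TetradPanel

__all__ = [
    "FilterReport",
    "compute_growth",
    "filter_baseline",
    "growth_ratio",
    "average_duplicates",
    "table_to_phenotypes",
    "build_panels",
    "DEFAULT_MIN_SIZE",
]

DEFAULT_MIN_SIZE = 200

COLONY_COLUMNS = [
    "strain_id", "cross_id", "role", "tetrad_index", "spore_index",
    "condition", "replicate_index", "size_0h", "size_24h",
]


@dataclass
class FilterReport:
    """Bookkeeping for the baseline filter."""

    n_colonies_removed: int = 0
    n_records_removed: int = 0
    fraction_records_removed: float = 0.0
    strains_without_reference: list = field(default_factory=list)


def compute_growth(size_0h, size_24h):
    """Colony growth over the incubation, clamped at zero.

    Negative growth (a colony imaged smaller at endpoint) is reassigned to
    zero.  Accepts scalars or arrays; negative sizes are an error.
    """
    s0 = np.asarray(size_0h, dtype=float)
    s24 = np.asarray(size_24h, dtype=float)
    if np.any(s0 < 0) or np.any(s24 < 0):
        raise ValueError("colony sizes must be non-negative")
    growth = np.maximum(s24 - s0, 0.0)
    if np.isscalar(size_0h) and np.isscalar(size_24h):
        return float(growth)
    return growth


def filter_baseline(
    table: pd.DataFrame,
    reference_condition: str,
    min_size: int = DEFAULT_MIN_SIZE,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop colonies with insufficient baseline growth on the reference.

    A colony is a strain x replicate; if its reference-condition endpoint
    size is strictly under ``min_size``, that colony's records are removed
    across all conditions.  Strains with no reference record at all are
    dropped entirely and listed in the report.
    """
    if reference_condition not in set(table["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref = table[table["condition"] == reference_condition]
    bad = ref.loc[ref["size_24h"] < min_size, ["strain_id", "replicate_index"]]
    bad_keys = set(map(tuple, bad.to_numpy()))
    with_ref = set(ref["strain_id"])
    no_ref = sorted(set(table["strain_id"]) - with_ref)

    keys = list(zip(table["strain_id"], table["replicate_index"]))
    keep = np.array(
        [k not in bad_keys and k[0] in with_ref for k in keys], dtype=bool
    )
    out = table[keep].reset_index(drop=True)
    n_removed = int((~keep).sum())
    report = FilterReport(
        n_colonies_removed=len(bad_keys),
        n_records_removed=n_removed,
        fraction_records_removed=n_removed / len(table) if len(table) else 0.0,
        strains_without_reference=no_ref,
    )
    return out, report


def growth_ratio(growth_condition, growth_reference):
    """Treatment growth over reference growth; NaN when the reference is 0."""
    gc = np.asarray(growth_condition, dtype=float)
    gr = np.asarray(growth_reference, dtype=float)
    if np.any(gc < 0) or np.any(gr < 0):
        raise ValueError("growth values must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gr > 0, gc / np.where(gr > 0, gr, 1.0), np.nan)
    if np.isscalar(growth_condition) and np.isscalar(growth_reference):
        return float(ratio)
    return ratio


def average_duplicates(ratios) -> tuple[float, int]:
    """Mean growth ratio over surviving replicates.

    Returns ``(mean_ratio, n_replicates_used)``; NaN with 0 replicates when
    nothing survives.
    """
    arr = np.asarray([r for r in np.atleast_1d(ratios) if np.isfinite(r)], float)
    if arr.size == 0:
        return float("nan"), 0
    return float(arr.mean()), int(arr.size)


def table_to_phenotypes(
    table: pd.DataFrame,
    reference_condition: str,
    min_size: int = DEFAULT_MIN_SIZE,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full pipeline from a colony table to per-strain growth ratios.

    Reference growth is replicate-matched when the same replicate index
    exists on the reference plate, else the strain's mean reference growth.
    Returns a frame with columns strain_id, cross_id, role, tetrad_index,
    spore_index, condition, growth_ratio, n_replicates_used (one row per
    strain x non-reference condition) and the baseline-filter report.
    """
    table, report = filter_baseline(table, reference_condition, min_size)
    table = table.copy()
    table["growth"] = compute_growth(
        table["size_0h"].to_numpy(), table["size_24h"].to_numpy()
    )

    ref = table[table["condition"] == reference_condition]
    ref_by_rep = {
        (s, r): g
        for s, r, g in zip(ref["strain_id"], ref["replicate_index"], ref["growth"])
    }
    ref_mean = ref.groupby("strain_id")["growth"].mean().to_dict()

    cond = table[table["condition"] != reference_condition]
    ref_growth = np.array(
        [
            ref_by_rep.get((s, r), ref_mean.get(s, np.nan))
            for s, r in zip(cond["strain_id"], cond["replicate_index"])
        ]
    )
    ratios = growth_ratio(cond["growth"].to_numpy(), np.nan_to_num(ref_growth))
    ratios = np.where(np.isfinite(ref_growth), ratios, np.nan)

    cond = cond.assign(ratio=ratios)
    rows = []
    group_cols = ["strain_id", "cross_id", "role", "tetrad_index",
                  "spore_index", "condition"]
    for key, grp in cond.groupby(group_cols, sort=False, dropna=False):
        mean_ratio, n_used = average_duplicates(grp["ratio"].to_numpy())
        rows.append((*key, mean_ratio, n_used))
    return (
        pd.DataFrame(rows, columns=group_cols + ["growth_ratio", "n_replicates_used"]),
        report,
    )


def build_panels(phenotypes: pd.DataFrame, plan=None) -> list[TetradPanel]:
    """Group per-strain phenotypes into one panel per cross x condition.

    Missing spores (filtered colonies) stay as NaN markers so the tetrad
    structure is preserved; ``TetradPanel.complete_fraction`` records the
    completeness.  ``plan`` (a :class:`~tetraclass.synthetic_data.PanelPlan`)
    fixes the tetrad count; otherwise it is inferred per cross.
    """
    panels = []
    n_tetrads_plan = getattr(plan, "n_tetrads", None)
    for (cross, cond), grp in phenotypes.groupby(
        ["cross_id", "condition"], sort=False
    ):
        seg = grp[grp["role"] == "segregant"]
        par = grp[grp["role"] == "parent"].sort_values("strain_id")
        if seg.empty:
            continue
        tet_idx = seg["tetrad_index"].astype(float)
        if tet_idx.isna().any():
            raise ValueError(f"segregants of {cross} missing tetrad indices")
        n_tetrads = int(n_tetrads_plan or tet_idx.max())
        if tet_idx.max() > n_tetrads or seg["spore_index"].astype(float).max() > 4:
            raise ValueError(f"unknown tetrad/spore index in cross {cross}")
        values = np.full((n_tetrads, 4), np.nan)
        values[
            tet_idx.astype(int) - 1,
            seg["spore_index"].astype(int) - 1,
        ] = seg["growth_ratio"].to_numpy()
        parent_values = (
            par["growth_ratio"].to_numpy()
            if len(par) == 2
            else np.array([np.nan, np.nan])
        )
        panels.append(
            TetradPanel(
                cross_id=str(cross), condition=str(cond), values=values,
                parent_values=parent_values, provenance="experimental",
            )
        )
    return panels
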