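"""Synthetic half-diallel colony-size panels with planted architectures.

Emulates the raw data of a species-wide diallel phenotyping screen: a set
of parents crossed in all pairwise combinations (no selfs, no reciprocals),
40 four-spore tetrads per cross, duplicate colonies, one untreated
reference condition and any number of treatment conditions.  Each cross x
treatment carries a planted :class:`~tetraclass.simulate.GeneticArchitecture`
of known complexity class, so the entire downstream pipeline — baseline
filtering, growth ratios, feature extraction, classification, spectrum
summaries — can be validated against ground truth.

Colony sizes are derived from the simulated growth ratios by an invertible
affine map: ``size_24h = size_0h + round(G_ref * ratio)`` with a reference
growth ``G_ref`` (default 400 pixels) and a uniform baseline size, so
preprocessing recovers the planted ratio up to rounding.  Replicate noise
is multiplicative lognormal on the growth increment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate as sim
from .preprocess import COLONY_COLUMNS

__all__ = [
    "PanelPlan",
    "plan_half_diallel",
    "architecture_for_class",
    "plant_random_classes",
    "generate_colony_table",
    "write_colony_table",
    "read_colony_table",
    "CLASS_NAMES",
    "DEFAULT_REFERENCE_GROWTH",
]

CLASS_NAMES = ("monogenic", "oligogenic", "complex", "no_growth")

DEFAULT_REFERENCE_GROWTH = 400
DEFAULT_SIZE0_RANGE = (80, 120)
#: Multiplicative lognormal sd on replicate growth; 0.05 reproduces the
#: high duplicate correlation seen in dense colony arrays.
DEFAULT_REPLICATE_NOISE_SD = 0.05


@dataclass
class PanelPlan:
    """The structure of a half-diallel phenotyping panel."""

    parent_ids: tuple[str, ...]
    crosses: tuple[tuple[str, str], ...]
    conditions: tuple[str, ...]
    reference_condition: str
    n_tetrads: int = 40
    n_replicates: int = 2
    #: map (cross_id, condition) -> GeneticArchitecture for every
    #: non-reference condition
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_condition not in self.conditions:
            raise ValueError("reference condition must be one of conditions")
        seen = set()
        for a, b in self.crosses:
            if a == b:
                raise ValueError(f"self-cross {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"reciprocal/duplicate cross {a}x{b}")
            seen.add(key)

    @property
    def treatment_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.reference_condition)

    def cross_id(self, pair: tuple[str, str]) -> str:
        return f"{pair[0]}x{pair[1]}"


def plan_half_diallel(
    parent_ids,
    conditions=("SC_ref", "treatment1"),
    reference_condition: str | None = None,
    n_tetrads: int = 40,
    n_replicates: int = 2,
) -> PanelPlan:
    """All unordered pairs of distinct parents: n(n-1)/2 crosses.

    20 parents give the classic 190-hybrid half diallel.
    """
    parent_ids = tuple(str(p) for p in parent_ids)
    if len(set(parent_ids)) != len(parent_ids):
        raise ValueError("parent ids must be distinct")
    if len(parent_ids) < 2:
        raise ValueError("need at least two parents")
    crosses = tuple(itertools.combinations(parent_ids, 2))
    return PanelPlan(
        parent_ids=parent_ids,
        crosses=crosses,
        conditions=tuple(conditions),
        reference_condition=reference_condition or tuple(conditions)[0],
        n_tetrads=n_tetrads,
        n_replicates=n_replicates,
    )


def architecture_for_class(
    true_class: str,
    rng_seed=0,
    noise_sd: float = sim.DEFAULT_NOISE_SD,
) -> sim.GeneticArchitecture:
    """Draw an architecture whose offspring distribution has a known class.

    monogenic: a single dominant primary gene with weight in [0.85, 1]
    (clearly bimodal, 2:2 segregation).  oligogenic: two epistatic primary
    loci (recessive or dominant interaction) sharing a weight in
    [0.85, 1], giving bimodal but 3:1/1:3-like proportions.  complex:
    primary weight in [0, 0.15], unimodal.  no_growth: zero phenotype for
    every spore, uncallable by design.
    """
    rng = sim._check_rng(rng_seed)
    if true_class == "monogenic":
        arch = sim.assign_architecture(
            w1=float(rng.uniform(0.85, 1.0)), epistasis_mode="none",
            rng_seed=rng, noise_sd=noise_sd,
        )
    elif true_class == "oligogenic":
        mode = rng.choice(["recessive", "dominant"])
        arch = sim.assign_architecture(
            w1=float(rng.uniform(0.85, 1.0)), epistasis_mode=str(mode),
            rng_seed=rng, noise_sd=noise_sd,
        )
    elif true_class == "complex":
        arch = sim.assign_architecture(
            w1=float(rng.uniform(0.0, 0.15)), epistasis_mode="none",
            rng_seed=rng, noise_sd=noise_sd,
        )
    elif true_class == "no_growth":
        arch = sim.assign_architecture(
            w1=0.0, epistasis_mode="none", rng_seed=rng, noise_sd=noise_sd
        )
        arch.no_growth = True
    else:
        raise ValueError(f"unknown class {true_class!r}")
    return arch


def plant_random_classes(
    plan: PanelPlan,
    rng_seed=0,
    class_probs: dict[str, float] | None = None,
    noise_sd: float = sim.DEFAULT_NOISE_SD,
) -> PanelPlan:
    """Plant an architecture for every cross x treatment condition.

    Classes are drawn from ``class_probs`` (default: mostly complex with a
    minority of monogenic/oligogenic cases, as in real growth traits).
    """
    rng = sim._check_rng(rng_seed)
    if class_probs is None:
        class_probs = {"complex": 0.8, "oligogenic": 0.1, "monogenic": 0.1}
    names = list(class_probs)
    probs = np.array([class_probs[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    for pair in plan.crosses:
        for cond in plan.treatment_conditions:
            cls = str(rng.choice(names, p=probs))
            plan.planted[(plan.cross_id(pair), cond)] = architecture_for_class(
                cls, rng_seed=rng, noise_sd=noise_sd
            )
    return plan


def _true_class(arch: sim.GeneticArchitecture) -> str:
    if arch.no_growth:
        return "no_growth"
    if arch.w1 >= 0.5:
        return "monogenic" if arch.epistasis_mode == "none" else "oligogenic"
    return "complex"


def generate_colony_table(
    plan: PanelPlan,
    rng_seed: int = 0,
    reference_growth: int = DEFAULT_REFERENCE_GROWTH,
    size0_range: tuple[int, int] = DEFAULT_SIZE0_RANGE,
    replicate_noise_sd: float = DEFAULT_REPLICATE_NOISE_SD,
    return_panels: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw colony sizes plus the ground-truth class table for a plan.

    Every cross x treatment condition must carry a planted architecture.
    Returns ``(colony_table, truth)``; ``truth`` has one row per cross x
    treatment condition with the planted class, primary weight and
    epistasis mode.  With ``return_panels`` the underlying simulated
    :class:`~tetraclass.simulate.TetradPanel` objects (the planted growth
    ratios before the colony-size mapping) are appended to the return.
    Same seed, same plan -> byte-identical output.
    """
    rng = np.random.default_rng(rng_seed)
    records = []
    truth_rows = []
    panels = []
    for pair in plan.crosses:
        cross = plan.cross_id(pair)
        for cond in plan.treatment_conditions:
            if (cross, cond) not in plan.planted:
                raise ValueError(f"no planted architecture for {cross} x {cond}")
        genotypes = sim.simulate_tetrad_genotypes(
            plan.n_tetrads, rng_seed=rng
        )
        strains = [(pair[0], "parent", None, None), (pair[1], "parent", None, None)]
        strains += [
            (f"{cross}_t{t + 1:02d}s{s + 1}", "segregant", t + 1, s + 1)
            for t in range(plan.n_tetrads)
            for s in range(4)
        ]
        # growth ratio per strain and condition (reference ratio is 1)
        ratios = {plan.reference_condition: np.ones(len(strains))}
        for cond in plan.treatment_conditions:
            arch = plan.planted[(cross, cond)]
            panel = sim.compute_phenotypes(
                genotypes, arch, rng_seed=rng, cross_id=cross, condition=cond
            )
            ratios[cond] = np.concatenate(
                [panel.parent_values, panel.segregants]
            )
            panels.append(panel)
            truth_rows.append(
                (cross, cond, _true_class(arch), arch.w1, arch.epistasis_mode)
            )
        for cond in plan.conditions:
            r = np.maximum(ratios[cond], 0.0)
            for rep in range(1, plan.n_replicates + 1):
                size0 = rng.integers(size0_range[0], size0_range[1] + 1,
                                     size=len(strains))
                noise = (
                    rng.lognormal(0.0, replicate_noise_sd, size=len(strains))
                    if replicate_noise_sd > 0
                    else np.ones(len(strains))
                )
                growth = np.rint(reference_growth * r * noise).astype(int)
                for (sid, role, t, s), s0, g in zip(strains, size0, growth):
                    records.append(
                        (sid, cross, role, t, s, cond, rep, int(s0), int(s0 + g))
                    )
    table = pd.DataFrame(records, columns=COLONY_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["cross_id", "condition", "true_class", "w1", "epistasis_mode"],
    )
    if return_panels:
        return table, truth, panels
    return table, truth


def write_colony_table(table: pd.DataFrame, path) -> None:
    """Tab-separated colony table; empty fields for non-applicable indices."""
    out = table.copy()
    for col in ("tetrad_index", "spore_index"):
        out[col] = out[col].astype("Int64")
    out.to_csv(path, sep="\t", index=False)


def read_colony_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"tetrad_index": "Int64", "spore_index": "Int64"},
    )
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"colony table missing columns: {sorted(missing)}")
    return df[COLONY_COLUMNS]
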