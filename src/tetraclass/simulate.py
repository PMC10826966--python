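"""Simulation of tetrad-structured segregant phenotype distributions.

A yeast cross between two haploid parents yields tetrads of four spores in
which every biallelic locus segregates 2:2.  This module emulates that
process on a simplified linear "genome" of ``n_loci`` binary loci: each
tetrad is built from two recombinant strings (a parental 1-string and a
parental 0-string joined at two breakpoints) together with their locus-wise
complements, which enforces 2:2 segregation exactly.

Phenotypes follow an additive model with one primary gene of weight ``w1``
and 100 secondary genes whose non-negative weights sum to ``1 - w1``.
Epistatic variants replace the single primary gene with two loci sharing the
weight ``w1``, combined by AND (recessive) or OR (dominant).  Gaussian noise
emulates measurement error of the growth-ratio phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GeneticArchitecture",
    "TetradPanel",
    "LabeledPanel",
    "EPISTASIS_MODES",
    "simulate_tetrad_genotypes",
    "assign_architecture",
    "compute_phenotypes",
    "generate_training_set",
    "generate_labeled_eval_set",
    "write_panels",
    "read_panels",
]

EPISTASIS_MODES = ("none", "recessive", "dominant")

DEFAULT_N_LOCI = 101
DEFAULT_N_TETRADS = 40
#: Default phenotype noise standard deviation, on the [0, 1] phenotype scale.
#: Chosen to emulate the high replicate reproducibility of colony growth
#: ratios (duplicate correlation around 0.96 in dense-array screens).
DEFAULT_NOISE_SD = 0.05


@dataclass
class GeneticArchitecture:
    """A planted genetic architecture for one cross x condition.

    Parameters
    ----------
    w1
        Weight of the primary gene, in [0, 1].  High values produce bimodal
        segregant distributions; low values produce unimodal, approximately
        normal ones.
    secondary_weights
        Non-negative weights of the secondary genes, summing to ``1 - w1``.
    epistasis_mode
        ``"none"`` (single primary locus), ``"recessive"`` (two primary loci
        combined by AND) or ``"dominant"`` (OR).
    primary_positions
        Locus index of the primary gene (one locus for ``"none"``, two for
        the epistatic modes).
    secondary_positions
        Locus index of each secondary gene (a random injection into loci).
    noise_sd
        Standard deviation of the additive Gaussian phenotype noise.
    no_growth
        If set, the architecture represents a cross that does not grow at
        all under the condition: every phenotype is zero regardless of
        genotype.  Used to plant uncallable distributions.
    """

    w1: float
    secondary_weights: np.ndarray
    epistasis_mode: str = "none"
    primary_positions: tuple[int, ...] = (0,)
    secondary_positions: np.ndarray | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    no_growth: bool = False

    def __post_init__(self) -> None:
        self.secondary_weights = np.asarray(self.secondary_weights, dtype=float)
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError(f"w1 must lie in [0, 1], got {self.w1}")
        if np.any(self.secondary_weights < 0):
            raise ValueError("secondary weights must be non-negative")
        total = self.w1 + self.secondary_weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if self.epistasis_mode not in EPISTASIS_MODES:
            raise ValueError(f"unknown epistasis mode {self.epistasis_mode!r}")
        n_primary = 1 if self.epistasis_mode == "none" else 2
        if len(self.primary_positions) != n_primary:
            raise ValueError(
                f"{self.epistasis_mode!r} mode requires {n_primary} primary "
                f"position(s), got {len(self.primary_positions)}"
            )


@dataclass
class TetradPanel:
    """One cross x condition phenotype distribution.

    ``values`` is a (n_tetrads, 4) matrix of segregant phenotypes (growth
    ratios); ``parent_values`` holds the two parental phenotypes.
    Experimental panels may carry NaN for missing spores; simulated panels
    are always complete.
    """

    cross_id: str
    condition: str
    values: np.ndarray
    parent_values: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parent_values = np.asarray(self.parent_values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("values must be an (n_tetrads, 4) matrix")

    @property
    def n_tetrads(self) -> int:
        return self.values.shape[0]

    @property
    def segregants(self) -> np.ndarray:
        """Flat vector of segregant phenotypes (row-major over tetrads)."""
        return self.values.ravel()

    @property
    def complete_fraction(self) -> float:
        return float(np.isfinite(self.values).mean())


@dataclass
class LabeledPanel:
    """A simulated panel with its generating primary weight and mode."""

    panel: TetradPanel
    w1: float
    epistasis_mode: str


def _check_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _recombinant_block(
    rng: np.random.Generator, n_panels: int, n_tetrads: int, n_loci: int
) -> np.ndarray:
    """Genotypes for a block of panels, shape (n_panels, 4*n_tetrads, n_loci).

    Each tetrad holds two independent recombinant strings and their
    complements, so every locus segregates 2:2 within the tetrad.  A
    recombinant string carries the parental 1-allele outside the breakpoint
    interval [b1, b2) and the parental 0-allele inside it, with
    0 <= b1 <= b2 <= n_loci drawn uniformly.
    """
    bp = rng.integers(0, n_loci + 1, size=(n_panels, n_tetrads, 2, 2))
    bp.sort(axis=-1)
    b1 = bp[..., 0][..., None]  # (P, T, 2, 1)
    b2 = bp[..., 1][..., None]
    loci = np.arange(n_loci)
    rec = ~((loci >= b1) & (loci < b2))  # (P, T, 2, L) boolean
    spores = np.empty((n_panels, n_tetrads, 4, n_loci), dtype=np.int8)
    spores[:, :, 0] = rec[:, :, 0]
    spores[:, :, 1] = 1 - rec[:, :, 0]
    spores[:, :, 2] = rec[:, :, 1]
    spores[:, :, 3] = 1 - rec[:, :, 1]
    return spores.reshape(n_panels, 4 * n_tetrads, n_loci)


def simulate_tetrad_genotypes(
    n_tetrads: int, n_loci: int = DEFAULT_N_LOCI, rng_seed=0
) -> np.ndarray:
    """Simulate binary genotypes for ``4 * n_tetrads`` spores.

    Returns a (4*n_tetrads, n_loci) int8 matrix; spores are grouped in
    consecutive blocks of four per tetrad and every locus sums to exactly 2
    within each tetrad (2:2 segregation).
    """
    if n_tetrads < 1 or n_loci < 1:
        raise ValueError("n_tetrads and n_loci must be positive")
    rng = _check_rng(rng_seed)
    return _recombinant_block(rng, 1, n_tetrads, n_loci)[0]


def assign_architecture(
    w1: float,
    epistasis_mode: str = "none",
    n_secondary: int = 100,
    rng_seed=0,
    n_loci: int = DEFAULT_N_LOCI,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> GeneticArchitecture:
    """Draw a random genetic architecture with primary weight ``w1``.

    Secondary weights are iid uniforms renormalised to sum to ``1 - w1``;
    genes are placed on loci by a uniform random bijection.  For the
    epistatic modes the two primary loci are drawn independently and may be
    linked (close or identical on the simulated string).
    """
    if not 0.0 <= w1 <= 1.0:
        raise ValueError(f"w1 must lie in [0, 1], got {w1}")
    if n_secondary < 0:
        raise ValueError("n_secondary must be >= 0")
    if epistasis_mode not in EPISTASIS_MODES:
        raise ValueError(f"unknown epistasis mode {epistasis_mode!r}")
    rng = _check_rng(rng_seed)
    if n_secondary:
        raw = rng.uniform(size=n_secondary)
        weights = raw / raw.sum() * (1.0 - w1)
    else:
        weights = np.zeros(0)
    perm = rng.permutation(n_loci)
    if epistasis_mode == "none":
        primary = (int(perm[0]),)
        secondary_pos = perm[1 : n_secondary + 1]
    else:
        primary = tuple(int(p) for p in rng.integers(0, n_loci, size=2))
        secondary_pos = perm[:n_secondary]
    if len(secondary_pos) < n_secondary:
        raise ValueError("n_loci too small for the requested secondary genes")
    return GeneticArchitecture(
        w1=w1,
        secondary_weights=weights,
        epistasis_mode=epistasis_mode,
        primary_positions=primary,
        secondary_positions=np.asarray(secondary_pos, dtype=int),
        noise_sd=noise_sd,
    )


def _primary_effect(states: np.ndarray, arch: GeneticArchitecture) -> np.ndarray:
    """Primary-gene contribution per individual, in {0, 1} before weighting."""
    pos = arch.primary_positions
    if arch.epistasis_mode == "none":
        return states[..., pos[0]].astype(float)
    a = states[..., pos[0]]
    b = states[..., pos[1]]
    if arch.epistasis_mode == "recessive":
        return (a & b).astype(float)
    return (a | b).astype(float)


def compute_phenotypes(
    genotypes: np.ndarray,
    arch: GeneticArchitecture,
    rng_seed=0,
    cross_id: str = "sim",
    condition: str = "sim",
) -> TetradPanel:
    """Phenotype each spore under ``arch`` and return a TetradPanel.

    phenotype = sum_i w_i * state_i  +  w1 * f(primary states)  + N(0, sd^2)

    where f is the identity (no epistasis), AND (recessive) or OR
    (dominant).  Parental phenotypes are the noiseless phenotypes of the
    all-1 and all-0 parental genotypes (1 and 0 on this scale).
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[0] % 4:
        raise ValueError("genotypes must be (4*n_tetrads, n_loci)")
    n_loci = genotypes.shape[1]
    if arch.secondary_positions is not None and len(arch.secondary_positions) and (
        arch.secondary_positions.max() >= n_loci
    ):
        raise ValueError("architecture positions exceed the genotype loci")
    if max(arch.primary_positions) >= n_loci:
        raise ValueError("architecture positions exceed the genotype loci")
    rng = _check_rng(rng_seed)
    wvec = np.zeros(n_loci)
    if arch.secondary_positions is not None:
        wvec[arch.secondary_positions] += arch.secondary_weights
    if arch.no_growth:
        pheno = np.zeros(genotypes.shape[0])
        parents = np.zeros(2)
    else:
        pheno = genotypes @ wvec + arch.w1 * _primary_effect(genotypes, arch)
        if arch.noise_sd > 0:
            pheno = pheno + rng.normal(0.0, arch.noise_sd, size=pheno.shape)
        parents = np.array([0.0, 1.0])
    return TetradPanel(
        cross_id=cross_id,
        condition=condition,
        values=pheno.reshape(-1, 4),
        parent_values=parents,
    )


def _panel_block(
    rng: np.random.Generator,
    n_panels: int,
    w1: np.ndarray,
    mode: str,
    n_tetrads: int,
    n_loci: int,
    n_secondary: int,
    noise_sd: float,
) -> np.ndarray:
    """Vectorised phenotypes for a block of panels sharing one epistasis mode.

    Returns (n_panels, 4*n_tetrads) phenotype values.  Equivalent to calling
    :func:`assign_architecture` + :func:`compute_phenotypes` panel by panel,
    but batched for speed.
    """
    states = _recombinant_block(rng, n_panels, n_tetrads, n_loci)  # (P, N, L)
    raw = rng.uniform(size=(n_panels, n_secondary))
    sec_w = raw / raw.sum(axis=1, keepdims=True) * (1.0 - w1)[:, None]
    wvec = np.zeros((n_panels, n_loci))
    if mode == "none":
        perm = np.argsort(rng.uniform(size=(n_panels, n_loci)), axis=1)
        rows = np.arange(n_panels)[:, None]
        wvec[rows, perm[:, 1 : n_secondary + 1]] = sec_w
        primary = states[rows, :, perm[:, :1]].astype(float)[:, 0]
    else:
        perm = np.argsort(rng.uniform(size=(n_panels, n_loci)), axis=1)
        rows = np.arange(n_panels)[:, None]
        wvec[rows, perm[:, :n_secondary]] = sec_w
        ppos = rng.integers(0, n_loci, size=(n_panels, 2))
        a = states[rows, :, ppos[:, :1]][:, 0]
        b = states[rows, :, ppos[:, 1:2]][:, 0]
        primary = ((a & b) if mode == "recessive" else (a | b)).astype(float)
    pheno = np.einsum("pnl,pl->pn", states.astype(float), wvec)
    pheno += w1[:, None] * primary
    if noise_sd > 0:
        pheno += rng.normal(0.0, noise_sd, size=pheno.shape)
    return pheno


def generate_training_set(
    n_none: int = 25_000,
    n_recessive: int = 12_500,
    n_dominant: int = 12_500,
    w1_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    rng_seed=0,
    n_tetrads: int = DEFAULT_N_TETRADS,
    n_loci: int = DEFAULT_N_LOCI,
    n_secondary: int = 100,
    noise_sd: float = DEFAULT_NOISE_SD,
    chunk_size: int = 2_000,
) -> list[LabeledPanel]:
    """Generate a labeled training set of simulated phenotype distributions.

    The default configuration produces 25,000 non-epistatic, 12,500
    recessive-epistatic and 12,500 dominant-epistatic panels (50,000 in
    total) with ``w1`` drawn uniformly on [0, 1] per panel, spanning the
    full range from unimodal (complex-like) to clearly bimodal
    (monogenic-like) distributions.

    ``w1_sampler(rng, n)`` may be given to control the ``w1`` law.
    Generation is chunked internally; results are independent of
    ``chunk_size``-unrelated ordering (panels are returned grouped by mode).
    """
    for n in (n_none, n_recessive, n_dominant):
        if n < 0:
            raise ValueError("panel counts must be >= 0")
    rng = _check_rng(rng_seed)
    if w1_sampler is None:
        w1_sampler = lambda r, n: r.uniform(0.0, 1.0, size=n)
    out: list[LabeledPanel] = []
    for mode, count in (
        ("none", n_none),
        ("recessive", n_recessive),
        ("dominant", n_dominant),
    ):
        done = 0
        while done < count:
            block = min(chunk_size, count - done)
            w1 = np.asarray(w1_sampler(rng, block), dtype=float)
            if np.any((w1 < 0) | (w1 > 1)):
                raise ValueError("w1_sampler must return values in [0, 1]")
            values = _panel_block(
                rng, block, w1, mode, n_tetrads, n_loci, n_secondary, noise_sd
            )
            for j in range(block):
                idx = len(out)
                panel = TetradPanel(
                    cross_id=f"sim{idx:06d}",
                    condition=f"sim_{mode}",
                    values=values[j].reshape(-1, 4),
                    parent_values=np.array([0.0, 1.0]),
                )
                out.append(LabeledPanel(panel, float(w1[j]), mode))
            done += block
    return out


#: w1 bands used to label held-out panels for ROC calibration: panels with a
#: weak primary gene are unimodal, panels with a dominant one bimodal.
UNIMODAL_W1_BAND = (0.0, 0.3)
BIMODAL_W1_BAND = (0.7, 1.0)


def generate_labeled_eval_set(
    n_unimodal: int,
    n_bimodal: int,
    rng_seed=0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[tuple[TetradPanel, bool]]:
    """Held-out panels with binary bimodality labels for ROC calibration.

    Unimodal panels draw w1 uniformly from ``UNIMODAL_W1_BAND`` and bimodal
    panels from ``BIMODAL_W1_BAND``; intermediate weights are excluded so
    the labels are unambiguous.  Non-epistatic architectures only.
    """
    rng = _check_rng(rng_seed)
    lo, hi = UNIMODAL_W1_BAND
    uni = generate_training_set(
        n_unimodal, 0, 0,
        w1_sampler=lambda r, n: r.uniform(lo, hi, size=n),
        rng_seed=rng, noise_sd=noise_sd,
    )
    lo, hi = BIMODAL_W1_BAND
    bi = generate_training_set(
        n_bimodal, 0, 0,
        w1_sampler=lambda r, n: r.uniform(lo, hi, size=n),
        rng_seed=rng, noise_sd=noise_sd,
    )
    return [(lp.panel, False) for lp in uni] + [(lp.panel, True) for lp in bi]


def write_panels(panels: Sequence[TetradPanel], path) -> None:
    """Serialize panels to a tab-separated file (parents in companion rows)."""
    import pandas as pd

    rows = []
    for p in panels:
        for t in range(p.n_tetrads):
            for s in range(4):
                rows.append(
                    (p.cross_id, p.condition, t + 1, s + 1, p.values[t, s])
                )
        for k, v in enumerate(p.parent_values):
            rows.append((p.cross_id, p.condition, "", k + 1, v))
    df = pd.DataFrame(
        rows,
        columns=["cross_id", "condition", "tetrad_index", "spore_index", "phenotype"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_panels(path) -> list[TetradPanel]:
    """Read panels written by :func:`write_panels`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"tetrad_index": "Int64"})
    panels = []
    for (cross, cond), grp in df.groupby(["cross_id", "condition"], sort=False):
        seg = grp[grp["tetrad_index"].notna()]
        par = grp[grp["tetrad_index"].isna()].sort_values("spore_index")
        n_tetrads = int(seg["tetrad_index"].max())
        values = np.full((n_tetrads, 4), np.nan)
        values[
            seg["tetrad_index"].astype(int) - 1, seg["spore_index"].astype(int) - 1
        ] = seg["phenotype"].to_numpy()
        panels.append(
            TetradPanel(
                cross_id=str(cross),
                condition=str(cond),
                values=values,
                parent_values=par["phenotype"].to_numpy(),
            )
        )
    return panels
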