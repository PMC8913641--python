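"""Seeded synthetic community biomass data with planted correlation structure.

A Gaussian copula with lognormal marginals: latent taxon abundances are
drawn from a zero-mean multivariate normal whose correlation matrix
carries planted guild blocks (positive within-guild correlation),
antagonist pairs (negative correlation, e.g. predator-prey or
interference competition) and an optional background correlation; each
latent coordinate is mapped through exp(logmean + logsd * z) to a
positive, right-skewed biomass, and cells are then zeroed independently
with a fixed probability to mimic detection zeros.

The study fixture emulates three turbidity-class datasets (high,
moderate, low turbidity) with the shapes 158 samples x 27 taxa,
180 x 28 and 136 x 22, with planted interaction density increasing
from the low- to the high-turbidity class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BiomassMatrix

__all__ = [
    "SyntheticSpec",
    "TargetCorrelation",
    "GuildConflictError",
    "build_target_correlation",
    "generate",
    "planted_edges",
    "study_fixture_specs",
    "make_study_fixture",
]


class GuildConflictError(ValueError):
    """A taxon pair is assigned both a guild and an antagonist correlation."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic community dataset.

    guilds are groups of taxon indices sharing the within-guild latent
    correlation ``rho_within``; ``antagonist_pairs`` get ``rho_neg``;
    every other pair gets ``background_rho``.  Marginals are lognormal
    per taxon (scalar values broadcast to all taxa).
    """

    n_taxa: int
    n_samples: int
    guilds: tuple[tuple[int, ...], ...] = ()
    rho_within: float = 0.6
    antagonist_pairs: tuple[tuple[int, int], ...] = ()
    rho_neg: float = -0.5
    background_rho: float = 0.0
    marginal_logmean: float | Sequence[float] = 0.0
    marginal_logsd: float | Sequence[float] = 1.0
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError(f"n_taxa must be >= 2, got {self.n_taxa}")
        if self.n_samples < 4:
            raise ValueError(f"n_samples must be >= 4, got {self.n_samples}")
        if not 0 <= self.rho_within < 1:
            raise ValueError(f"rho_within must be in [0, 1), got {self.rho_within}")
        if not -1 < self.rho_neg <= 0:
            raise ValueError(f"rho_neg must be in (-1, 0], got {self.rho_neg}")
        if not -1 < self.background_rho < 1:
            raise ValueError(f"background_rho must be in (-1, 1), got {self.background_rho}")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError(f"zero_inflation must be in [0, 1), got {self.zero_inflation}")
        for g in self.guilds:
            if any(not 0 <= i < self.n_taxa for i in g):
                raise ValueError(f"guild {g} references a taxon index outside [0, {self.n_taxa})")
        for i, j in self.antagonist_pairs:
            if i == j:
                raise ValueError(f"antagonist pair ({i}, {j}) is a self-pair")
            if any(not 0 <= k < self.n_taxa for k in (i, j)):
                raise ValueError(f"antagonist pair ({i}, {j}) outside [0, {self.n_taxa})")
        if np.any(np.asarray(self.marginal_logsd, dtype=float) < 0):
            raise ValueError("marginal_logsd must be non-negative")

    def logmeans(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.marginal_logmean, dtype=float), (self.n_taxa,)).copy()

    def logsds(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.marginal_logsd, dtype=float), (self.n_taxa,)).copy()


@dataclass(frozen=True)
class TargetCorrelation:
    """Planted latent correlation matrix after positive-semidefinite repair.

    ``repaired`` is True when eigenvalue clipping was needed;
    ``max_drift`` reports the largest absolute entry change the repair
    introduced relative to the requested matrix.
    """

    matrix: np.ndarray
    repaired: bool
    max_drift: float


def build_target_correlation(spec: SyntheticSpec) -> TargetCorrelation:
    """Assemble the planted latent correlation matrix and repair it to PSD.

    Entry (i, j) is rho_within when i and j share a guild, rho_neg for
    antagonist pairs and background_rho otherwise.  A pair assigned both
    a guild and an antagonist correlation is a conflict.  If the
    resulting matrix is not positive semi-definite it is repaired by
    clipping negative eigenvalues at zero and re-normalising to unit
    diagonal; the repair is reported in the result.
    """
    p = spec.n_taxa
    guild_pairs: set[tuple[int, int]] = set()
    for g in spec.guilds:
        for a in g:
            for b in g:
                if a < b:
                    guild_pairs.add((a, b))
    antagonist_pairs = {(min(i, j), max(i, j)) for i, j in spec.antagonist_pairs}
    clash = sorted(guild_pairs & antagonist_pairs)
    if clash:
        raise GuildConflictError(
            f"taxon pairs assigned both guild and antagonist correlation: {clash}"
        )

    target = np.full((p, p), spec.background_rho, dtype=float)
    for i, j in guild_pairs:
        target[i, j] = target[j, i] = spec.rho_within
    for i, j in antagonist_pairs:
        target[i, j] = target[j, i] = spec.rho_neg
    np.fill_diagonal(target, 1.0)

    eigval, eigvec = np.linalg.eigh(target)
    repaired = bool(eigval.min() < -1e-10)
    if repaired:
        clipped = np.clip(eigval, 0.0, None)
        fixed = (eigvec * clipped) @ eigvec.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        fixed = (fixed + fixed.T) / 2.0
        np.fill_diagonal(fixed, 1.0)
        drift = float(np.max(np.abs(fixed - target)))
        return TargetCorrelation(fixed, True, drift)
    return TargetCorrelation(target, False, 0.0)


def planted_edges(spec: SyntheticSpec) -> dict[tuple[int, int], str]:
    """Map of planted taxon-index pairs to their sign ('+' guild, '-' antagonist)."""
    edges: dict[tuple[int, int], str] = {}
    if spec.rho_within > 0:
        for g in spec.guilds:
            for a in g:
                for b in g:
                    if a < b:
                        edges[(a, b)] = "+"
    if spec.rho_neg < 0:
        for i, j in spec.antagonist_pairs:
            edges[(min(i, j), max(i, j))] = "-"
    return edges


def _taxon_names(n: int) -> list[str]:
    return [f"taxon_{i + 1:02d}" for i in range(n)]


def generate(spec: SyntheticSpec) -> BiomassMatrix:
    """Draw one synthetic biomass dataset.

    Deterministic under a fixed spec (the seed is part of the spec):
    latent vectors come from N(0, C) with C the repaired target
    correlation, biomass is exp(logmean + logsd * z), and each cell is
    independently zeroed with probability ``zero_inflation``.
    """
    target = build_target_correlation(spec)
    rng = np.random.default_rng(spec.seed)
    eigval, eigvec = np.linalg.eigh(target.matrix)
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((spec.n_samples, spec.n_taxa)) @ factor.T
    biomass = np.exp(spec.logmeans() + spec.logsds() * z)
    if spec.zero_inflation > 0:
        biomass[rng.random(biomass.shape) < spec.zero_inflation] = 0.0
    values = pd.DataFrame(
        biomass,
        index=pd.Index([f"s{i + 1:04d}" for i in range(spec.n_samples)], name="sample_id"),
        columns=_taxon_names(spec.n_taxa),
    )
    return BiomassMatrix(values)


# ---------------------------------------------------------------------------
# Study fixture: three turbidity-class datasets
# ---------------------------------------------------------------------------

def _spread(lo: float, hi: float, n: int) -> np.ndarray:
    return np.linspace(lo, hi, n)


def study_fixture_specs(seed: int = 0) -> dict[str, SyntheticSpec]:
    """Specs for the three turbidity-class datasets.

    Shapes match the study design (HT 158x27, MT 180x28, LT 136x22) and
    the planted interaction density increases from LT to HT: the
    high-turbidity community carries large positively correlated
    consumer guilds plus balanced antagonist pairs, the low-turbidity
    one only a few small guilds.  Marginal log-means span a realistic
    biomass range (~0.02-1 mg/l per taxon); log-sd 0.6 gives the
    right-skew typical of biomass data.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    ht = SyntheticSpec(
        n_taxa=27,
        n_samples=158,
        guilds=((0, 1, 2, 3, 4, 5), (6, 7, 8, 9, 10), (11, 12, 13, 14, 15), (16, 17, 18, 19)),
        rho_within=0.65,
        antagonist_pairs=((0, 20), (6, 21), (11, 22), (16, 23), (1, 24), (7, 25)),
        rho_neg=-0.6,
        marginal_logmean=_spread(-4.0, 0.0, 27),
        marginal_logsd=0.6,
        seed=seeds[0],
    )
    mt = SyntheticSpec(
        n_taxa=28,
        n_samples=180,
        guilds=((0, 1, 2, 3), (4, 5, 6, 7), (8, 9, 10)),
        rho_within=0.65,
        antagonist_pairs=((0, 11), (4, 12)),
        rho_neg=-0.6,
        marginal_logmean=_spread(-4.0, 0.0, 28),
        marginal_logsd=0.6,
        seed=seeds[1],
    )
    lt = SyntheticSpec(
        n_taxa=22,
        n_samples=136,
        guilds=((0, 1, 2), (3, 4, 5)),
        rho_within=0.65,
        antagonist_pairs=((0, 6), (3, 7)),
        rho_neg=-0.6,
        marginal_logmean=_spread(-5.0, -1.0, 22),
        marginal_logsd=0.6,
        seed=seeds[2],
    )
    return {"HT": ht, "MT": mt, "LT": lt}


def make_study_fixture(seed: int = 0) -> dict[str, BiomassMatrix]:
    """Generate the three class datasets, labelled HT, MT and LT.

    Bit-identical across calls with the same seed.  Each matrix carries
    its class in the sample metadata so the pipeline can run unchanged
    on synthetic and real inputs.
    """
    out: dict[str, BiomassMatrix] = {}
    for cls, spec in study_fixture_specs(seed).items():
        m = generate(spec)
        m.samples["turbidity_class"] = cls
        m.values.index = pd.Index([f"{cls}_{sid}" for sid in m.values.index], name="sample_id")
        m.samples.index = m.values.index
        out[cls] = m
    return out
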