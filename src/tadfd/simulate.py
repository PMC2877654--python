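"""Synthetic regional pools, community assembly, and habitat gradients.

The analysis pipeline was designed for field data that pairs (a) a
species-by-trait matrix for a regional tadpole pool, (b) a
site-by-species presence table for stream sections, and (c) a
site-by-habitat table.  This module generates all three with the
statistical structure the analysis assumes, so every downstream stage
(ordination, trait space, null model) can be exercised and calibrated
end to end.

Study-scale defaults mirror the field design the pipeline targets: a
regional pool of 36 species scored on 18 morphological traits (13
binary columns from three mutually exclusive shape groups plus five
continuous measurements), 29 stream sites holding 2-18 species each,
and 14 habitat variables dominated by a single stream size-velocity
gradient.

The pool is *guild structured*: species belong to functional guilds
(ecomorphs) of skewed prevalence — a few common generalised
morphotypes, several rare specialists — and a guild sets both the
modal state of each categorical shape group and the centre of each
continuous trait.  Real tadpole pools are organised this way, and it
is what gives the regional dendrogram its clustered shape and the
FD-richness curve its saturating form; a pool of independent uniform
traits is nearly unclustered, its FD curve almost linear in richness,
and the saturating-curve comparison downstream degenerates.  Set
``n_guilds=0`` for such an unstructured pool.

Community assembly supports three rules:

``neutral``
    Species drawn uniformly without replacement from the pool.
``filtering``
    One regional trait optimum — the pool's modal phenotype, i.e. the
    species with the smallest mean Gower distance to all others —
    filters species-rich sites: a site of richness ``S`` draws species
    with weight ``exp(-s_eff * gower(species, optimum))`` where the
    effective strength ramps linearly from 0 at ``onset_richness`` to
    ``strength`` at the top of the richness range (0 at or below the
    onset).  This emulates a single habitat gradient (stream
    size-velocity) whose filter tightens toward the rich end, so trait
    convergence appears in species-rich communities while poor
    communities accumulate traits at random.
``competition``
    Greedy sequential assembly at every site; each newcomer is drawn
    with weight ``exp(strength * min gower distance to residents)``,
    favouring trait-dissimilar species (limiting similarity).

Strength 0 reduces every rule to neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CommunityTable, HabitatTable, HABITAT_VARIABLES
from .traitspace import TraitMatrix, gower_distance

__all__ = [
    "TraitSpec",
    "AssemblyScenario",
    "generate_trait_matrix",
    "generate_communities",
    "generate_habitat",
    "transect_coverage",
]

ASSEMBLY_RULES = ("neutral", "filtering", "competition")


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TraitSpec:
    """Blueprint for a synthetic species-by-trait matrix.

    Defaults reproduce an 18-trait tadpole table: three mutually
    exclusive binary groups (six oral-disc shapes, six jaw-sheath
    shapes, one eye-position flag) and five continuous traits
    (keratodont row count, papillae count, relative oral-disc width,
    relative tail-muscle height, relative tail length).

    Parameters
    ----------
    n_guilds
        Number of functional guilds in the pool; 0 disables guild
        structure (all traits independent, continuous traits uniform).
    guild_weights
        Relative guild prevalences (skewed: common generalists, rare
        specialists).  Pool membership is apportioned deterministically
        by largest remainder.
    guild_fidelity
        Probability that a species carries its guild's modal state in
        each multi-state shape group (the remainder is a uniform random
        state).
    guild_trait_sd
        Within-guild standard deviation of continuous traits, as a
        fraction of the trait range; values are clipped to the range.
    """

    group_names: tuple = ("oral_disc", "jaw_sheath", "eye_position")
    group_sizes: tuple = (6, 6, 1)
    continuous_names: tuple = (
        "keratodont_rows",
        "papillae",
        "rel_oral_disc_width",
        "rel_tail_muscle_height",
        "rel_tail_length",
    )
    continuous_ranges: tuple = ((0.0, 8.0), (0.0, 120.0), (0.2, 0.8), (0.1, 0.5), (0.5, 0.8))
    n_guilds: int = 6
    guild_weights: tuple = (0.35, 0.25, 0.15, 0.12, 0.08, 0.05)
    guild_fidelity: float = 0.9
    guild_trait_sd: float = 0.05

    def __post_init__(self):
        if len(self.group_names) != len(self.group_sizes):
            raise ValueError("group_names and group_sizes lengths differ")
        if any(int(s) < 1 for s in self.group_sizes):
            raise ValueError("binary group sizes must be >= 1")
        if len(self.continuous_names) != len(self.continuous_ranges):
            raise ValueError("continuous names and ranges lengths differ")
        for name, (lo, hi) in zip(self.continuous_names, self.continuous_ranges):
            if not lo < hi:
                raise ValueError(f"continuous trait {name!r} needs min < max")
        if self.n_guilds < 0:
            raise ValueError("n_guilds must be >= 0")
        if self.n_guilds > 0 and len(self.guild_weights) != self.n_guilds:
            raise ValueError("guild_weights length must equal n_guilds")
        if not 0.0 <= self.guild_fidelity <= 1.0:
            raise ValueError("guild_fidelity must lie in [0, 1]")

    @property
    def n_traits(self) -> int:
        return int(sum(self.group_sizes)) + len(self.continuous_names)


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` among ``weights``."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:short]] += 1
    return base


def generate_trait_matrix(spec: TraitSpec = TraitSpec(), pool_size: int = 36,
                          seed=None) -> TraitMatrix:
    """Draw a regional pool of species in the trait space of ``spec``.

    Within each multi-state binary group exactly one column is 1 per
    species (states are mutually exclusive); a single-column group is a
    free 0/1 trait.  With guild structure, each guild has a modal state
    per shape group and an archetype value per continuous trait, and
    species scatter tightly around their guild; without it, states are
    uniform and continuous traits uniform within their ranges.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be at least 2")
    rng = _rng(seed)

    if spec.n_guilds > 0:
        sizes = _apportion(np.asarray(spec.guild_weights, float), pool_size)
        guild = np.repeat(np.arange(spec.n_guilds), sizes)
    else:
        guild = None

    cols, names, kinds, groups = [], [], [], []
    for gname, gsize in zip(spec.group_names, spec.group_sizes):
        gsize = int(gsize)
        if gsize == 1:
            if guild is None:
                block = rng.integers(0, 2, size=(pool_size, 1)).astype(float)
            else:
                p_one = rng.random(spec.n_guilds)
                block = (rng.random(pool_size) < p_one[guild]).astype(float)[:, None]
        else:
            if guild is None:
                states = rng.integers(0, gsize, size=pool_size)
            else:
                modal = (rng.choice(gsize, size=spec.n_guilds, replace=False)
                         if spec.n_guilds <= gsize
                         else rng.integers(0, gsize, size=spec.n_guilds))
                states = np.where(rng.random(pool_size) < spec.guild_fidelity,
                                  modal[guild], rng.integers(0, gsize, pool_size))
            block = np.zeros((pool_size, gsize))
            block[np.arange(pool_size), states] = 1.0
        cols.append(block)
        names += [f"{gname}_{k + 1}" for k in range(gsize)] if gsize > 1 else [gname]
        kinds += ["binary"] * gsize
        groups += [gname] * gsize
    for cname, (lo, hi) in zip(spec.continuous_names, spec.continuous_ranges):
        if guild is None:
            vals = rng.uniform(lo, hi, size=pool_size)
        else:
            arch = rng.uniform(lo, hi, size=spec.n_guilds)
            vals = np.clip(arch[guild] + rng.normal(0.0, spec.guild_trait_sd * (hi - lo),
                                                    pool_size), lo, hi)
        cols.append(vals[:, None])
        names.append(cname)
        kinds.append("continuous")
        groups.append(cname)
    values = np.hstack(cols)
    species = tuple(f"sp{i + 1:02d}" for i in range(pool_size))
    return TraitMatrix(species_ids=species, values=values, trait_names=tuple(names),
                       trait_kinds=tuple(kinds), trait_groups=tuple(groups))


@dataclass(frozen=True)
class AssemblyScenario:
    """Community-assembly settings for a set of stream sites.

    ``onset_richness`` (filtering only): sites at or below this
    richness assemble neutrally; above it the filter strength ramps
    linearly, reaching ``strength`` at the top of the richness range.
    ``None`` uses the midpoint of ``richness_range``; 0 filters every
    site (with the same linear ramp).
    """

    rule: str = "neutral"
    strength: float = 0.0
    richness_range: tuple = (2, 18)
    n_sites: int = 29
    pool_size: int = 36
    onset_richness: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.rule not in ASSEMBLY_RULES:
            raise ValueError(f"rule must be one of {ASSEMBLY_RULES}")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid richness_range")
        if hi > self.pool_size:
            raise ValueError("richness_range maximum exceeds pool size")
        if self.n_sites < 1:
            raise ValueError("need at least one site")

    @property
    def onset(self) -> int:
        if self.onset_richness is not None:
            return int(self.onset_richness)
        lo, hi = self.richness_range
        return (lo + hi) // 2


def _weighted_subset(rng, weights: np.ndarray, size: int) -> np.ndarray:
    """Sequential weighted sampling without replacement."""
    w = weights.astype(float).copy()
    chosen = []
    for _ in range(size):
        p = w / w.sum()
        i = rng.choice(len(w), p=p)
        chosen.append(i)
        w[i] = 0.0
    return np.asarray(chosen, dtype=int)


def generate_communities(traits: TraitMatrix, scenario: AssemblyScenario) -> CommunityTable:
    """Assemble site communities from the pool under the scenario's rule.

    Site richness is drawn uniformly from ``richness_range`` and then
    met exactly.  See the module docstring for the three assembly
    rules; the filtering optimum is the pool's modal phenotype (the
    species minimising mean Gower distance to the rest of the pool,
    first index on ties).
    """
    if traits.n_species != scenario.pool_size:
        raise ValueError(
            f"trait matrix has {traits.n_species} species but scenario expects "
            f"{scenario.pool_size}"
        )
    rng = _rng(scenario.seed)
    N = traits.n_species
    D = gower_distance(traits).d
    lo, hi = scenario.richness_range
    richness = rng.integers(lo, hi + 1, size=scenario.n_sites)
    P = np.zeros((scenario.n_sites, N), dtype=bool)
    s = scenario.strength
    optimum = int(np.argmin(D.mean(axis=1)))
    for i, S in enumerate(richness):
        if scenario.rule == "competition" and s > 0:
            first = rng.integers(N)
            idx = [first]
            avail = np.ones(N, dtype=bool)
            avail[first] = False
            for _ in range(S - 1):
                cand = np.flatnonzero(avail)
                mind = D[np.ix_(cand, idx)].min(axis=1)
                w = np.exp(s * mind)
                pick = cand[rng.choice(len(cand), p=w / w.sum())]
                idx.append(pick)
                avail[pick] = False
            idx = np.asarray(idx)
        elif scenario.rule == "filtering" and s > 0 and S > scenario.onset:
            top = scenario.richness_range[1]
            ramp = (S - scenario.onset) / max(top - scenario.onset, 1)
            w = np.exp(-s * ramp * D[optimum])
            idx = _weighted_subset(rng, w, S)
        else:  # neutral, or strength 0, or below the filtering onset
            idx = rng.choice(N, size=S, replace=False)
        P[i, idx] = True
    sites = tuple(f"site{i + 1:02d}" for i in range(scenario.n_sites))
    return CommunityTable(site_ids=sites, species_ids=traits.species_ids, presence=P)


def generate_habitat(communities: CommunityTable, coupling: float = 0.9,
                     seed=None, return_latent: bool = False):
    """Per-site habitat variables around one latent size-velocity axis.

    A latent stream-size/velocity gradient is constructed with Pearson
    correlation ~``coupling`` to site species richness.  The gradient
    loads positively on stream width and dragonfly-larvae abundance and
    negatively on slope and on both stream and forest canopy cover; the
    four ground-substrate percentages shift from leaves/sand (small,
    shaded streams) toward gravel/rock (large, open streams) and always
    sum to 100.  The remaining variables (mayfly larvae, forest shrubs
    and trees, leaf-litter depth, riparian vegetation) are independent
    noise.  With ``return_latent`` the latent gradient is returned
    alongside the table (useful for validating the coupling contract).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = _rng(seed)
    sr = communities.sr.astype(float)
    n = len(sr)
    if n > 1 and sr.std() > 0:
        z_sr = (sr - sr.mean()) / sr.std()
    else:
        z_sr = np.zeros(n)
    latent = coupling * z_sr + np.sqrt(1.0 - coupling**2) * rng.normal(size=n)

    e = lambda scale=1.0: rng.normal(scale=scale, size=n)
    width = np.exp(0.8 + 0.6 * latent + 0.25 * e())
    slope = np.exp(0.0 - 0.6 * latent + 0.25 * e())
    canopy = 1.0 / (1.0 + np.exp(-(0.5 - 1.5 * latent + 0.6 * e())))
    forest_canopy = 100.0 / (1.0 + np.exp(-(0.8 - 1.2 * latent + 0.6 * e())))
    dragonfly = rng.poisson(np.exp(1.2 + 0.7 * latent)).astype(float)

    logits = np.column_stack([
        -0.9 * latent + 0.5 * e(),   # leaves
        -0.9 * latent + 0.5 * e(),   # sand
        +0.9 * latent + 0.5 * e(),   # gravel
        +0.9 * latent + 0.5 * e(),   # rock
    ])
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    micro = 100.0 * expl / expl.sum(axis=1, keepdims=True)

    df = pd.DataFrame(
        {
            "width": width,
            "slope": slope,
            "canopy_cover": canopy,
            "leaves": micro[:, 0],
            "sand": micro[:, 1],
            "gravel": micro[:, 2],
            "rock": micro[:, 3],
            "dragonfly_larvae": dragonfly,
            "mayfly_larvae": rng.poisson(6.0, size=n).astype(float),
            "forest_shrubs": rng.poisson(15.0, size=n).astype(float),
            "forest_trees": rng.poisson(8.0, size=n).astype(float),
            "forest_canopy_cover": forest_canopy,
            "leaf_litter": np.exp(1.0 + 0.4 * e()),
            "riparian_vegetation": rng.poisson(20.0, size=n).astype(float),
        },
        index=list(communities.site_ids),
    ).rename_axis("site")
    table = HabitatTable(df=df.loc[:, list(HABITAT_VARIABLES)])
    return (table, latent) if return_latent else table


def transect_coverage(n_transects: int = 10, transect_width: float = 1.0,
                      section_length: float = 30.0) -> float:
    """Percent of a stream section's area covered by transversal transects.

    Transects span the full stream width, so areal coverage reduces to
    the covered fraction of section length: ten 1 m transects across a
    30 m section cover a third of its area.
    """
    if n_transects < 0 or transect_width <= 0 or section_length <= 0:
        raise ValueError("invalid sampling design")
    covered = n_transects * transect_width
    if covered > section_length:
        raise ValueError("transects exceed the section length")
    return 100.0 * covered / section_length
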