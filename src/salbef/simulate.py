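"""Synthetic salinity-gradient microcosm experiments.

This module generates artificial biodiversity–ecosystem-functioning (BEF)
experiments patterned on salt-lake isolate studies: a library of bacterial
strains with unimodal (Gaussian) salt-tolerance curves, monoculture yield
assays across culture salinities, richness-gradient community designs with
equal-density inoculation, and mixture outcomes produced by a generative
model whose selection- and complementarity-effect ground truth is known in
closed form.

Generative model for one mixture at salinity ``s`` (documented here verbatim;
see also docs/methods.md):

1. Members whose monoculture yield ``M_i(s)`` is at or below the detection
   floor are assumed to wash out; the model operates on the viable
   sub-community of size ``N`` with inoculation proportions ``RY_E,i``
   renormalized over viable members.
2. Observed relative yields are
   ``RY_O,i = RY_E,i * (1 + phi*(1 - 1/N)) + (theta/N) * (M_i/Mbar - 1)``
   with ``Mbar`` the mean viable monoculture yield. The ``phi`` term is a
   richness-dependent complementarity uplift; the ``theta`` term is a
   mean-zero tilt of relative yields toward high-yielding strains, i.e. a
   pure selection effect.
3. Member yields are ``Y_O,i = RY_O,i * M_i`` times a single multiplicative
   lognormal noise factor ``10**eps``, ``eps ~ Normal(0, noise_sd)`` (log10
   scale), shared by all members so shares are preserved; ``Y_O`` is their sum.

Under additive partitioning this construction yields, noise off and equal
inoculation, exactly ``CE = phi*(1-1/N)*Mbar`` and ``SE = theta*var_pop(M)/Mbar``,
so ``theta = phi = 0`` is a zero-NBE null and each dial moves exactly one
component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ClippedYieldWarning, DesignInfeasibleError, NoGrowthWarning
from . import io as _io

__all__ = [
    "StrainProfile",
    "SimulationConfig",
    "CommunityDesign",
    "MixtureObservation",
    "Experiment",
    "generate_strain_library",
    "tolerance_yield",
    "simulate_monocultures",
    "design_communities",
    "simulate_mixture",
    "simulate_experiment",
    "composition_table",
    "write_experiment",
    "read_experiment",
    "GENUS_POOL",
]

#: Genus labels for simulated isolates. Drawn from genera commonly recovered
#: from saline and hypersaline lakes (halophiles, halotolerant firmicutes and
#: actinobacteria); 32 labels so a default 40-strain library contains
#: congeneric strains, as real isolate collections do.
GENUS_POOL = (
    "Halomonas", "Marinobacter", "Virgibacillus", "Bacillus", "Halobacillus",
    "Oceanobacillus", "Salinicoccus", "Planococcus", "Nesterenkonia", "Marinococcus",
    "Alkalibacillus", "Gracilibacillus", "Thalassobacillus", "Piscibacillus", "Salimicrobium",
    "Pontibacillus", "Paraliobacillus", "Lentibacillus", "Sediminibacillus", "Aquibacillus",
    "Salinivibrio", "Chromohalobacter", "Kushneria", "Idiomarina", "Salinicola",
    "Psychrobacter", "Staphylococcus", "Micrococcus", "Kocuria", "Brevibacterium",
    "Corynebacterium", "Arthrobacter",
)

# Stream ids for fanning one experiment seed out to per-stage generators, so
# stages can be rerun in isolation yet the whole run is reproducible.
_STREAM_LIBRARY = 0
_STREAM_DESIGN = 1
_STREAM_MONOCULTURE = 2
_STREAM_MIXTURE = 3


def _stage_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


@dataclass(frozen=True)
class StrainProfile:
    """One strain: identity plus Gaussian salt-tolerance-curve parameters.

    Parameters
    ----------
    strain_id : str
        Unique identifier within a library.
    genus : str
        Genus label; mixtures report composition at this level.
    s_opt : float
        Optimum salinity, % (w/v) NaCl, within the assay range [0, 30].
    sigma_tol : float
        Tolerance breadth (salinity % units), > 0.
    y_max : float
        Maximum monoculture yield (OD600-equivalent) at ``s_opt``, > 0.
    """

    strain_id: str
    genus: str
    s_opt: float
    sigma_tol: float
    y_max: float

    def __post_init__(self):
        if not (0.0 <= self.s_opt <= 30.0):
            raise ValueError(f"s_opt must lie in the assay range [0, 30]: {self.s_opt}")
        if self.sigma_tol <= 0:
            raise ValueError(f"sigma_tol must be > 0: {self.sigma_tol}")
        if self.y_max <= 0:
            raise ValueError(f"y_max must be > 0: {self.y_max}")


def _default_theta() -> dict:
    # Selection dominance rises with salinity stress up to 15% NaCl, then
    # drops at 20% where even halophile dominance cannot rescue function.
    return {0.9: 0.05, 3.5: 0.10, 7.0: 0.25, 15.0: 0.70, 20.0: 0.15}


def _default_phi() -> dict:
    # Complementarity (niche partitioning among strains) declines as salinity
    # stress narrows the set of strains with usable niche space.
    return {0.9: 0.50, 3.5: 0.35, 7.0: 0.20, 15.0: 0.06, 20.0: 0.02}


@dataclass
class SimulationConfig:
    """Design and generative parameters for one synthetic experiment.

    Defaults encode the study design this generator emulates: 40 strains,
    richness levels 5/10/20/40 with 4/8/16/3 replicate communities (groups
    A–D), five culture salinities (0.9, 3.5, 7, 15, 20 % NaCl), equal-density
    inoculation, and salinity-dependent selection/complementarity structure.
    """

    n_strains: int = 40
    richness_levels: tuple = (5, 10, 20, 40)
    replicate_counts: tuple = (4, 8, 16, 3)
    salinities: tuple = (0.9, 3.5, 7.0, 15.0, 20.0)
    theta_by_salinity: dict = field(default_factory=_default_theta)
    phi_by_salinity: dict = field(default_factory=_default_phi)
    noise_sd: float = 0.05
    detection_floor: float = 0.01
    seed: int = 0
    #: Assay range over which tolerance optima are placed.
    assay_range: tuple = (0.0, 30.0)
    #: Skew of the tolerance-optimum grid: >1 concentrates optima at low
    #: salinity (most environmental isolates are only mildly halotolerant).
    halotolerance_skew: float = 1.8
    #: Fractional y_max penalty at the top of the assay range, the metabolic
    #: cost of osmoadaptation. y_max declines ~exp(-cost * s_opt / s_max).
    halotolerance_cost: float = 1.0
    #: Reference maximum yield (OD600-equivalent) of a non-halophile.
    y_ref: float = 1.2
    #: Range of tolerance breadths sigma_tol drawn uniformly.
    sigma_range: tuple = (2.0, 4.5)
    #: If True, community replicates are stratified across salt-tolerance
    #: classes (quartiles of s_opt) instead of uniform random combinations.
    stratified_communities: bool = False
    #: SD (log10 scale) of a per-community lognormal yield offset shared by
    #: all of that community's mixtures across salinities — replicate
    #: identity effects, the ground truth for the mixed model's random
    #: intercept. Off by default.
    community_sd: float = 0.0

    def __post_init__(self):
        self.richness_levels = tuple(int(r) for r in self.richness_levels)
        self.replicate_counts = tuple(int(c) for c in self.replicate_counts)
        self.salinities = tuple(float(s) for s in self.salinities)
        self.theta_by_salinity = {float(k): float(v) for k, v in self.theta_by_salinity.items()}
        self.phi_by_salinity = {float(k): float(v) for k, v in self.phi_by_salinity.items()}
        self.validate()

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if len(self.replicate_counts) != len(self.richness_levels):
            raise ValueError("replicate_counts must align with richness_levels")
        if any(r < 1 for r in self.richness_levels) or any(c < 1 for c in self.replicate_counts):
            raise ValueError("richness levels and replicate counts must be >= 1")
        if max(self.richness_levels) > self.n_strains:
            raise DesignInfeasibleError(
                f"richness level {max(self.richness_levels)} exceeds library size {self.n_strains}"
            )
        sal = self.salinities
        if len(sal) < 1 or any(b <= a for a, b in zip(sal, sal[1:])):
            raise ValueError("salinities must be strictly increasing")
        if any(s < 0 for s in sal):
            raise ValueError("salinities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.community_sd < 0:
            raise ValueError("community_sd must be >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        if any(v < 0 for v in self.theta_by_salinity.values()):
            raise ValueError("theta values must be >= 0")

    def theta(self, salinity: float) -> float:
        return self.theta_by_salinity.get(float(salinity), 0.0)

    def phi(self, salinity: float) -> float:
        return self.phi_by_salinity.get(float(salinity), 0.0)

    def to_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "richness_levels": list(self.richness_levels),
            "replicate_counts": list(self.replicate_counts),
            "salinities": list(self.salinities),
            "theta_by_salinity": dict(self.theta_by_salinity),
            "phi_by_salinity": dict(self.phi_by_salinity),
            "noise_sd": self.noise_sd,
            "detection_floor": self.detection_floor,
            "seed": self.seed,
            "assay_range": list(self.assay_range),
            "halotolerance_skew": self.halotolerance_skew,
            "halotolerance_cost": self.halotolerance_cost,
            "y_ref": self.y_ref,
            "sigma_range": list(self.sigma_range),
            "stratified_communities": self.stratified_communities,
            "community_sd": self.community_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        for key in ("richness_levels", "replicate_counts", "salinities", "assay_range", "sigma_range"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class CommunityDesign:
    """One assembled community: members and inoculated proportions.

    ``ry_expected`` maps each member strain to its expected relative yield
    RY_E,i — under common-density inoculation simply 1/N.
    """

    community_id: str
    group: str
    members: tuple
    ry_expected: dict

    def __post_init__(self):
        if set(self.members) != set(self.ry_expected):
            raise ValueError("ry_expected keys must equal the member set")
        total = math.fsum(self.ry_expected.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"ry_expected must sum to 1 (got {total!r})")

    @property
    def richness(self) -> int:
        return len(self.members)


@dataclass
class MixtureObservation:
    """Observed outcome of one mixture culture at one salinity."""

    community_id: str
    salinity: float
    y_o: float
    member_yields: dict | None = None
    rel_abundance: dict | None = None

    def __post_init__(self):
        if self.y_o < 0:
            raise ValueError("Y_O must be >= 0")
        if self.member_yields is not None and self.y_o > 0:
            total = math.fsum(self.member_yields.values())
            if abs(total - self.y_o) > 1e-9 * max(self.y_o, 1.0):
                raise ValueError("member yields must sum to Y_O")
        if self.rel_abundance is not None and self.rel_abundance:
            total = math.fsum(self.rel_abundance.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("relative abundances must sum to 1")


@dataclass
class Experiment:
    """A complete simulated experiment: inputs and observations as tables."""

    config: SimulationConfig
    library: list
    designs: list
    monocultures: pd.DataFrame
    observations: pd.DataFrame
    member_yields: pd.DataFrame


# ---------------------------------------------------------------------------
# strain library

def generate_strain_library(config: SimulationConfig) -> list:
    """Draw a reproducible strain library spanning the salinity assay range.

    Tolerance optima are placed on a jittered stratified grid over the assay
    range, skewed toward low salinity (``halotolerance_skew``); maximum yields
    decline with the optimum (``halotolerance_cost``), reflecting the
    metabolic cost of osmoadaptation. After drawing, tolerance breadths are
    widened where needed so every configured culture salinity lies within one
    ``sigma_tol`` of at least one optimum — guaranteeing that assembled
    communities can grow at every treatment.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STREAM_LIBRARY)
    n = config.n_strains
    lo, hi = config.assay_range
    span = hi - lo

    u = rng.uniform(size=n)
    quantiles = (np.arange(n) + u) / n
    s_opt = lo + span * quantiles ** config.halotolerance_skew
    sigma = rng.uniform(config.sigma_range[0], config.sigma_range[1], size=n)
    y_max = (
        config.y_ref
        * np.exp(-config.halotolerance_cost * (s_opt - lo) / span)
        * 10 ** rng.normal(0.0, 0.04, size=n)
    )

    # Coverage guarantee: each culture salinity within one sigma of an optimum.
    for s in config.salinities:
        dist = np.abs(s_opt - s)
        if not np.any(dist <= sigma):
            i = int(np.argmin(dist))
            sigma[i] = dist[i] * 1.0001

    width = len(str(n))
    profiles = [
        StrainProfile(
            strain_id=f"S{i + 1:0{width}d}",
            genus=GENUS_POOL[i % len(GENUS_POOL)],
            s_opt=float(np.clip(s_opt[i], lo, hi)),
            sigma_tol=float(sigma[i]),
            y_max=float(y_max[i]),
        )
        for i in range(n)
    ]
    return profiles


def tolerance_yield(strain: StrainProfile, salinity: float) -> float:
    """Expected monoculture yield at ``salinity`` from the Gaussian tolerance curve.

    ``y_max * exp(-(salinity - s_opt)^2 / (2 sigma_tol^2))``; maximal exactly
    at ``s_opt``.
    """
    if salinity < 0:
        raise ValueError(f"salinity must be >= 0 (got {salinity})")
    z = (salinity - strain.s_opt) / strain.sigma_tol
    return strain.y_max * math.exp(-0.5 * z * z)


def simulate_monocultures(library: list, config: SimulationConfig) -> pd.DataFrame:
    """Stationary-phase monoculture yield of every strain at every salinity.

    Returns a long table (strain_id, salinity_pct, yield): tolerance-curve
    value times multiplicative lognormal noise (sd ``noise_sd`` on the log10
    scale); values below ``detection_floor`` are recorded as 0. With
    ``noise_sd = 0`` the table equals the (floored) tolerance-curve values
    exactly.
    """
    if not library:
        raise ValueError("strain library is empty")
    rng = _stage_rng(config.seed, _STREAM_MONOCULTURE)
    rows = []
    for strain in library:
        for s in config.salinities:
            mu = tolerance_yield(strain, s)
            y = mu if config.noise_sd == 0 else mu * 10 ** rng.normal(0.0, config.noise_sd)
            if y < config.detection_floor:
                y = 0.0
            rows.append((strain.strain_id, s, y))
    return pd.DataFrame(rows, columns=["strain_id", "salinity_pct", "yield"])


# ---------------------------------------------------------------------------
# community design

def _sample_distinct_combinations(ids, size, count, rng):
    """``count`` pairwise-distinct sorted member tuples of ``size`` from ``ids``."""
    n = len(ids)
    total = math.comb(n, size)
    if count > total:
        raise DesignInfeasibleError(
            f"{count} distinct communities of {size} strains requested but only "
            f"C({n},{size}) = {total} combinations exist"
        )
    if total <= max(1000, 4 * count):
        from itertools import combinations

        pool = list(combinations(range(n), size))
        picks = rng.choice(total, size=count, replace=False)
        chosen = [pool[int(k)] for k in picks]
    else:
        seen, chosen = set(), []
        while len(chosen) < count:
            combo = tuple(sorted(rng.choice(n, size=size, replace=False).tolist()))
            if combo not in seen:
                seen.add(combo)
                chosen.append(combo)
    return [tuple(ids[i] for i in combo) for combo in chosen]


def _sample_stratified_combinations(library, size, count, rng):
    """Distinct combinations balanced across s_opt quartile tolerance classes."""
    order = np.argsort([p.s_opt for p in library], kind="stable")
    classes = np.array_split(order, min(4, size))
    seen, chosen = set(), []
    attempts = 0
    while len(chosen) < count:
        attempts += 1
        if attempts > 1000 * count:
            raise DesignInfeasibleError(
                f"could not draw {count} distinct stratified communities of size {size}"
            )
        quota = [size // len(classes)] * len(classes)
        for i in rng.choice(len(classes), size=size % len(classes), replace=False):
            quota[int(i)] += 1
        picked = []
        for cls, q in zip(classes, quota):
            q = min(q, len(cls))
            picked.extend(rng.choice(cls, size=q, replace=False).tolist())
        while len(picked) < size:  # top up if a class was too small
            extra = int(rng.choice(len(library)))
            if extra not in picked:
                picked.append(extra)
        combo = tuple(sorted(picked))
        if combo not in seen:
            seen.add(combo)
            chosen.append(combo)
    return [tuple(library[i].strain_id for i in combo) for combo in chosen]


def design_communities(library: list, config: SimulationConfig) -> list:
    """Assemble the richness-gradient community designs (groups A, B, ...).

    Within each group below full richness, member sets are pairwise distinct,
    sampled without replacement from the C(n, N) combination space (optionally
    stratified across salt-tolerance classes). At full richness only one
    composition exists; it is replicated under distinct community ids.
    Every member is inoculated at the common density RY_E = 1/N.
    """
    config.validate()
    if max(config.richness_levels) > len(library):
        raise DesignInfeasibleError(
            f"richness level {max(config.richness_levels)} exceeds library size {len(library)}"
        )
    rng = _stage_rng(config.seed, _STREAM_DESIGN)
    ids = [p.strain_id for p in library]
    designs = []
    for gi, (richness, reps) in enumerate(zip(config.richness_levels, config.replicate_counts)):
        group = chr(ord("A") + gi)
        if richness == len(library):
            member_sets = [tuple(ids)] * reps
        elif config.stratified_communities:
            member_sets = _sample_stratified_combinations(library, richness, reps, rng)
        else:
            member_sets = _sample_distinct_combinations(ids, richness, reps, rng)
        for ri, members in enumerate(member_sets, start=1):
            ry = 1.0 / richness
            designs.append(
                CommunityDesign(
                    community_id=f"{group}{ri}",
                    group=group,
                    members=tuple(members),
                    ry_expected={m: ry for m in members},
                )
            )
    return designs


# ---------------------------------------------------------------------------
# mixture outcomes

def _mono_lookup(monocultures: pd.DataFrame) -> dict:
    return {
        (row.strain_id, row.salinity_pct): row[2]
        for row in monocultures.itertuples(index=False)
    }


def simulate_mixture(
    design: CommunityDesign,
    monocultures: pd.DataFrame | dict,
    config: SimulationConfig,
    salinity: float,
    rng: np.random.Generator | None = None,
) -> MixtureObservation:
    """Simulate one mixture culture under the documented generative model.

    ``monocultures`` may be the long table from :func:`simulate_monocultures`
    or a pre-built ``{(strain_id, salinity): M}`` dict. ``rng`` defaults to a
    fresh mixture-stage generator derived from ``config.seed`` (pass one
    explicitly when simulating many mixtures in sequence).
    """
    salinity = float(salinity)
    mono = monocultures if isinstance(monocultures, dict) else _mono_lookup(monocultures)
    if rng is None:
        rng = _stage_rng(config.seed, _STREAM_MIXTURE)

    members = list(design.members)
    try:
        m_all = np.array([mono[(sid, salinity)] for sid in members], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no monoculture row for {exc.args[0]} at salinity {salinity}") from exc

    viable = m_all > config.detection_floor
    yields = {sid: 0.0 for sid in members}
    if not viable.any():
        warnings.warn(
            f"community {design.community_id}: no member grows at {salinity}% salinity",
            NoGrowthWarning,
            stacklevel=2,
        )
        return MixtureObservation(design.community_id, salinity, 0.0, member_yields=yields)

    sub = [sid for sid, v in zip(members, viable) if v]
    m = m_all[viable]
    n_v = len(sub)
    ry_e = np.array([design.ry_expected[sid] for sid in sub], dtype=float)
    ry_e = ry_e / ry_e.sum()  # renormalized over the viable sub-community

    theta, phi = config.theta(salinity), config.phi(salinity)
    m_bar = m.mean()
    ry_o = ry_e * (1.0 + phi * (1.0 - 1.0 / n_v)) + (theta / n_v) * (m / m_bar - 1.0)
    if np.any(ry_o < 0):
        warnings.warn(
            f"community {design.community_id}: selection tilt clipped at zero "
            f"(theta={theta} too strong for this composition)",
            ClippedYieldWarning,
            stacklevel=2,
        )
        ry_o = np.clip(ry_o, 0.0, None)

    base = ry_o * m
    factor = 1.0 if config.noise_sd == 0 else 10 ** rng.normal(0.0, config.noise_sd)
    obs = base * factor
    for sid, y in zip(sub, obs):
        yields[sid] = float(y)
    return MixtureObservation(design.community_id, salinity, float(obs.sum()), member_yields=yields)


def simulate_experiment(config: SimulationConfig, library: list | None = None) -> Experiment:
    """Run the full generator: library, monocultures, designs, all mixtures.

    Every community is cultured at every configured salinity. Returns an
    :class:`Experiment` whose ``observations`` table (community_id, group,
    salinity_pct, richness, Y_O) and ``member_yields`` table (community_id,
    salinity_pct, strain_id, yield) feed the downstream modules directly.
    """
    if library is None:
        library = generate_strain_library(config)
    monocultures = simulate_monocultures(library, config)
    designs = design_communities(library, config)
    mono = _mono_lookup(monocultures)
    rng = _stage_rng(config.seed, _STREAM_MIXTURE)

    # Replicate-identity offsets: one lognormal factor per community, shared
    # by all of its mixtures. Drawn first so the mixture stream is unchanged
    # when community_sd == 0.
    if config.community_sd > 0:
        offsets = {
            d.community_id: 10 ** rng.normal(0.0, config.community_sd) for d in designs
        }
    else:
        offsets = {d.community_id: 1.0 for d in designs}

    obs_rows, member_rows = [], []
    for design in designs:
        off = offsets[design.community_id]
        for s in config.salinities:
            ob = simulate_mixture(design, mono, config, s, rng=rng)
            obs_rows.append((design.community_id, design.group, s, design.richness, ob.y_o * off))
            for sid in design.members:
                member_rows.append((design.community_id, s, sid, ob.member_yields[sid] * off))
    observations = pd.DataFrame(
        obs_rows, columns=["community_id", "group", "salinity_pct", "richness", "Y_O"]
    )
    member_yields = pd.DataFrame(
        member_rows, columns=["community_id", "salinity_pct", "strain_id", "yield"]
    )
    return Experiment(config, library, designs, monocultures, observations, member_yields)


def composition_table(experiment: Experiment, groups: tuple = ("D",)) -> pd.DataFrame:
    """Genus-level relative abundances for the chosen groups.

    Emulates sequencing-based composition profiling of the highest-diversity
    mixtures: per community x salinity, each genus's proportion of total
    yield. Rows with zero total yield are omitted (nothing to profile).
    """
    genus_of = {p.strain_id: p.genus for p in experiment.library}
    keep = {d.community_id for d in experiment.designs if d.group in groups}
    rows = []
    my = experiment.member_yields
    for (cid, s), grp in my[my.community_id.isin(keep)].groupby(["community_id", "salinity_pct"]):
        total = grp["yield"].sum()
        if total <= 0:
            continue
        by_genus = grp.assign(genus=grp.strain_id.map(genus_of)).groupby("genus")["yield"].sum()
        for genus, y in by_genus.items():
            rows.append((cid, s, genus, y / total))
    return pd.DataFrame(rows, columns=["community_id", "salinity_pct", "genus", "proportion"])


# ---------------------------------------------------------------------------
# persistence

def write_experiment(experiment: Experiment, path) -> dict:
    """Write the experiment file set (CSV tables + YAML config echo).

    Emits strains.csv, designs.csv, monocultures.csv, observations.csv,
    member_yields.csv and config.yaml under ``path``; returns
    ``{filename: row_count}``. Tables round-trip losslessly through
    :func:`read_experiment`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    strains = pd.DataFrame(
        [(p.strain_id, p.genus, p.s_opt, p.sigma_tol, p.y_max) for p in experiment.library],
        columns=["strain_id", "genus", "s_opt", "sigma_tol", "y_max"],
    )
    designs = pd.DataFrame(
        [
            (d.community_id, d.group, sid, d.ry_expected[sid])
            for d in experiment.designs
            for sid in d.members
        ],
        columns=["community_id", "group", "strain_id", "ry_expected"],
    )
    tables = {
        "strains.csv": strains,
        "designs.csv": designs,
        "monocultures.csv": experiment.monocultures,
        "observations.csv": experiment.observations,
        "member_yields.csv": experiment.member_yields,
    }
    counts = {}
    for name, table in tables.items():
        _io.write_table(table, path / name)
        counts[name] = len(table)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(experiment.config.to_dict(), fh, sort_keys=False)
    counts["config.yaml"] = 1
    return counts


def read_experiment(path) -> Experiment:
    """Read an experiment file set written by :func:`write_experiment`."""
    path = Path(path)
    with open(path / "config.yaml") as fh:
        config = SimulationConfig.from_dict(yaml.safe_load(fh))

    strains = _io.read_table(path / "strains.csv", _io.STRAINS_COLUMNS)
    library = [
        StrainProfile(r.strain_id, r.genus, r.s_opt, r.sigma_tol, r.y_max)
        for r in strains.itertuples(index=False)
    ]
    designs_df = _io.read_table(path / "designs.csv", _io.DESIGNS_COLUMNS)
    designs = []
    for (cid, group), grp in designs_df.groupby(["community_id", "group"], sort=False):
        designs.append(
            CommunityDesign(
                community_id=cid,
                group=group,
                members=tuple(grp.strain_id),
                ry_expected=dict(zip(grp.strain_id, grp.ry_expected)),
            )
        )
    monocultures = _io.read_table(path / "monocultures.csv", _io.MONOCULTURES_COLUMNS)
    observations = _io.read_table(path / "observations.csv", _io.OBSERVATIONS_COLUMNS)
    member_yields = _io.read_table(path / "member_yields.csv", _io.MEMBER_YIELDS_COLUMNS)
    return Experiment(config, library, designs, monocultures, observations, member_yields)
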