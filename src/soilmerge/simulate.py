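"""Synthetic soil-microcosm experiments with known ground truth.

The generator emulates the statistical structure of a two-phase microcosm
coalescence study so that every analysis stage can be exercised against a
known answer:

* two taxa-diverse resident communities ("SC", soil-derived, and "LC",
  lake-derived) sharing a configurable fraction of genera but almost no
  ASVs, plus a defined 21-member transplant community ("SynCom");
* phenomenological guild templates for taxon trajectories — *fast bloomers*
  peak at day 3 and crash by day 7, *slow growers* rise monotonically,
  *decliners* fall monotonically — scaled so the community total follows a
  configured trajectory (default: 100-fold growth by day 3, then decline
  and stabilisation);
* four biological replicates per condition, sampled at days 0/3/7/21/60,
  with per-sample log-normal replicate variation, multinomial read
  sampling at a drawn library depth, and log-normal measurement noise on
  the flow-cytometry / CFU / DNA totals;
* mergers that mix two grown communities by soil mass, let transplant
  members decay to below 1% relative abundance by day 60, and optionally
  inject known displacement effects (a chosen ASV set shifted by delta
  log10 units in the merged community from an onset day), recorded as
  ground truth.

Everything is deterministic for a fixed scenario seed.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import tables

__all__ = [
    "GUILD_PROFILES",
    "DisplacementEffect",
    "ScenarioConfig",
    "SyntheticExperiment",
    "generate_community",
    "dilute_community",
    "generate_merger",
    "generate_coalescence_dataset",
    "phase2_composition",
    "write_experiment",
    "read_experiment",
]

#: Multiplicative trajectory templates per guild (day -> fold change of a
#: taxon's weight relative to day 0); interpolated log-linearly in between.
GUILD_PROFILES: dict[str, dict[float, float]] = {
    "fast_bloomer": {0: 1.0, 3: 300.0, 7: 30.0, 21: 15.0, 60: 10.0},
    "slow_grower": {0: 1.0, 3: 20.0, 7: 60.0, 21: 120.0, 60: 130.0},
    "decliner": {0: 1.0, 3: 0.6, 7: 0.15, 21: 0.03, 60: 0.01},
}

#: Phyla a guild's genera are drawn from (fast copiotrophs vs slow
#: oligotroph-leaning soil phyla).
GUILD_PHYLA: dict[str, tuple[str, ...]] = {
    "fast_bloomer": ("Proteobacteria", "Bacteroidetes", "Firmicutes"),
    "slow_grower": (
        "Actinobacteria",
        "Verrucomicrobia",
        "Acidobacteria",
        "Planctomycetes",
        "Gemmatimonadetes",
    ),
    "decliner": (
        "Proteobacteria",
        "Bacteroidetes",
        "Firmicutes",
        "Chloroflexi",
        "Cyanobacteria",
    ),
}

#: Genus names (and phyla) for the cultured transplant isolates.
_SYNCOM_POOL: tuple[tuple[str, str], ...] = (
    ("Lysobacter", "Proteobacteria"),
    ("Pseudomonas", "Proteobacteria"),
    ("Sphingomonas", "Proteobacteria"),
    ("Rhizobium", "Proteobacteria"),
    ("Mesorhizobium", "Proteobacteria"),
    ("Cupriavidus", "Proteobacteria"),
    ("Variovorax", "Proteobacteria"),
    ("Ensifer", "Proteobacteria"),
    ("Brevundimonas", "Proteobacteria"),
    ("Bacillus", "Firmicutes"),
    ("Paenibacillus", "Firmicutes"),
    ("Arthrobacter", "Actinobacteria"),
    ("Streptomyces", "Actinobacteria"),
    ("Rhodococcus", "Actinobacteria"),
    ("Microbacterium", "Actinobacteria"),
    ("Cellulomonas", "Actinobacteria"),
    ("Flavobacterium", "Bacteroidetes"),
    ("Chryseobacterium", "Bacteroidetes"),
    ("Pedobacter", "Bacteroidetes"),
    ("Dyadobacter", "Bacteroidetes"),
    ("Mucilaginibacter", "Bacteroidetes"),
)


@dataclass(frozen=True)
class DisplacementEffect:
    """A known displacement injected into the merged community.

    ``asv_ids`` are resident ASVs whose relative weight is multiplied by
    10**``delta_log10`` from ``onset_day`` onward (positive = enriched,
    negative = depleted)."""

    asv_ids: tuple[str, ...]
    delta_log10: float
    onset_day: float = 3.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_log10):
            raise ValueError("delta_log10 must be finite")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the emulated microcosm study.

    Defaults mirror the study design the analyses assume: 4 biological
    replicates, sampling at days 0/3/7/21/60, ~10^6 cells g^-1 seeding,
    ~100-fold community growth by day 3, a 21-member transplant, 28% genus
    but 1% ASV overlap between the two resident origins, and transplant
    decay to below 1% relative abundance within two months of a merger.
    """

    seed: int = 0
    n_replicates: int = 4
    days: tuple[float, ...] = (0, 3, 7, 21, 60)
    n_asvs: int = 400
    n_genera: int = 120
    overlap_genus_fraction: float = 0.28
    overlap_asv_fraction: float = 0.01
    n_syncom_members: int = 21
    syncom_shared_with_residents: int = 1
    read_depth_mean: float = 1_200_000.0
    read_depth_cv: float = 0.10
    initial_total: float = 1e6  # cells g^-1 at seeding
    total_fold: Mapping[float, float] = field(
        default_factory=lambda: {0: 1.0, 3: 100.0, 7: 45.0, 21: 30.0, 60: 25.0}
    )
    origin_size_factor: Mapping[str, float] = field(
        default_factory=lambda: {"SC": 1.0, "LC": 0.4, "SynCom": 1.5}
    )
    guild_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"fast_bloomer": 0.3, "slow_grower": 0.4, "decliner": 0.3}
    )
    base_abundance_sigma_log10: float = 1.0
    replicate_sigma_log10: float = 0.15
    fc_noise_cv: float = 0.15
    culturability: Mapping[str, float] = field(
        default_factory=lambda: {"SC": 1.0, "LC": 0.3, "SynCom": 1.0}
    )
    genome_pg: Mapping[str, float] = field(
        default_factory=lambda: {"SC": 0.00511, "LC": 0.00292, "SynCom": 0.00511}
    )
    mixing_fractions: tuple[float, float] = (0.1, 0.1)
    transplant_share: Mapping[float, float] = field(
        default_factory=lambda: {3: 0.35, 7: 0.15, 21: 0.03, 60: 0.004}
    )
    merger_size_boost: Mapping[float, float] = field(
        default_factory=lambda: {0: 1.0, 3: 1.6, 7: 1.4, 21: 1.0, 60: 0.9}
    )
    displacement_effects: tuple[DisplacementEffect, ...] = ()

    def __post_init__(self) -> None:
        for name in ("overlap_genus_fraction", "overlap_asv_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        days = tuple(self.days)
        if list(days) != sorted(set(days)):
            raise ValueError("days must be strictly increasing")
        if self.n_syncom_members < 1:
            raise ValueError("n_syncom_members must be >= 1")
        if sum(self.mixing_fractions) > 1:
            raise ValueError("mixing fractions must sum to <= 1")
        unknown = set(self.guild_fractions) - set(GUILD_PROFILES)
        if unknown:
            raise ValueError(f"unknown guild(s) in guild_fractions: {sorted(unknown)}")
        total = sum(self.guild_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"guild fractions must sum to 1, got {total}")
        object.__setattr__(self, "days", days)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        d["mixing_fractions"] = list(self.mixing_fractions)
        d["displacement_effects"] = [
            {"asv_ids": list(e.asv_ids), "delta_log10": e.delta_log10, "onset_day": e.onset_day}
            for e in self.displacement_effects
        ]
        for key in ("total_fold", "transplant_share", "merger_size_boost"):
            d[key] = {float(k): float(v) for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "days" in d:
            d["days"] = tuple(d["days"])
        if "mixing_fractions" in d:
            d["mixing_fractions"] = tuple(d["mixing_fractions"])
        if "displacement_effects" in d:
            d["displacement_effects"] = tuple(
                e
                if isinstance(e, DisplacementEffect)
                else DisplacementEffect(
                    asv_ids=tuple(e["asv_ids"]),
                    delta_log10=float(e["delta_log10"]),
                    onset_day=float(e.get("onset_day", 3.0)),
                )
                for e in d["displacement_effects"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SyntheticExperiment:
    """A generated dataset bundle plus its ground truth.

    ``truth`` holds three frames: ``"abundance"`` (true per-sample cells
    g^-1 for every taxon), ``"members"`` (taxon -> genus, phylum, guild,
    origin and deterministic base weight) and ``"displaced"`` (injected
    displacement effects)."""

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    sizes: pd.DataFrame
    syncom_members: frozenset[str]
    truth: dict[str, pd.DataFrame]
    origin: str | None = None
    config: ScenarioConfig | None = None


# ---------------------------------------------------------------------------
# deterministic machinery


def _rng(seed: int, stream: int, key: str = "") -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), stream, zlib.crc32(key.encode())])
    )


def _log_interp(profile: Mapping[float, float], day: float) -> float:
    xs = np.array(sorted(profile))
    ys = np.log10([profile[x] for x in xs])
    return float(10 ** np.interp(day, xs, ys))


def _guild_multiplier(guild: str, day: float) -> float:
    return _log_interp(GUILD_PROFILES[guild], day)


def _total_at(config: ScenarioConfig, origin: str, day: float, start_total: float | None = None) -> float:
    base = config.initial_total if start_total is None else start_total
    fold = _log_interp(dict(config.total_fold), day)
    factor = dict(config.origin_size_factor).get(origin, 1.0) if day >= 7 else 1.0
    return base * fold * factor


def _composition_path(members: pd.DataFrame, days: Sequence[float]) -> pd.DataFrame:
    """Deterministic relative composition (rows: days, columns: taxa)."""
    weights = np.empty((len(days), len(members)))
    guilds = members["guild"].to_numpy()
    base = members["base_abundance"].to_numpy(dtype=float)
    for i, day in enumerate(days):
        mult = np.array([_guild_multiplier(g, day) for g in guilds])
        weights[i] = base * mult
    rel = weights / weights.sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, index=list(days), columns=members.index)


def _make_genera(
    rng: np.random.Generator, prefix: str, n: int, config: ScenarioConfig
) -> pd.DataFrame:
    guild_names = list(config.guild_fractions)
    probs = np.array([config.guild_fractions[g] for g in guild_names])
    guilds = rng.choice(guild_names, size=n, p=probs)
    phyla = [rng.choice(GUILD_PHYLA[g]) for g in guilds]
    return pd.DataFrame(
        {"guild": guilds, "phylum": phyla},
        index=pd.Index([f"{prefix}_{i:03d}" for i in range(n)], name="genus"),
    )


def _taxa_universe(config: ScenarioConfig) -> dict[str, pd.DataFrame]:
    """Deterministic taxon membership for SC, LC and SynCom.

    Shared genera (and their guilds) are identical across resident origins;
    ASV identifiers are origin-specific except for a small shared set,
    mirroring high genus-level but minimal ASV-level overlap between the
    two inocula."""
    rng = _rng(config.seed, 101)
    n_shared_g = max(1, round(config.overlap_genus_fraction * config.n_genera))
    shared_gen = _make_genera(rng, "g_shared", n_shared_g, config)
    exclusive = {
        origin: _make_genera(rng, f"g_{origin}", config.n_genera - n_shared_g, config)
        for origin in ("SC", "LC")
    }
    n_shared_a = max(1, round(config.overlap_asv_fraction * config.n_asvs))
    shared_asv_genera = rng.choice(shared_gen.index, size=n_shared_a)
    shared_asv_ids = [f"asv_shared_{i:03d}" for i in range(n_shared_a)]

    members: dict[str, pd.DataFrame] = {}
    for origin in ("SC", "LC"):
        genera = pd.concat([shared_gen, exclusive[origin]])
        n_own = config.n_asvs - n_shared_a
        own_genera = rng.choice(genera.index, size=n_own)
        asv_ids = shared_asv_ids + [f"asv_{origin}_{i:04d}" for i in range(n_own)]
        asv_genus = np.concatenate([shared_asv_genera, own_genera])
        df = pd.DataFrame(
            {
                "genus": asv_genus,
                "phylum": genera.loc[asv_genus, "phylum"].to_numpy(),
                "guild": genera.loc[asv_genus, "guild"].to_numpy(),
                "origin": origin,
                "base_abundance": 10
                ** rng.normal(0.0, config.base_abundance_sigma_log10, len(asv_ids)),
            },
            index=pd.Index(asv_ids, name="asv_id"),
        )
        members[origin] = df

    # transplant: cultured isolates, optionally sharing ASV(s) with residents
    n_shared_syn = min(config.syncom_shared_with_residents, n_shared_a)
    syn_ids, syn_genus, syn_phylum, syn_guild = [], [], [], []
    for i in range(n_shared_syn):
        syn_ids.append(shared_asv_ids[i])
        g = shared_asv_genera[i]
        syn_genus.append(g)
        syn_phylum.append(shared_gen.loc[g, "phylum"])
        syn_guild.append(shared_gen.loc[g, "guild"])
    n_pool = config.n_syncom_members - n_shared_syn
    syn_guild_names = list(config.guild_fractions)
    for i in range(n_pool):
        name, phylum = _SYNCOM_POOL[i % len(_SYNCOM_POOL)]
        if i >= len(_SYNCOM_POOL):
            name = f"{name}_{i // len(_SYNCOM_POOL)}"
        syn_ids.append(f"asv_syn_{i:02d}")
        syn_genus.append(name)
        syn_phylum.append(phylum)
        # cultured isolates are copiotroph-leaning: no pure decliners
        syn_guild.append(
            "fast_bloomer"
            if name == "Lysobacter"
            else rng.choice(["fast_bloomer", "slow_grower"], p=[0.4, 0.6])
        )
    members["SynCom"] = pd.DataFrame(
        {
            "genus": syn_genus,
            "phylum": syn_phylum,
            "guild": syn_guild,
            "origin": "SynCom",
            "base_abundance": 10 ** rng.normal(0.0, 0.5, len(syn_ids)),
        },
        index=pd.Index(syn_ids, name="asv_id"),
    )
    return members


def _sample_block(
    condition: str,
    origin: str,
    members: pd.DataFrame,
    path: pd.DataFrame,
    totals: Mapping[float, float],
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Observe one condition: counts, metadata, sizes and true abundances."""
    rng = _rng(config.seed, 202, condition)
    cv = config.fc_noise_cv
    sigma_ln = float(np.sqrt(np.log1p(cv**2)))
    depth_sigma = float(np.sqrt(np.log1p(config.read_depth_cv**2)))
    depth_mu = float(np.log(config.read_depth_mean) - depth_sigma**2 / 2)
    cult = dict(config.culturability).get(origin, 1.0)
    g_pg = dict(config.genome_pg).get(origin, 0.005)
    taxa = path.columns
    counts_rows, truth_rows, meta_rows, size_rows, sample_ids = [], [], [], [], []
    for rep in range(1, config.n_replicates + 1):
        for day in path.index:
            sid = f"{condition}.r{rep}.d{day:g}"
            rel = path.loc[day].to_numpy()
            noise = 10 ** rng.normal(0.0, config.replicate_sigma_log10, len(taxa))
            abund = rel * totals[day] * noise
            total_true = abund.sum()
            fc = total_true * rng.lognormal(-(sigma_ln**2) / 2, sigma_ln)
            cfu = fc * cult * rng.lognormal(-(sigma_ln**2) / 2, sigma_ln)
            dna = (
                total_true * g_pg / 1000.0 * rng.lognormal(-(sigma_ln**2) / 2, sigma_ln)
            )
            depth = int(round(rng.lognormal(depth_mu, depth_sigma)))
            counts_rows.append(rng.multinomial(depth, abund / total_true))
            truth_rows.append(abund)
            meta_rows.append((condition, rep, float(day)))
            size_rows.append((fc, cfu, dna))
            sample_ids.append(sid)
    index = pd.Index(sample_ids, name=tables.SAMPLE_INDEX)
    counts = pd.DataFrame(np.array(counts_rows), index=index, columns=taxa)
    truth = pd.DataFrame(np.array(truth_rows), index=index, columns=taxa)
    metadata = pd.DataFrame(
        meta_rows, index=index, columns=["condition", "replicate", "day"]
    )
    sizes = pd.DataFrame(size_rows, index=index, columns=["fc_total", "cfu_total", "dna_conc"])
    return counts, metadata, sizes, truth


def _as_experiment(
    condition: str,
    origin: str,
    members: pd.DataFrame,
    path: pd.DataFrame,
    totals: Mapping[float, float],
    config: ScenarioConfig,
    syncom_members: frozenset[str] = frozenset(),
    displaced: pd.DataFrame | None = None,
) -> SyntheticExperiment:
    counts, metadata, sizes, truth_ab = _sample_block(
        condition, origin, members, path, totals, config
    )
    taxonomy = members[["genus", "phylum"]].copy()
    if displaced is None:
        displaced = pd.DataFrame(columns=["asv_id", "delta_log10", "onset_day"])
    return SyntheticExperiment(
        counts=counts,
        taxonomy=taxonomy,
        metadata=metadata,
        sizes=sizes,
        syncom_members=syncom_members,
        truth={"abundance": truth_ab, "members": members.copy(), "displaced": displaced},
        origin=origin,
        config=config,
    )


# ---------------------------------------------------------------------------
# public generators


def generate_community(config: ScenarioConfig, origin: str = "SC") -> SyntheticExperiment:
    """Phase-I single community grown from a fresh inoculum."""
    universe = _taxa_universe(config)
    if origin not in universe:
        raise ValueError(f"origin must be one of {sorted(universe)}, got {origin!r}")
    members = universe[origin]
    path = _composition_path(members, config.days)
    totals = {day: _total_at(config, origin, day) for day in config.days}
    syn = frozenset(members.index) if origin == "SynCom" else frozenset()
    return _as_experiment(origin, origin, members, path, totals, config, syn)


def _final_state(exp: SyntheticExperiment) -> tuple[pd.DataFrame, float]:
    """Deterministic composition and total size at the end of phase I."""
    config = exp.config
    last = config.days[-1]
    members = exp.truth["members"]
    final_rel = _composition_path(members, [last]).iloc[0]
    final_total = _total_at(config, exp.origin, last)
    members2 = members.copy()
    members2["base_abundance"] = final_rel.to_numpy()
    return members2, final_total


def dilute_community(
    exp: SyntheticExperiment, config: ScenarioConfig | None = None
) -> SyntheticExperiment:
    """Phase-II non-merged control: the grown community diluted into fresh
    sterile soil (by the resident mass fraction), restarting growth."""
    config = config or exp.config
    members2, final_total = _final_state(exp)
    start_total = final_total * config.mixing_fractions[0]
    path = _composition_path(members2, config.days)
    totals = {
        day: _total_at(config, exp.origin, day, start_total=start_total)
        for day in config.days
    }
    syn = frozenset(members2.index) if exp.origin == "SynCom" else frozenset()
    return _as_experiment(exp.origin, exp.origin, members2, path, totals, config, syn)


def phase2_composition(exp: SyntheticExperiment, days: Sequence[float] | None = None) -> pd.DataFrame:
    """Deterministic phase-II control composition path (no noise); useful
    for choosing detectable ASVs when designing displacement scenarios."""
    members2, _ = _final_state(exp)
    return _composition_path(members2, days if days is not None else exp.config.days)


def generate_merger(
    resident: SyntheticExperiment,
    transplant: SyntheticExperiment,
    config: ScenarioConfig | None = None,
) -> SyntheticExperiment:
    """Phase-II coalescence: resident and transplant mixed by soil mass.

    Starting abundances are the mass-weighted mixture of the two grown
    communities; the transplant's summed relative share then follows the
    configured decay trajectory while its internal composition evolves by
    guild; displacement effects multiply the chosen resident ASVs by
    10**delta from their onset day (recorded as ground truth)."""
    config = config or resident.config
    if transplant is None or not len(transplant.truth["members"]):
        raise ValueError("transplant member set is empty")
    res_members, res_total = _final_state(resident)
    tra_members, tra_total = _final_state(transplant)
    f_res, f_tra = config.mixing_fractions
    start_res = res_total * f_res
    start_tra = tra_total * f_tra
    start_total = start_res + start_tra
    share0 = start_tra / start_total
    share_profile = {0.0: share0, **{float(k): float(v) for k, v in dict(config.transplant_share).items()}}

    res_path = _composition_path(res_members, config.days)
    tra_path = _composition_path(tra_members, config.days)

    # displacement effects apply to resident taxa only
    effects = config.displacement_effects
    for eff in effects:
        missing = set(eff.asv_ids) - set(res_members.index)
        if missing:
            raise KeyError(f"displacement effect targets unknown resident ASV(s): {sorted(missing)[:5]}")

    taxa = res_members.index.union(tra_members.index, sort=False)
    rows = []
    for day in config.days:
        share = _log_interp(share_profile, day) if day > 0 else share0
        res_rel = res_path.loc[day].copy()
        for eff in effects:
            if day >= eff.onset_day:
                res_rel[list(eff.asv_ids)] *= 10.0**eff.delta_log10
        res_rel /= res_rel.sum()
        combined = pd.Series(0.0, index=taxa)
        combined = combined.add(res_rel * (1.0 - share), fill_value=0.0)
        combined = combined.add(tra_path.loc[day] * share, fill_value=0.0)
        rows.append(combined.reindex(taxa).to_numpy())
    path = pd.DataFrame(rows, index=list(config.days), columns=taxa)

    members = pd.concat(
        [res_members, tra_members.loc[tra_members.index.difference(res_members.index, sort=False)]]
    ).loc[taxa]
    boost = dict(config.merger_size_boost)
    totals = {
        day: _total_at(config, resident.origin, day, start_total=start_total)
        * (_log_interp(boost, day) if boost else 1.0)
        for day in config.days
    }
    displaced = pd.DataFrame(
        [
            (asv, eff.delta_log10, eff.onset_day)
            for eff in effects
            for asv in eff.asv_ids
        ],
        columns=["asv_id", "delta_log10", "onset_day"],
    )
    condition = f"{resident.origin}+SynCom"
    return _as_experiment(
        condition,
        resident.origin,
        members,
        path,
        totals,
        config,
        syncom_members=frozenset(tra_members.index),
        displaced=displaced,
    )


def concat_experiments(experiments: Sequence[SyntheticExperiment]) -> SyntheticExperiment:
    """Union several condition blocks into one dataset (taxa aligned, 0-filled)."""
    taxa = experiments[0].counts.columns
    for exp in experiments[1:]:
        taxa = taxa.union(exp.counts.columns, sort=False)
    counts = pd.concat(
        [e.counts.reindex(columns=taxa, fill_value=0) for e in experiments]
    )
    truth_ab = pd.concat(
        [e.truth["abundance"].reindex(columns=taxa, fill_value=0.0) for e in experiments]
    )
    taxonomy = pd.concat([e.taxonomy for e in experiments])
    taxonomy = taxonomy[~taxonomy.index.duplicated()].reindex(taxa)
    members = pd.concat([e.truth["members"] for e in experiments])
    members = members[~members.index.duplicated()].reindex(taxa)
    nonempty = [e.truth["displaced"] for e in experiments if len(e.truth["displaced"])]
    displaced = (
        pd.concat(nonempty, ignore_index=True).drop_duplicates()
        if nonempty
        else pd.DataFrame(columns=["asv_id", "delta_log10", "onset_day"])
    )
    syn = frozenset().union(*(e.syncom_members for e in experiments))
    return SyntheticExperiment(
        counts=counts,
        taxonomy=taxonomy,
        metadata=pd.concat([e.metadata for e in experiments]),
        sizes=pd.concat([e.sizes for e in experiments]),
        syncom_members=syn,
        truth={"abundance": truth_ab, "members": members, "displaced": displaced},
        origin=None,
        config=experiments[0].config,
    )


def generate_coalescence_dataset(config: ScenarioConfig | None = None) -> SyntheticExperiment:
    """The full phase-II design: SC, LC and SynCom controls plus both mergers."""
    config = config or ScenarioConfig()
    sc = generate_community(config, "SC")
    lc = generate_community(config, "LC")
    syn = generate_community(config, "SynCom")
    blocks = [
        dilute_community(sc, config),
        dilute_community(lc, config),
        dilute_community(syn, config),
        generate_merger(sc, syn, config),
        generate_merger(lc, syn, config),
    ]
    return concat_experiments(blocks)


# ---------------------------------------------------------------------------
# persistence


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> Path:
    """Write counts/taxonomy/metadata/sizes, member list and truth tables."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        tables.write_count_table(exp.counts, outdir / "counts.tsv")
        tables.write_taxonomy(exp.taxonomy, outdir / "taxonomy.tsv")
        tables.write_metadata(exp.metadata, outdir / "metadata.tsv")
        tables.write_sizes(exp.sizes, outdir / "sizes.tsv")
        (outdir / "syncom_members.txt").write_text(
            "".join(f"{m}\n" for m in sorted(exp.syncom_members)), encoding="utf-8"
        )
        exp.truth["abundance"].to_csv(outdir / "truth" / "abundance.tsv", sep="\t", lineterminator="\n")
        exp.truth["members"].to_csv(outdir / "truth" / "members.tsv", sep="\t", lineterminator="\n")
        exp.truth["displaced"].to_csv(
            outdir / "truth" / "displaced.tsv", sep="\t", index=False, lineterminator="\n"
        )
    except OSError as err:
        raise OSError(f"failed writing experiment to {outdir}: {err}") from err
    return outdir


def read_experiment(outdir: str | Path) -> SyntheticExperiment:
    """Re-read a written experiment (truth tables included when present)."""
    outdir = Path(outdir)
    counts = tables.read_count_table(outdir / "counts.tsv")
    taxonomy = tables.read_taxonomy(outdir / "taxonomy.tsv")
    metadata = tables.read_metadata(outdir / "metadata.tsv")
    sizes = tables.read_sizes(outdir / "sizes.tsv")
    members_path = outdir / "syncom_members.txt"
    syn = frozenset(
        line.strip()
        for line in members_path.read_text(encoding="utf-8").splitlines()
        if line.strip()
    ) if members_path.exists() else frozenset()
    truth: dict[str, pd.DataFrame] = {}
    tdir = outdir / "truth"
    if (tdir / "abundance.tsv").exists():
        truth["abundance"] = pd.read_csv(tdir / "abundance.tsv", sep="\t", index_col=0)
    if (tdir / "members.tsv").exists():
        truth["members"] = pd.read_csv(tdir / "members.tsv", sep="\t", index_col=0)
    if (tdir / "displaced.tsv").exists():
        truth["displaced"] = pd.read_csv(tdir / "displaced.tsv", sep="\t")
    return SyntheticExperiment(
        counts=counts,
        taxonomy=taxonomy,
        metadata=metadata,
        sizes=sizes,
        syncom_members=syn,
        truth=truth,
    )
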