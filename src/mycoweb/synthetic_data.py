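"""Synthetic metacommunities with planted association structure.

The generator emulates the processed inputs of a two-country soil survey:
an OTU count table, per-sample metadata (country, region, management,
weather) and full ground truth for every planted construct.  Its
ecological skeleton:

* Sites lie on a temperature gradient; OTUs belong to one of K guilds
  whose niche optima tile the gradient, each OTU's optimum jittered
  around its guild centre.
* Each site follows one of two occupancy regimes mapped from its farming
  management.  *Cooperative* sites (biodynamic-like) filter species by
  temperature niche and apply a shared site-quality factor that co-boosts
  every resident — producing mixed, densely associated communities.
  *Partitioned* sites (conventional-like) are dominated by the guild
  whose optimum matches the local temperature; species of other guilds
  are suppressed by the exclusion strength epsilon irrespective of their
  optima — producing niche-partitioned communities that still harbour
  thinned remnants of every guild.  Organic sites mix the two regimes.
* Occupancy carries all of the ecological signal; the abundance layer
  (lognormal weights, multinomial reads at the site's depth) exists to
  exercise rarefaction realistically.
* A fraction of OTUs is flagged as plant pathogens; their occupancy is
  additionally suppressed at partitioned sites, planting a negative
  relationship between pathogen richness and co-exclusion structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community_io import CommunityMatrix, write_otu_table

REGIME_COOPERATIVE = "cooperative"
REGIME_PARTITIONED = "partitioned"

#: management -> occupancy regime; organic mixes the two
REGIME_MAP = {
    "conventional": REGIME_PARTITIONED,
    "biodynamic": REGIME_COOPERATIVE,
}


@dataclass
class CountryConfig:
    """Survey design of one country: sites per management and climate band."""

    name: str
    management_counts: dict[str, int]
    temp_range: tuple[float, float]
    region_names: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return sum(self.management_counts.values())


def _default_countries() -> tuple[CountryConfig, ...]:
    # site counts echo the survey design: 175 sites per country with
    # management known for 124 (ES) and 172 (US) of them
    return (
        CountryConfig(
            "ES",
            {"conventional": 65, "organic": 39, "biodynamic": 20, "unknown": 51},
            (14.0, 27.0),
            ("Spain_west", "Spain_east", "Spain_islands"),
        ),
        CountryConfig(
            "US",
            {"conventional": 78, "organic": 79, "biodynamic": 15, "unknown": 3},
            (10.0, 23.0),
            ("USA_northwest", "USA_southwest", "USA_east"),
        ),
    )


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic metacommunity.

    The defaults are the study conditions the rest of the package is
    tested under; see the methods note for the rationale behind each
    value.
    """

    countries: tuple[CountryConfig, ...] = field(default_factory=_default_countries)
    n_otus: int = 600
    n_guilds: int = 4
    #: niche breadth (deg C) per regime: cooperative sites sort by
    #: temperature; partitioned sites are governed by guild dominance, so
    #: their thermal filter is broad
    niche_breadth: dict = field(
        default_factory=lambda: {REGIME_COOPERATIVE: 1.8, REGIME_PARTITIONED: 9.0}
    )
    guild_jitter: float = 2.5  # sd of OTU optima around the guild centre
    exclusion_strength: float = 0.7  # epsilon: cross-guild suppression
    base_occupancy: float = 0.35
    site_quality_sd: float = 0.7  # lognormal sd of the cooperative co-boost
    organic_coop_weight: float = 0.5  # P(cooperative) for organic sites
    depth_range: tuple[int, int] = (21_000, 40_000)  # reads per sample
    abundance_lognormal: tuple[float, float] = (0.0, 1.0)
    pathogen_fraction: float = 0.05
    pathogen_suppression: float = 0.8  # extra suppression at partitioned sites
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.exclusion_strength <= 1:
            raise ValueError("exclusion_strength must lie in [0, 1]")
        for regime, sigma in self.niche_breadth.items():
            if sigma <= 0:
                raise ValueError(f"niche breadth for {regime!r} must be positive")
        if self.depth_range[0] < 20_000:
            raise ValueError("depth_range minimum must be >= 20000 reads")


@dataclass
class GroundTruth:
    """Planted structure underlying one generated metacommunity."""

    guild_of: pd.Series  # OTU -> guild id
    niche_optimum: pd.Series  # OTU -> deg C
    pathogen_flags: pd.Series  # OTU -> bool
    site_regime: pd.Series  # sample -> regime
    site_dominant_guild: pd.Series  # sample -> guild id (-1 at cooperative sites)


def small_config(seed: int = 0) -> GeneratorConfig:
    """The small benchmark: 30 sites x 150 OTUs, one country."""
    return GeneratorConfig(
        countries=(
            CountryConfig(
                "ES",
                {"conventional": 12, "organic": 6, "biodynamic": 12},
                (14.0, 27.0),
                ("Spain_west", "Spain_east", "Spain_islands"),
            ),
        ),
        n_otus=150,
        seed=seed,
    )


def standard_config(seed: int = 0) -> GeneratorConfig:
    """The standard benchmark: 120 sites x 600 OTUs, two regimes, one country."""
    return GeneratorConfig(
        countries=(
            CountryConfig(
                "ES",
                {"conventional": 50, "organic": 20, "biodynamic": 50},
                (14.0, 27.0),
                ("Spain_west", "Spain_east", "Spain_islands"),
            ),
        ),
        n_otus=600,
        seed=seed,
    )


def generate_metacommunity(
    config: GeneratorConfig,
) -> tuple[CommunityMatrix, pd.DataFrame, GroundTruth]:
    """Draw one metacommunity: counts, metadata and ground truth.

    Deterministic given ``config.seed``.  Samples that come out with
    fewer than two occupied OTUs are redrawn (capped at 100 retries).
    """
    rng = np.random.default_rng(config.seed)
    otu_ids = [f"OTU_{i:04d}" for i in range(config.n_otus)]

    # --- OTU layer: guilds, optima, pathogen flags -----------------------
    tmin = min(c.temp_range[0] for c in config.countries)
    tmax = max(c.temp_range[1] for c in config.countries)
    centres = np.linspace(tmin + 1.5, tmax - 1.5, config.n_guilds)
    guild = rng.integers(0, config.n_guilds, size=config.n_otus)
    optimum = centres[guild] + rng.normal(0.0, config.guild_jitter, size=config.n_otus)
    n_path = int(round(config.pathogen_fraction * config.n_otus))
    pathogen = np.zeros(config.n_otus, dtype=bool)
    pathogen[rng.choice(config.n_otus, size=n_path, replace=False)] = True

    # --- site layer ------------------------------------------------------
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    regimes: list[str] = []
    dominants: list[int] = []
    temps: list[float] = []
    qualities: list[float] = []
    for country in config.countries:
        lo, hi = country.temp_range
        edges = np.linspace(lo, hi, len(country.region_names) + 1)
        k = 0
        for mgmt, n in country.management_counts.items():
            for _ in range(n):
                sid = f"{country.name}_{k:03d}"
                k += 1
                t = float(rng.uniform(lo, hi))
                region = country.region_names[
                    min(np.searchsorted(edges, t, side="right") - 1, len(country.region_names) - 1)
                ]
                if mgmt in REGIME_MAP:
                    regime = REGIME_MAP[mgmt]
                else:  # organic and unknown mix the regimes
                    regime = (
                        REGIME_COOPERATIVE
                        if rng.random() < config.organic_coop_weight
                        else REGIME_PARTITIONED
                    )
                dom = int(np.argmin(np.abs(centres - t))) if regime == REGIME_PARTITIONED else -1
                q = float(rng.lognormal(0.0, config.site_quality_sd))
                sample_ids.append(sid)
                regimes.append(regime)
                dominants.append(dom)
                temps.append(t)
                qualities.append(q)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "country": country.name,
                        "region": region,
                        "management": mgmt,
                        "latitude": float(rng.uniform(36, 43) if country.name == "ES" else rng.uniform(33, 47)),
                        "longitude": float(rng.uniform(-9, 3) if country.name == "ES" else rng.uniform(-123, -75)),
                        "altitude": float(rng.uniform(0, 900)),
                        "max_temperature": t,
                        "min_temperature": t - float(rng.uniform(5, 12)),
                        "humidity": float(np.clip(rng.beta(5, 2), 0, 1)),
                        "wind_speed": float(rng.gamma(2.0, 1.5)),
                        "precipitation_intensity": float(rng.gamma(1.5, 2.0)),
                        "date": "2019-06-15",
                    }
                )

    # --- occupancy and reads --------------------------------------------
    n_sites = len(sample_ids)
    counts = np.zeros((n_sites, config.n_otus), dtype=np.int64)
    mu_ab, sd_ab = config.abundance_lognormal
    eps = config.exclusion_strength
    for s in range(n_sites):
        sigma = config.niche_breadth[regimes[s]]
        p = config.base_occupancy * np.exp(-((temps[s] - optimum) ** 2) / (2 * sigma**2))
        if regimes[s] == REGIME_PARTITIONED:
            p = np.where(guild == dominants[s], p, p * (1 - eps))
            p = np.where(pathogen, p * (1 - config.pathogen_suppression), p)
        else:
            p = p * qualities[s]
        p = np.clip(p, 0.0, 0.98)
        depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        for _attempt in range(100):
            occupied = rng.random(config.n_otus) < p
            if occupied.sum() >= 2:
                break
        else:
            raise RuntimeError(f"sample {sample_ids[s]} stayed empty after 100 redraws")
        weights = np.zeros(config.n_otus)
        weights[occupied] = rng.lognormal(mu_ab, sd_ab, size=int(occupied.sum()))
        counts[s] = rng.multinomial(depth, weights / weights.sum())
        # multinomial sampling can miss rare occupants; that is real
        # sequencing behaviour and is kept as-is

    matrix = CommunityMatrix(sample_ids, otu_ids, counts)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    truth = GroundTruth(
        guild_of=pd.Series(guild, index=otu_ids, name="guild"),
        niche_optimum=pd.Series(optimum, index=otu_ids, name="niche_optimum"),
        pathogen_flags=pd.Series(pathogen, index=otu_ids, name="pathogen"),
        site_regime=pd.Series(regimes, index=sample_ids, name="regime"),
        site_dominant_guild=pd.Series(dominants, index=sample_ids, name="dominant_guild"),
    )
    return matrix, metadata, truth


def write_truth(truth: GroundTruth, otu_path, site_path) -> None:
    otu = pd.concat([truth.guild_of, truth.niche_optimum, truth.pathogen_flags], axis=1)
    otu.rename_axis("otu_id").to_csv(otu_path, sep="\t")
    site = pd.concat([truth.site_regime, truth.site_dominant_guild], axis=1)
    site.rename_axis("sample_id").to_csv(site_path, sep="\t")


def benchmark_suite(seed_list, outdir) -> Path:
    """Write the canonical small and standard fixtures for a list of seeds.

    Each fixture directory holds the count table (TSV and BIOM twins),
    the metadata TSV and the two ground-truth TSVs.
    """
    if len(seed_list) < 3:
        raise ValueError("need at least 3 seeds")
    outdir = Path(outdir)
    for seed in seed_list:
        for label, cfg in (("small", small_config(seed)), ("standard", standard_config(seed))):
            d = outdir / f"{label}_seed{seed}"
            d.mkdir(parents=True, exist_ok=True)
            matrix, metadata, truth = generate_metacommunity(cfg)
            write_otu_table(matrix, d / "otu_table.tsv", format="tsv")
            write_otu_table(matrix, d / "otu_table.biom", format="biom")
            metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
            write_truth(truth, d / "truth_otus.tsv", d / "truth_sites.tsv")
    return outdir
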