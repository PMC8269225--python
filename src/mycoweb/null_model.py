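"""Randomisation null models for local network properties.

Observed per-sample properties are compared to the properties of random
species sets of the same richness drawn uniformly without replacement
from the metaweb node universe.  The deviation of a sample is expressed
as a z-score, (observed - null mean) / null sd, and the conventional
|z| > 2 band separates communities structured beyond chance from those
indistinguishable from a random draw of equally many species.

This null keeps each sample's richness fixed and destroys species
identity; an occurrence-frequency-weighted draw is available for
communities where common species should be drawn more often.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .local_networks import local_profile
from .metaweb import Metaweb

DEFAULT_PROPERTIES = (
    "modularity_pos",
    "clustering_pos",
    "avg_path_length_pos",
    "cooccurrence_proportion",
    "coexclusion_proportion",
)


@dataclass
class NullModelScore:
    sample_id: str
    property: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when undefined (sd == 0 or missing values)
    n_randomizations: int
    n_used: int  # randomisations where the property was defined

    def as_row(self) -> dict:
        return dict(self.__dict__)


def _profile_values(metaweb: Metaweb, species: set[str], properties, steps: int) -> dict:
    prof = local_profile(metaweb, species, walktrap_steps=steps).as_row()
    return {p: prof.get(p, np.nan) for p in properties}


def null_zscores(
    metaweb: Metaweb,
    sample_species: set[str],
    properties=DEFAULT_PROPERTIES,
    n_rand: int = 1000,
    seed: int = 0,
    sample_id: str = "",
    weighted: np.ndarray | None = None,
    walktrap_steps: int = 4,
) -> list[NullModelScore]:
    """z-scores of one sample's properties against equal-richness random draws.

    Parameters
    ----------
    weighted
        Optional per-node sampling weights (aligned with ``metaweb.nodes``)
        for a frequency-weighted null; uniform when None.

    Randomisations where a property is undefined (e.g. modularity of an
    edge-less draw) are excluded from that property's null distribution;
    the count actually used is reported per property.
    """
    if n_rand < 2:
        raise ValueError("need at least 2 randomizations")
    nodes = np.asarray(metaweb.nodes, dtype=object)
    k = len(sample_species)
    if k > len(nodes):
        raise ValueError("sample richness exceeds metaweb size")
    properties = list(properties)
    observed = _profile_values(metaweb, sample_species, properties, walktrap_steps)
    rng = np.random.default_rng(seed)
    p = None
    if weighted is not None:
        w = np.asarray(weighted, dtype=float)
        p = w / w.sum()
    draws = np.empty((n_rand, len(properties)))
    for r in range(n_rand):
        pick = rng.choice(nodes, size=k, replace=False, p=p)
        vals = _profile_values(metaweb, set(pick), properties, walktrap_steps)
        draws[r] = [vals[q] for q in properties]
    scores = []
    for j, prop in enumerate(properties):
        col = draws[:, j]
        used = col[~np.isnan(col)]
        mean = float(used.mean()) if used.size else np.nan
        if used.size > 1:
            # identical draws must give an exact zero, not rounding dust
            sd = 0.0 if np.ptp(used) == 0 else float(used.std(ddof=1))
        else:
            sd = np.nan
        obs = float(observed[prop]) if observed[prop] is not None else np.nan
        if np.isnan(obs) or np.isnan(sd) or sd == 0.0:
            z = np.nan
        else:
            z = (obs - mean) / sd
        scores.append(
            NullModelScore(sample_id, prop, obs, mean, sd, z, n_rand, int(used.size))
        )
    return scores


def deviation_class(z: float, band: float = 2.0) -> str:
    """Classify a z-score against the +/- band: higher / lower / within.

    Comparisons are strict, so z equal to the band edge is ``within``;
    undefined (NaN) z propagates as ``undefined``.
    """
    if band <= 0:
        raise ValueError("band must be positive")
    if z is None or np.isnan(z):
        return "undefined"
    if z > band:
        return "higher"
    if z < -band:
        return "lower"
    return "within"


def scores_table(scores: list[NullModelScore], band: float = 2.0) -> pd.DataFrame:
    """Tidy TSV-ready table with the deviation class column added."""
    df = pd.DataFrame([s.as_row() for s in scores])
    df["class"] = [deviation_class(z, band) for z in df["z"]]
    return df
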