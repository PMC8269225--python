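"""Community-matrix I/O, normalisation and ordination primitives.

The unit of data throughout the pipeline is a :class:`CommunityMatrix`
(samples x OTUs, raw read counts).  This module reads and writes the two
table formats used in amplicon surveys (plain TSV with OTUs as rows, and
the JSON dialect of the BIOM 1.0 standard), rarefies to a fixed sequencing
depth, filters rare OTUs by prevalence, binarises to presence/absence, and
provides the diversity / ordination statistics used downstream: Shannon
H', Bray-Curtis dissimilarity, non-metric multidimensional scaling,
ANOSIM, Mantel tests and multivariate dispersion (betadisper).
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MANAGEMENT_LEVELS = ("conventional", "organic", "biodynamic", "unknown")

#: metadata columns required by the statistical layer
REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "country",
    "region",
    "management",
    "max_temperature",
    "humidity",
    "wind_speed",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every sample or OTU."""


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Integer sample x OTU count table.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers (rows).
    otu_ids
        Unique OTU identifiers (columns).
    counts
        Non-negative integer matrix of shape ``(len(sample_ids), len(otu_ids))``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValidationError(f"duplicate {name} id: {dup!r}")
        self.counts = counts.astype(np.int64)

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, keep: Sequence[int] | np.ndarray) -> "CommunityMatrix":
        keep = np.asarray(keep)
        return CommunityMatrix(
            [self.sample_ids[i] for i in keep], list(self.otu_ids), self.counts[keep]
        )

    def select_otus(self, keep: Sequence[int] | np.ndarray) -> "CommunityMatrix":
        keep = np.asarray(keep)
        return CommunityMatrix(
            list(self.sample_ids), [self.otu_ids[i] for i in keep], self.counts[:, keep]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class PresenceMatrix:
    """Binary occurrence matrix with the same axes as its source counts."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray  # uint8, 0/1

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def richness(self) -> np.ndarray:
        """Per-sample species richness S (row sums)."""
        return self.values.sum(axis=1)

    def species_of(self, sample_id: str) -> set[str]:
        i = self.sample_ids.index(sample_id)
        row = self.values[i]
        return {self.otu_ids[j] for j in np.flatnonzero(row)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_otu_table(path, format: str = "tsv") -> CommunityMatrix:
    """Read an OTU table from TSV (OTUs as rows) or BIOM 1.0 JSON.

    The TSV dialect is the one most amplicon pipelines emit: first column
    OTU id, remaining columns one per sample, header row of sample ids.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")


def _read_tsv(path) -> CommunityMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        n = len(sample_ids)
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 1:
                raise ValidationError(
                    f"line {lineno}: expected {n + 1} fields, got {len(parts)}"
                )
            otu_ids.append(parts[0])
            try:
                rows.append([int(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValidationError(f"line {lineno}: non-integer count ({exc})") from None
    counts = np.asarray(rows, dtype=np.int64).T if rows else np.zeros((n, 0), dtype=np.int64)
    return CommunityMatrix(sample_ids, otu_ids, counts)


def write_otu_table(m: CommunityMatrix, path, format: str = "tsv") -> None:
    """Write a community matrix as TSV (OTUs as rows) or BIOM 1.0 JSON."""
    if format == "tsv":
        df = pd.DataFrame(m.counts.T, index=m.otu_ids, columns=m.sample_ids)
        df.index.name = "#OTU_ID"
        df.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(m, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom(path) -> CommunityMatrix:
    # BIOM 1.0 is plain JSON; matrices are OTUs (rows) x samples (columns),
    # either dense or sparse [row, col, value] triplets.
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    else:
        mat[:] = np.asarray(doc["data"])
    return CommunityMatrix(sample_ids, otu_ids, mat.T)


def _write_biom(m: CommunityMatrix, path) -> None:
    mat = m.counts.T  # BIOM stores observations (OTUs) as rows
    nz = np.argwhere(mat > 0)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "mycoweb",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [m.n_otus, m.n_samples],
        "rows": [{"id": o, "metadata": None} for o in m.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in m.sample_ids],
        "data": [[int(r), int(c), int(mat[r, c])] for r, c in nz],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata from TSV/CSV, validating required columns."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id in metadata: {dup.iloc[0]!r}")
    bad = set(df["management"].dropna()) - set(MANAGEMENT_LEVELS)
    if bad:
        raise ValidationError(f"unknown management levels: {sorted(bad)}")
    if "humidity" in df and ((df["humidity"] < 0) | (df["humidity"] > 1)).any():
        raise ValidationError("humidity must lie in [0, 1]")
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def rarefy(m: CommunityMatrix, depth: int = 20_000, seed: int = 0) -> CommunityMatrix:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged), so
    that all OTUs have equal detectability across the retained samples.
    The draw is a multivariate hypergeometric per sample and is
    deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = m.row_sums()
    keep = np.flatnonzero(totals >= depth)
    if keep.size == 0:
        raise EmptyResultError(f"no sample reaches depth {depth} (max total {totals.max()})")
    dropped = m.n_samples - keep.size
    if dropped:
        logger.info("rarefy: dropped %d/%d samples below depth %d", dropped, m.n_samples, depth)
    rng = np.random.default_rng(seed)
    out = np.empty((keep.size, m.n_otus), dtype=np.int64)
    for i, r in enumerate(keep):
        row = m.counts[r]
        if totals[r] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CommunityMatrix([m.sample_ids[i] for i in keep], list(m.otu_ids), out)


def prevalence_filter(m: CommunityMatrix, min_prevalence: float = 0.02) -> CommunityMatrix:
    """Keep OTUs occurring in at least ``min_prevalence`` of samples (inclusive)."""
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must lie in (0, 1]")
    prevalence = (m.counts > 0).sum(axis=0) / m.n_samples
    keep = np.flatnonzero(prevalence >= min_prevalence)
    if keep.size == 0:
        raise EmptyResultError("prevalence filter removed every OTU")
    return m.select_otus(keep)


def to_presence(m: CommunityMatrix) -> PresenceMatrix:
    """Binarise counts to presence/absence (1 where count > 0)."""
    return PresenceMatrix(
        list(m.sample_ids), list(m.otu_ids), (m.counts > 0).astype(np.uint8)
    )


# ---------------------------------------------------------------------------
# diversity and dissimilarity
# ---------------------------------------------------------------------------


def shannon_diversity(m: CommunityMatrix) -> pd.Series:
    """Shannon H' per sample in nats: ``-sum p ln p`` over OTUs with p > 0."""
    totals = m.row_sums().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-sum sample(s); remove before computing diversity")
    p = m.counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=m.sample_ids, name="shannon_H")


def bray_curtis(m: CommunityMatrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|a-b| / sum(a+b)."""
    if m.n_samples < 2:
        raise ValueError("need at least two samples")
    x = m.counts.astype(float)
    empty = np.flatnonzero(x.sum(axis=1) == 0)
    if empty.size >= 2:
        raise ValueError("Bray-Curtis undefined for pairs of all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


def _as_square(d) -> np.ndarray:
    a = np.asarray(d, dtype=float) if not isinstance(d, pd.DataFrame) else d.to_numpy(float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square dissimilarity matrix")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    return a


def mantel_test(d1, d2, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    Pearson r of the upper triangles; the p-value permutes sample labels
    (rows and columns jointly) of the second matrix and counts
    permutations with ``r_perm >= r_obs`` (one-tailed, observed included).
    """
    a, b = _as_square(d1), _as_square(d2)
    if a.shape != b.shape:
        raise ValueError("matrices must share axes")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if va.std() == 0 or b[iu].std() == 0:
        raise ValueError("constant distances: Mantel r undefined")
    va = (va - va.mean()) / va.std()

    def corr(mat: np.ndarray) -> float:
        vb = mat[iu]
        vb = (vb - vb.mean()) / vb.std()
        return float(va @ vb) / len(va)

    r_obs = corr(b)
    if math.factorial(n) <= 10_000:  # exact test over the full permutation group
        hits = total = 0
        for p in itertools.permutations(range(n)):
            total += 1
            if corr(b[np.ix_(p, p)]) >= r_obs - 1e-12:
                hits += 1
        return r_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 1  # observed ordering counts as one permutation
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(b[np.ix_(p, p)]) >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / (n_perm + 1)


def anosim(d, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Analysis of similarities: R = (rb - rw) / (M / 2).

    ``rb``/``rw`` are mean ranks of between/within-group distances among
    the M unordered sample pairs; the denominator M/2 scales R into
    [-1, 1].  The p-value permutes group labels.
    """
    a = _as_square(d)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >=2 groups with >=2 members each")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(a[iu])
    m_pairs = len(ranks)
    denom = m_pairs / 2.0

    def stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = stat(groups)
    if math.factorial(n) <= 10_000:  # exact test over all label orderings
        hits = total = 0
        for p in itertools.permutations(range(n)):
            total += 1
            if stat(groups[list(p)]) >= r_obs - 1e-12:
                hits += 1
        return float(r_obs), hits / total
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        if stat(rng.permutation(groups)) >= r_obs - 1e-12:
            hits += 1
    return float(r_obs), hits / (n_perm + 1)


def nmds(d, k: int = 2, seed: int = 0, n_restarts: int = 20, max_iter: int = 300):
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Minimises Kruskal stress-1 by SMACOF with isotonic regression, taking
    the best of ``n_restarts`` random starts.  Returns ``(scores, stress)``
    with scores as a DataFrame when the input carries sample ids.
    """
    from sklearn.manifold import MDS

    a = _as_square(d)
    ids = list(d.index) if isinstance(d, pd.DataFrame) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_restarts,
            max_iter=max_iter,
            random_state=seed,
            normalized_stress=True,
        )
        scores = model.fit_transform(a)
    stress = float(model.stress_)
    if stress > 0.3:
        warnings.warn(f"nMDS stress {stress:.3f} > 0.3: embedding may be unreliable")
    if ids is not None:
        scores = pd.DataFrame(scores, index=ids, columns=[f"NMDS{i+1}" for i in range(k)])
    return scores, stress


def betadispersion(d, groups) -> tuple[pd.Series, pd.Series]:
    """Distance of each sample to its group centroid in PCoA space.

    The dissimilarity matrix is embedded by principal coordinates; axes
    with negative eigenvalues contribute negatively to squared distances
    (the standard real/imaginary split of betadisper).  Returns the
    per-sample distances and the per-group means.
    """
    a = _as_square(d)
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(a.shape[0]))
    groups = pd.Series(np.asarray(groups), index=ids)
    n = a.shape[0]
    # Gower-centred double-centering of -d^2/2
    a2 = -0.5 * a**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a2 @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    nz = np.abs(vals) > 1e-10 * max(1.0, np.abs(vals).max())
    vals, vecs = vals[nz], vecs[:, nz]
    coords = vecs * np.sqrt(np.abs(vals))
    signs = np.sign(vals)  # +1 real axes, -1 imaginary axes

    dist = np.zeros(n)
    for lab in groups.unique():
        idx = np.flatnonzero(groups.to_numpy() == lab)
        if idx.size == 1:
            warnings.warn(f"group {lab!r} has a single sample; dispersion set to 0")
            continue
        centroid = coords[idx].mean(axis=0)
        sq = ((coords[idx] - centroid) ** 2 * signs).sum(axis=1)
        dist[idx] = np.sqrt(np.clip(sq, 0.0, None))
    per_sample = pd.Series(dist, index=ids, name="dist_to_centroid")
    group_means = per_sample.groupby(groups).mean()
    return per_sample, group_means
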