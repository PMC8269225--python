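"""Downstream statistics relating network properties to environment.

Covers the statistical layer of the analysis: Spearman screens between
network properties, envfit-style vector fitting onto ordinations,
variation partitioning of nMDS scores into geography / weather / network
blocks with forward selection, linear mixed models of log properties on
management and weather with region as a random effect, two-way ANOVA
(management x country), the pathogen-presence binomial GLM, and a PCA of
log-scaled environmental variables.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: the local-network properties screened against each other and the
#: environment (Fig-3-style relationship graphs)
CORE_PROPERTIES = (
    "modularity_pos",
    "clustering_pos",
    "avg_path_length_pos",
    "modularity_neg",
    "avg_path_length_neg",
    "cooccurrence_proportion",
    "coexclusion_proportion",
)


# ---------------------------------------------------------------------------
# property-property correlations
# ---------------------------------------------------------------------------


def property_correlations(
    profiles: pd.DataFrame,
    strata: pd.Series | None = None,
    properties=CORE_PROPERTIES,
    r_threshold: float = 0.5,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Spearman correlations between all property pairs, per stratum and pooled.

    A pair is flagged as a relationship when |r| > ``r_threshold`` in at
    least one stratum with p < ``p_threshold`` (the joint rule used for
    the relationship graphs; no multiplicity correction is applied on top).
    """
    properties = [p for p in properties if p in profiles.columns]
    strata_groups: dict[str, pd.DataFrame] = {"pooled": profiles}
    if strata is not None:
        strata = strata.loc[profiles.index]
        for lab in strata.dropna().unique():
            strata_groups[str(lab)] = profiles[strata == lab]
    rows = []
    for (px, py), (lab, df) in itertools.product(
        itertools.combinations(properties, 2), strata_groups.items()
    ):
        x, y = df[px], df[py]
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            logger.warning("skipping %s~%s in %s: constant or too few values", px, py, lab)
            continue
        r, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"prop_x": px, "prop_y": py, "stratum": lab, "r": r, "p": p, "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    flag = (
        out[out["stratum"] != "pooled"]
        .groupby(["prop_x", "prop_y"])
        .apply(
            lambda g: bool(((g["r"].abs() > r_threshold) & (g["p"] < p_threshold)).any()),
            include_groups=False,
        )
        if (out["stratum"] != "pooled").any()
        else pd.Series(dtype=bool)
    )
    if flag.empty:  # single-stratum runs fall back to the pooled rule
        flag = (
            out.groupby(["prop_x", "prop_y"])
            .apply(
                lambda g: bool(((g["r"].abs() > r_threshold) & (g["p"] < p_threshold)).any()),
                include_groups=False,
            )
        )
    out["relationship"] = [
        bool(flag.get((a, b), False)) for a, b in zip(out["prop_x"], out["prop_y"])
    ]
    return out


def diversity_property_correlation(
    profiles: pd.DataFrame, shannon: pd.Series, properties=CORE_PROPERTIES
) -> pd.DataFrame:
    """Spearman correlation of alpha diversity H' against each network property."""
    shannon = shannon.loc[profiles.index]
    rows = []
    for prop in properties:
        if prop not in profiles.columns:
            continue
        y = profiles[prop]
        ok = y.notna() & shannon.notna()
        r, p = stats.spearmanr(shannon[ok], y[ok])
        rows.append({"property": prop, "r": r, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ordination fits and variation partitioning
# ---------------------------------------------------------------------------


def envfit_vectors(
    scores: pd.DataFrame, variables: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Fit numeric variables onto ordination space (vegan's envfit).

    For each variable the squared multiple correlation r2 of the
    least-squares fit onto the ordination axes is computed, with a
    permutation p-value from shuffling the variable across samples.  The
    fitted direction is the unit vector of the regression coefficients.
    """
    x = scores.loc[variables.index].to_numpy(float)
    xc = x - x.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        v = variables[name].to_numpy(float)
        ok = ~np.isnan(v)
        if v[ok].std() == 0:
            logger.warning("envfit: skipping constant variable %r", name)
            continue
        xi = xc[ok] - xc[ok].mean(axis=0)
        vi = v[ok] - v[ok].mean()

        def r2_of(vec: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(xi, vec, rcond=None)
            fitted = xi @ beta
            return float((fitted**2).sum() / (vec**2).sum()), beta

        r2, beta = r2_of(vi)
        hits = 1
        for _ in range(n_perm):
            perm = rng.permutation(vi)
            if r2_of(perm - perm.mean())[0] >= r2 - 1e-12:
                hits += 1
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        rows.append(
            {
                "variable": name,
                "r2": r2,
                "p": hits / (n_perm + 1),
                **{f"axis{i+1}": d for i, d in enumerate(direction)},
            }
        )
    return pd.DataFrame(rows)


def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Ezekiel-adjusted R2 of a multivariate least-squares fit (with intercept)."""
    n = y.shape[0]
    x1 = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
    resid = y - x1 @ beta
    yc = y - y.mean(axis=0)
    sst = (yc**2).sum()
    if sst == 0:
        raise ValueError("constant response")
    r2 = 1 - (resid**2).sum() / sst
    p = np.linalg.matrix_rank(x1) - 1
    if n - p - 1 <= 0:
        return r2
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VariancePartition:
    """Adjusted-R2 decomposition of ordination scores over three blocks.

    ``fractions`` holds the 7 unique/shared components keyed by block-name
    subsets (e.g. ``'weather'``, ``'weather&geography'``) plus
    ``'residual'``.  Shared fractions can be negative; they are reported
    untruncated.
    """

    block_names: tuple[str, str, str]
    fractions: dict[str, float] = field(default_factory=dict)

    def total_explained(self) -> float:
        return 1.0 - self.fractions["residual"]


def variation_partitioning(
    scores: pd.DataFrame, blocks: dict[str, pd.DataFrame]
) -> VariancePartition:
    """Partition ordination-score variance among three explanatory blocks.

    Adjusted R2 is computed for every union of blocks and the 7
    unique/pairwise/three-way fractions follow by inclusion-exclusion, as
    in vegan's varpart.  Order of blocks does not matter.
    """
    if len(blocks) != 3:
        raise ValueError("variation partitioning needs exactly three blocks")
    names = tuple(sorted(blocks))
    y = scores.to_numpy(float)
    y = y - y.mean(axis=0)
    mats = {}
    for name in names:
        b = blocks[name].loc[scores.index]
        x = b.to_numpy(float)
        keep = []
        for jcol in range(x.shape[1]):
            trial = x[:, keep + [jcol]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(jcol)
            else:
                logger.warning(
                    "variation_partitioning: dropping collinear column %r of block %r",
                    b.columns[jcol], name,
                )
        mats[name] = x[:, keep]
    r2 = {}
    for rset in range(1, 4):
        for combo in itertools.combinations(names, rset):
            x = np.column_stack([mats[n] for n in combo])
            r2[frozenset(combo)] = _adjusted_r2(y, x)
    a, b, c = names
    fa, fb, fc = r2[frozenset([a])], r2[frozenset([b])], r2[frozenset([c])]
    fab, fac = r2[frozenset([a, b])], r2[frozenset([a, c])]
    fbc = r2[frozenset([b, c])]
    fabc = r2[frozenset([a, b, c])]
    unique_a = fabc - fbc
    unique_b = fabc - fac
    unique_c = fabc - fab
    # inclusion-exclusion on adjusted R2 (vegan varpart convention)
    ab = fa + fb - fab  # total shared between a and b (incl. three-way)
    ac = fa + fc - fac
    bc = fb + fc - fbc
    three_way = fa + fb + fc - fab - fac - fbc + fabc
    pair_ab = ab - three_way
    pair_ac = ac - three_way
    pair_bc = bc - three_way
    fractions = {
        a: unique_a,
        b: unique_b,
        c: unique_c,
        f"{a}&{b}": pair_ab,
        f"{a}&{c}": pair_ac,
        f"{b}&{c}": pair_bc,
        f"{a}&{b}&{c}": three_way,
        "residual": 1.0 - fabc,
    }
    return VariancePartition(names, fractions)


def forward_select(
    scores: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
    vif_threshold: float = 10.0,
) -> list[str]:
    """Forward selection of explanatory variables for ordination scores.

    Collinear candidates (variance inflation factor above the threshold,
    checked sequentially) are removed first.  Variables are then added by
    largest adjusted-R2 gain, each addition requiring a permutation
    p-value below ``alpha``, with the double stopping rule that the
    selected model's adjusted R2 may not exceed the full-model adjusted R2.
    """
    y = scores.loc[candidates.index].to_numpy(float)
    y = y - y.mean(axis=0)
    cols = list(candidates.columns)
    # collinearity screen
    keep: list[str] = []
    for c in cols:
        x = candidates[keep + [c]].to_numpy(float)
        if len(keep) and np.linalg.matrix_rank(x) <= len(keep):
            logger.warning("forward_select: %r dropped (exactly collinear)", c)
            continue
        if len(keep):
            xc = candidates[keep].to_numpy(float)
            xc1 = np.column_stack([np.ones(len(xc)), xc])
            v = candidates[c].to_numpy(float)
            beta, *_ = np.linalg.lstsq(xc1, v, rcond=None)
            resid = v - xc1 @ beta
            ssr = (resid**2).sum()
            sst = ((v - v.mean()) ** 2).sum()
            r2 = 1 - ssr / sst if sst > 0 else 1.0
            if r2 > 1 - 1 / vif_threshold:
                logger.warning("forward_select: %r dropped (VIF > %g)", c, vif_threshold)
                continue
        keep.append(c)
    cols = keep
    if not cols:
        warnings.warn("forward_select: no candidates survive the collinearity screen")
        return []
    full_r2 = _adjusted_r2(y, candidates[cols].to_numpy(float))
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    current_r2 = 0.0
    while True:
        remaining = [c for c in cols if c not in selected]
        if not remaining:
            break
        gains = []
        for c in remaining:
            x = candidates[selected + [c]].to_numpy(float)
            gains.append(_adjusted_r2(y, x))
        best = int(np.argmax(gains))
        cand, cand_r2 = remaining[best], gains[best]
        # permutation test of the gain, permuting response rows
        hits = 1
        x = candidates[selected + [cand]].to_numpy(float)
        for _ in range(n_perm):
            perm = rng.permutation(len(y))
            if _adjusted_r2(y[perm], x) >= cand_r2 - 1e-12:
                hits += 1
        if hits / (n_perm + 1) >= alpha:
            break
        selected.append(cand)
        if cand_r2 >= full_r2 - 1e-12:
            break  # double stopping rule: full-model adjusted R2 reached
    if not selected:
        warnings.warn("forward_select: no variable met the entry criterion")
    return selected


# ---------------------------------------------------------------------------
# mixed models, ANOVA, pathogen model
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    response: str
    fixed_effects: pd.DataFrame  # estimate, se, p per term
    random_effect_var: float
    residual_var: float
    marginal_r2: float
    converged: bool
    note: str = ""


def fit_property_lmm(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = ("humidity", "max_temperature", "wind_speed"),
    random: str = "region",
    center_by: str | None = "country",
    scale: bool = True,
) -> MixedModelFit:
    """Linear mixed model of ln(property) on management and weather.

    Management enters as cell means (no global intercept: one estimate per
    level); continuous covariates are centred (and optionally scaled) per
    country before fitting; the region grouping is a random intercept fit
    by REML.  The marginal R2 is var(fixed predictor) over the sum of
    fixed, random and residual variances (Nakagawa & Schielzeth).
    """
    import statsmodels.formula.api as smf

    df = profiles.join(metadata.drop(columns=profiles.columns, errors="ignore"), how="inner")
    needed = [response, "management", random, *fixed]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if (df[response] <= 0).any():
        n_bad = int((df[response] <= 0).sum())
        logger.warning("dropping %d samples with non-positive %s for log transform", n_bad, response)
        df = df[df[response] > 0]
    if df[random].nunique() < 2:
        raise ValueError("need >=2 regions for the random effect")
    df = df.copy()
    df["_y"] = np.log(df[response])
    for c in fixed:
        grouper = df[center_by] if center_by and center_by in df else np.zeros(len(df))
        centred = df[c] - df.groupby(grouper)[c].transform("mean")
        if scale:
            sd = df.groupby(grouper)[c].transform("std").replace(0, 1.0)
            centred = centred / sd
        df[f"_{c}"] = centred
    terms = " + ".join([f"_{c}" for c in fixed])
    formula = f"_y ~ 0 + C(management) + {terms}" if terms else "_y ~ 0 + C(management)"
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[random])
        try:
            fit = model.fit(reml=True)
            re_var = float(fit.cov_re.iloc[0, 0])
            converged = bool(fit.converged)
        except Exception as exc:  # singular fits fall back to OLS
            fit = None
            re_var = 0.0
            converged = False
            note = f"mixed fit failed ({exc}); refit without random effect"
    if fit is None or not converged or not np.isfinite(re_var):
        import statsmodels.api as sm

        ols = smf.ols(formula, df).fit()
        params, bse, pvals = ols.params, ols.bse, ols.pvalues
        resid_var = float(ols.mse_resid)
        re_var = 0.0
        if not note:
            note = "random-effect variance singular; refit without random effect"
        fitted_fixed = ols.fittedvalues
    else:
        params, bse, pvals = fit.fe_params, fit.bse_fe, fit.pvalues[fit.fe_params.index]
        resid_var = float(fit.scale)
        design = pd.DataFrame(model.exog, columns=model.exog_names, index=df.index)
        fitted_fixed = design @ params
    var_fixed = float(np.var(fitted_fixed, ddof=0))
    marginal_r2 = var_fixed / (var_fixed + re_var + resid_var)
    fe = pd.DataFrame({"estimate": params, "se": bse, "p": pvals})
    return MixedModelFit(response, fe, re_var, resid_var, marginal_r2, fit is not None, note)


def two_way_anova(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("management", "country"),
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type-II sums of squares.

    Type II is appropriate for the unbalanced management x country design;
    if a factor-level cell is empty, the model falls back to additive
    (logged).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    f1, f2 = factors
    df = profiles.join(metadata.drop(columns=profiles.columns, errors="ignore"), how="inner")
    df = df.dropna(subset=[response, f1, f2]).copy()
    df["_y"] = df[response].astype(float)
    cells = df.groupby([f1, f2], observed=True).size().unstack()
    interaction = True
    if cells.isna().any().any() or (cells == 0).any().any():
        logger.warning("empty %s x %s cell: dropping interaction term", f1, f2)
        interaction = False
    formula = f"_y ~ C({f1}) * C({f2})" if interaction else f"_y ~ C({f1}) + C({f2})"
    fit = smf.ols(formula, df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table["significant"] = table["PR(>F)"] < 0.01
    return table


@dataclass
class PathogenAnalysis:
    richness: pd.Series
    spearman_r: float
    spearman_p: float
    coefficients: pd.DataFrame
    probability_curve: pd.DataFrame
    penalized: bool


def pathogen_analysis(
    profiles: pd.DataFrame,
    presence,
    pathogen_otus: list[str],
    predictors: tuple[str, ...] = (
        "clustering_pos",
        "modularity_pos",
        "avg_path_length_neg",
        "coexclusion_proportion",
    ),
    curve_variable: str = "coexclusion_proportion",
    n_curve: int = 50,
) -> PathogenAnalysis:
    """Plant-pathogen load versus local network structure.

    Pathogen richness is the count of curated pathogen OTUs present per
    sample; presence (richness >= 1) is modelled by a binomial GLM on the
    named network properties, and a predicted-probability curve along
    ``curve_variable`` is evaluated with the other predictors held at
    their medians.  Also reports the Spearman correlation of richness
    with the co-exclusion proportion.
    """
    import statsmodels.api as sm

    universe = set(presence.otu_ids)
    unknown = [o for o in pathogen_otus if o not in universe]
    if unknown:
        logger.warning("%d pathogen OTUs not in the table (ignored)", len(unknown))
    cols = [presence.otu_ids.index(o) for o in pathogen_otus if o in universe]
    richness = pd.Series(
        presence.values[:, cols].sum(axis=1) if cols else np.zeros(presence.n_samples, int),
        index=presence.sample_ids,
        name="pathogen_richness",
    )
    if richness.sum() == 0:
        raise ValueError("no pathogen OTU is present in any sample; nothing to model")
    df = profiles.loc[profiles.index.intersection(richness.index)].copy()
    rich = richness.loc[df.index]
    df = df.dropna(subset=list(predictors))
    if df.empty:
        raise ValueError(
            "no sample has all predictor properties defined; "
            f"check for missing values in {list(predictors)}"
        )
    rich = rich.loc[df.index]
    y = (rich >= 1).astype(int).to_numpy()
    x = sm.add_constant(df[list(predictors)].astype(float))
    r, p = stats.spearmanr(rich, df["coexclusion_proportion"])
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
            mu = fit.fittedvalues
            separated = ((mu > 1 - 1e-8) | (mu < 1e-8)).all() and (np.round(mu) == y).all()
            if not np.isfinite(fit.bse).all() or separated:
                raise ValueError("complete separation")
            coefs = pd.DataFrame({"estimate": fit.params, "se": fit.bse, "p": fit.pvalues})
        except Exception:
            # complete separation: ridge-penalised fallback
            penalized = True
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit_regularized(alpha=1e-3, L1_wt=0.0)
            coefs = pd.DataFrame({"estimate": fit.params, "se": np.nan, "p": np.nan})
    grid = np.linspace(df[curve_variable].min(), df[curve_variable].max(), n_curve)
    newx = pd.DataFrame(
        {c: np.repeat(df[c].median(), n_curve) for c in predictors}, columns=list(predictors)
    )
    newx[curve_variable] = grid
    newx = sm.add_constant(newx, has_constant="add")[x.columns]
    eta = newx.to_numpy(float) @ np.asarray(fit.params, float)
    curve = pd.DataFrame({curve_variable: grid, "probability": 1 / (1 + np.exp(-eta))})
    return PathogenAnalysis(richness, float(r), float(p), coefs, curve, penalized)


def env_pca(metadata: pd.DataFrame, variables: list[str] | None = None):
    """PCA of log-transformed, z-scaled environmental variables.

    Non-positive values are shifted before the log; constant variables are
    dropped with a warning.  Returns (scores, loadings, explained
    variance ratio).
    """
    num = metadata[variables] if variables else metadata.select_dtypes("number")
    num = num.dropna()
    keep = [c for c in num.columns if num[c].nunique() > 1]
    dropped = set(num.columns) - set(keep)
    if dropped:
        warnings.warn(f"env_pca: dropping constant variables {sorted(dropped)}")
    num = num[keep]
    x = num.to_numpy(float)
    shift = np.minimum(x.min(axis=0), 0)
    x = np.log(x - shift + 1e-9) if (x <= 0).any() else np.log(x)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.atleast_2d(np.corrcoef(x, rowvar=False))
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    scores = pd.DataFrame(
        x @ vecs, index=num.index, columns=[f"PC{i+1}" for i in range(len(vals))]
    )
    loadings = pd.DataFrame(
        vecs, index=keep, columns=[f"PC{i+1}" for i in range(len(vals))]
    )
    return scores, loadings, vals / vals.sum()
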