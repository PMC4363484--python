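"""Statistical stage: standardized linear models, all-subsets AIC averaging,
Akaike-weight variable importance, sapwood-area imputation, and path analysis.

The growth analysis regresses log biomass growth on six standardized traits
(log sapwood area, sqrt total leaf area, SLA, leaf and sapwood N, height)
with species as a fixed factor, evaluates every admissible predictor subset,
and averages the models within 2 AIC units of the best one.  Coefficients are
conditional (subset) averages - each coefficient is averaged only over models
containing it - with Burnham-Anderson adjusted standard errors; full
(zero-substitution) averages are computed alongside.  Variable importance is
the sum of renormalized Akaike weights of the selected models containing the
variable, so a variable in every selected model has importance exactly 1.

AIC is 2k - 2 log L with the Gaussian ML log-likelihood and the residual
variance counted in k (the convention of R's ``AIC`` on ``lm`` fits).  AICc
is available through ``use_aicc`` - with 43 trees and up to ~12 parameters it
materially changes selection, so the choice is explicit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import DomainError, InferenceError

__all__ = [
    "DesignSpec",
    "GROWTH_DESIGN",
    "SA_DESIGN",
    "TermGroup",
    "DesignMatrix",
    "transform_and_scale",
    "ModelFit",
    "fit_lm",
    "cooks_distance",
    "screen_interactions",
    "enumerate_subsets",
    "akaike_weights",
    "AveragedModel",
    "average_models",
    "impute_missing_sa",
    "fit_sa_model",
    "fit_growth_model",
    "PathResult",
    "path_analysis",
    "summarize_traits",
]

logger = logging.getLogger(__name__)

Transform = Literal["log", "sqrt", "none"]

REFERENCE_SPECIES = "Sweetia fruticosa"


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of a model design.

    ``predictors`` is a list of (trait column, transform) pairs; the species
    factor is reference-coded (reference ``reference_species``) and either
    always present or selectable during subset enumeration.
    """

    response: tuple[str, Transform]
    predictors: tuple[tuple[str, Transform], ...]
    species_term: Literal["always", "selectable"] = "selectable"
    interactions: tuple[str, ...] = ()
    scale: bool = True
    reference_species: str = REFERENCE_SPECIES


GROWTH_DESIGN = DesignSpec(
    response=("agr", "log"),
    predictors=(("sa", "log"), ("tla", "sqrt"), ("sla", "none"),
                ("n_sapw", "none"), ("n_leaf", "none"), ("height", "none")),
    species_term="selectable",
)

# Sapwood growth and lifespan stay untransformed; SA and stem BA are modelled
# on the log scale.
SA_DESIGN = DesignSpec(
    response=("sa", "log"),
    predictors=(("sapwood_growth", "none"), ("sapwood_lifespan", "none"),
                ("ba", "log")),
    species_term="always",
)


def transformed_name(trait: str, transform: Transform) -> str:
    if transform == "log":
        return f"log({trait})"
    if transform == "sqrt":
        return f"sqrt({trait})"
    return trait


def apply_transform(values: pd.Series, transform: Transform, trait: str,
                    ids: pd.Series | None = None) -> pd.Series:
    if transform == "none":
        return values.astype(float)
    bad = values <= 0 if transform == "log" else values < 0
    bad &= values.notna()
    if bad.any():
        where = (ids[bad].tolist() if ids is not None
                 else values.index[bad].tolist())
        raise DomainError(
            f"{transform} transform of {trait!r} undefined for tree(s) {where}")
    return np.log(values) if transform == "log" else np.sqrt(values)


@dataclass(frozen=True)
class TermGroup:
    """A named block of design columns that enters/leaves subsets as a unit.

    ``requires`` lists group names that must accompany this group
    (interaction marginality: no interaction without its main effects).
    """

    name: str
    columns: tuple[str, ...]
    requires: tuple[str, ...] = ()


@dataclass
class DesignMatrix:
    """Transformed, scaled design with the metadata to undo the scaling."""

    X: pd.DataFrame              # numeric + species indicator columns, no const
    y: pd.Series
    groups: tuple[TermGroup, ...]
    scaling: dict[str, tuple[float, float]]  # column/response -> (mean, sd)
    species: pd.Series
    response_name: str


def _species_indicators(species: pd.Series, reference: str) -> pd.DataFrame:
    levels = sorted(species.unique())
    ref = next((s for s in levels if s.lower() == reference.lower()), None)
    if ref is None:
        # fall back: first level alphabetically becomes the reference
        ref = levels[0]
        logger.warning("reference species %r absent; using %r", reference, ref)
    cols = {}
    for level in levels:
        if level == ref:
            continue
        cols[f"species[{level.split()[0]}]"] = (species == level).astype(float)
    return pd.DataFrame(cols, index=species.index)


def transform_and_scale(
    traits: pd.DataFrame, spec: DesignSpec,
    interactions: Sequence[str] = (),
) -> DesignMatrix:
    """Build the standardized design matrix for a model specification.

    Numeric columns are transformed, then centered and SD-scaled (sample SD,
    n-1).  Species enters as reference-coded indicators (indicators are not
    scaled).  Retained species x trait interactions multiply the indicator
    block by the scaled trait column.
    """
    ids = traits["tree_id"] if "tree_id" in traits else None
    resp_trait, resp_tf = spec.response
    rows = traits[resp_trait].notna()
    for trait, _ in spec.predictors:
        rows &= traits[trait].notna()
    sub = traits.loc[rows]
    ids = ids.loc[rows] if ids is not None else None

    scaling: dict[str, tuple[float, float]] = {}

    def scaled(trait: str, tf: Transform) -> tuple[str, pd.Series]:
        name = transformed_name(trait, tf)
        vals = apply_transform(sub[trait], tf, trait, ids)
        if spec.scale:
            mu, sd = float(vals.mean()), float(vals.std(ddof=1))
            if sd == 0:
                raise InferenceError(f"column {name} is constant; cannot scale")
            scaling[name] = (mu, sd)
            vals = (vals - mu) / sd
        return name, vals

    resp_name, y = scaled(resp_trait, resp_tf)
    X = {}
    groups: list[TermGroup] = []
    for trait, tf in spec.predictors:
        name, vals = scaled(trait, tf)
        X[name] = vals
        groups.append(TermGroup(name, (name,)))

    species = sub["species"].astype(str)
    sp_ind = _species_indicators(species, spec.reference_species)
    for c in sp_ind:
        X[c] = sp_ind[c]
    if not sp_ind.empty:
        groups.append(TermGroup("species", tuple(sp_ind.columns)))

    Xdf = pd.DataFrame(X, index=sub.index)
    for trait_name in interactions:
        if sp_ind.empty:
            break
        cols = []
        for c in sp_ind.columns:
            col = f"{c}:{trait_name}"
            Xdf[col] = Xdf[c] * Xdf[trait_name]
            cols.append(col)
        groups.append(TermGroup(f"species:{trait_name}", tuple(cols),
                                requires=("species", trait_name)))

    return DesignMatrix(X=Xdf, y=y.rename(resp_name), groups=tuple(groups),
                        scaling=scaling, species=species,
                        response_name=resp_name)


# ---------------------------------------------------------------------------
# OLS fits
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """One OLS fit with Gaussian-ML log-likelihood bookkeeping."""

    terms: tuple[str, ...]          # term-group names ("" columns imply const)
    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    loglik: float
    k: int                          # coefficients + 1 (residual variance)
    aic: float
    n: int
    rss: float
    _sm_results: object = field(default=None, repr=False, compare=False)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.params.index if c != "const")


def fit_lm(
    X: pd.DataFrame, y: pd.Series,
    terms: tuple[str, ...] = (),
    use_aicc: bool = False,
) -> ModelFit:
    """Ordinary least squares with an intercept.

    aic = 2k - 2 log L with k = (number of coefficients) + 1 for the residual
    variance, log L evaluated at the ML variance estimate.  P-values are
    two-sided t.  Rank-deficient designs raise, listing the aliased columns.
    """
    n = len(y)
    Xc = sm.add_constant(X, has_constant="add")
    if n <= Xc.shape[1]:
        raise InferenceError(
            f"need n > number of parameters; n={n}, p={Xc.shape[1]}")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        _, r = np.linalg.qr(Xc.to_numpy())
        aliased = [Xc.columns[i] for i in range(Xc.shape[1])
                   if abs(r[min(i, r.shape[0] - 1), i]) < 1e-10]
        raise InferenceError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y.to_numpy(), Xc).fit()
    k = Xc.shape[1] + 1
    aic = 2 * k - 2 * res.llf
    if use_aicc:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return ModelFit(
        terms=tuple(terms),
        params=pd.Series(res.params, index=Xc.columns),
        se=pd.Series(res.bse, index=Xc.columns),
        tvalues=pd.Series(res.tvalues, index=Xc.columns),
        pvalues=pd.Series(res.pvalues, index=Xc.columns),
        loglik=float(res.llf),
        k=k,
        aic=float(aic),
        n=n,
        rss=float(res.ssr),
        _sm_results=res,
    )


def cooks_distance(fit: ModelFit) -> pd.DataFrame:
    """Cook's distance per observation, flagged when D > 4/n (report only)."""
    if fit._sm_results is None:
        raise InferenceError("fit lacks the underlying regression results")
    if fit.rss <= 1e-12:   # exact fit: no observation is influential
        d = np.zeros(fit.n)
    else:
        d = OLSInfluence(fit._sm_results).cooks_distance[0]
    thresh = 4.0 / fit.n
    return pd.DataFrame({"cooks_d": d, "flagged": d > thresh})


def screen_interactions(
    traits: pd.DataFrame, spec: DesignSpec, alpha: float = 0.05,
) -> list[str]:
    """Partial F-tests of each species x trait interaction vs the additive model.

    Returns the transformed names of traits whose interaction with species is
    significant at ``alpha``.  Interactions without enough residual degrees of
    freedom are skipped with a warning.
    """
    dm = transform_and_scale(traits, spec)
    if traits["species"].nunique() < 2:
        return []
    base_cols = [c for g in dm.groups for c in g.columns]
    base = fit_lm(dm.X[base_cols], dm.y)
    retained = []
    for trait_name in [transformed_name(t, tf) for t, tf in spec.predictors]:
        dmi = transform_and_scale(traits, spec, interactions=[trait_name])
        int_cols = [c for g in dmi.groups for c in g.columns]
        df_extra = len(int_cols) - len(base_cols)
        df_res = len(dmi.y) - (len(int_cols) + 1)
        if df_res <= 0:
            logger.warning("skipping species x %s: insufficient df", trait_name)
            continue
        full = fit_lm(dmi.X[int_cols], dmi.y)
        F = ((base.rss - full.rss) / df_extra) / (full.rss / df_res)
        p = float(scipy.stats.f.sf(F, df_extra, df_res))
        if p < alpha:
            retained.append(trait_name)
    return retained


# ---------------------------------------------------------------------------
# All-subsets enumeration and averaging
# ---------------------------------------------------------------------------

MAX_TERMS = 15


def enumerate_subsets(
    dm: DesignMatrix, use_aicc: bool = False,
) -> list[ModelFit]:
    """Fit every admissible subset of term groups, sorted ascending by AIC.

    The species block enters or leaves as one term; an interaction group is
    only admissible together with its required main effects (marginality).
    The intercept-only model is always included.  Ties sort by the original
    enumeration order (stable sort).
    """
    if len(dm.groups) > MAX_TERMS:
        raise InferenceError(
            f"{len(dm.groups)} candidate terms exceed the combinatorial guard "
            f"of {MAX_TERMS}")
    fits = []
    names = [g.name for g in dm.groups]
    by_name = {g.name: g for g in dm.groups}
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            chosen = set(combo)
            if any(req not in chosen
                   for name in combo for req in by_name[name].requires):
                continue
            cols = [c for name in combo for c in by_name[name].columns]
            fits.append(fit_lm(dm.X[cols], dm.y, terms=combo, use_aicc=use_aicc))
    fits.sort(key=lambda f: f.aic)
    return fits


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2), delta vs the minimum."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise InferenceError("no models to weight")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class AveragedModel:
    """Delta-AIC < cut model set with conditional averages and importances."""

    component_models: list[ModelFit]
    weights: np.ndarray
    coefficients: pd.Series        # conditional (subset) averages
    se_adj: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    coefficients_full: pd.Series   # zero-substitution averages
    importance: pd.Series          # per term group
    delta_cut: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.coefficients,
            "se_adj": self.se_adj,
            "z": self.zvalues,
            "p": self.pvalues,
            "beta_full": self.coefficients_full,
        })


def average_models(
    candidates: Sequence[ModelFit], delta_cut: float = 2.0,
) -> AveragedModel:
    """Average the models within ``delta_cut`` AIC units of the best one.

    Weights are Akaike weights renormalized over the selected set.  Each
    coefficient is averaged conditionally over the models containing it, with
    the Burnham-Anderson adjusted SE
    ``sum_i w_i * sqrt(SE_i^2 + (b_i - b_bar)^2)`` (weights renormalized over
    the containing models).  Importance of a term is the summed weight of the
    selected models containing it; averaged-coefficient p-values use a normal
    approximation.
    """
    if not candidates:
        raise InferenceError("no candidate models")
    best = min(f.aic for f in candidates)
    sel = [f for f in candidates if f.aic - best < delta_cut]
    sel.sort(key=lambda f: f.aic)
    w = akaike_weights([f.aic for f in sel])

    cols: list[str] = []
    for f in sel:
        for c in f.params.index:
            if c != "const" and c not in cols:
                cols.append(c)
    cols = ["const"] + cols

    beta, se_adj, beta_full = {}, {}, {}
    for c in cols:
        mask = np.array([c in f.params.index for f in sel])
        wc = w[mask] / w[mask].sum()
        b = np.array([f.params[c] for f, m in zip(sel, mask) if m])
        s = np.array([f.se[c] for f, m in zip(sel, mask) if m])
        bbar = float(np.sum(wc * b))
        beta[c] = bbar
        se_adj[c] = float(np.sum(wc * np.sqrt(s ** 2 + (b - bbar) ** 2)))
        beta_full[c] = float(np.sum(w[mask] * b))  # absent models contribute 0

    beta = pd.Series(beta)
    se_adj = pd.Series(se_adj)
    z = beta / se_adj
    p = pd.Series(2 * scipy.stats.norm.sf(np.abs(z)), index=beta.index)

    group_names = sorted({t for f in sel for t in f.terms})
    importance = pd.Series({
        g: float(np.sum([wi for f, wi in zip(sel, w) if g in f.terms]))
        for g in group_names
    })

    return AveragedModel(
        component_models=sel, weights=w, coefficients=beta, se_adj=se_adj,
        zvalues=z, pvalues=p, coefficients_full=pd.Series(beta_full),
        importance=importance, delta_cut=delta_cut,
    )


# ---------------------------------------------------------------------------
# SA imputation and the two headline models
# ---------------------------------------------------------------------------

def impute_missing_sa(traits: pd.DataFrame) -> pd.DataFrame:
    """Predict missing sapwood area from all traits and stem BA.

    Fits log(SA) ~ height + sqrt(TLA) + SLA + N_leaf + N_sapw + sapwood
    growth + log(BA) + species on the trees with observed SA.  Sapwood
    growth is included because annual ring growth is measurable without a
    visible sapwood boundary, unlike sapwood lifespan.  The species factor
    (over the observed species) keeps the trait slopes free of
    species-intercept confounding; the species lacking SA has no estimable
    level, so its prediction uses the training-share-weighted average
    intercept.  Filled rows are flagged ``sa_imputed``; observed rows are
    untouched.
    """
    observed = traits["sa"].notna()
    if not observed.any():
        raise InferenceError("no observed sapwood area to fit the imputation")
    if traits.loc[observed, "species"].nunique() < 2:
        raise InferenceError(
            "imputation needs observed sapwood area from >= 2 species")
    if observed.all():
        return traits.copy()

    pred_cols = {
        "height": ("height", "none"), "sqrt(tla)": ("tla", "sqrt"),
        "sla": ("sla", "none"), "n_leaf": ("n_leaf", "none"),
        "n_sapw": ("n_sapw", "none"),
        "sapwood_growth": ("sapwood_growth", "none"),
        "log(ba)": ("ba", "log"),
    }
    X = pd.DataFrame({
        name: apply_transform(traits[trait], tf, trait,
                              traits.get("tree_id"))
        for name, (trait, tf) in pred_cols.items()
    })
    # species factor over the observed species; the masked species gets the
    # training-share-weighted average intercept at prediction time
    obs_species = sorted(traits.loc[observed, "species"].unique())
    shares = (traits.loc[observed, "species"].value_counts(normalize=True)
              .reindex(obs_species).fillna(0.0))
    for level in obs_species[1:]:
        X[f"species[{level.split()[0]}]"] = (
            traits["species"] == level).astype(float)
    y = apply_transform(traits.loc[observed, "sa"], "log", "sa")
    fit = fit_lm(X.loc[observed], y)
    missing = ~observed
    Xm = sm.add_constant(X.loc[missing].copy(), has_constant="add")
    for level in obs_species[1:]:
        Xm[f"species[{level.split()[0]}]"] = float(shares[level])
    Xm = Xm[fit.params.index]
    pred = np.exp(Xm.to_numpy() @ fit.params.to_numpy())

    out = traits.copy()
    out.loc[missing, "sa"] = pred
    out.loc[missing, "sa_imputed"] = True
    return out


def fit_growth_model(
    traits: pd.DataFrame,
    delta_cut: float = 2.0,
    use_aicc: bool = False,
    screen: bool = True,
    alpha: float = 0.05,
) -> tuple[AveragedModel, list[ModelFit], list[str]]:
    """The growth analysis: screen interactions, enumerate subsets, average.

    Expects a trait table with no missing SA (impute or drop beforehand).
    Returns (averaged model, all candidate fits, retained interactions).
    """
    interactions = screen_interactions(traits, GROWTH_DESIGN, alpha) if screen else []
    dm = transform_and_scale(traits, GROWTH_DESIGN, interactions=interactions)
    fits = enumerate_subsets(dm, use_aicc=use_aicc)
    return average_models(fits, delta_cut), fits, interactions


def fit_sa_model(traits: pd.DataFrame, use_aicc: bool = False) -> ModelFit:
    """The sapwood-area determinants model (full model, no averaging).

    Scaled log(SA) ~ scaled{sapwood growth, sapwood lifespan, log(BA)} +
    species, on trees with *observed* SA only (imputed rows excluded).
    """
    ok = traits["sa"].notna()
    if "sa_imputed" in traits:
        ok &= ~traits["sa_imputed"].astype(bool)
    sub = traits.loc[ok]
    if sub.empty:
        raise InferenceError("no trees with observed sapwood area")
    dm = transform_and_scale(sub, SA_DESIGN)
    cols = [c for g in dm.groups for c in g.columns]
    return fit_lm(dm.X[cols], dm.y, terms=tuple(g.name for g in dm.groups),
                  use_aicc=use_aicc)


# ---------------------------------------------------------------------------
# Path analysis
# ---------------------------------------------------------------------------

@dataclass
class PathResult:
    """Saturated path model on species-mean-centered variables.

    ``paths``: regression of growth on height, SA, TLA (coef, se, t, p).
    ``correlations``: pairwise Pearson r (and p) among the three predictors.
    The model is saturated, so no overall fit statistic exists.
    """

    paths: pd.DataFrame
    correlations: pd.DataFrame
    n: int


def path_analysis(traits: pd.DataFrame, scale: bool = True) -> PathResult:
    """Growth ~ height + SA + TLA with species means subtracted.

    Variables are transformed as in the growth model (log growth, log SA,
    sqrt TLA), species-mean-centered to remove intercept differences among
    species, and (by default) SD-scaled.  Path coefficients equal the OLS
    estimates on the centered data; predictor associations are Pearson
    correlations with t-based p-values.
    """
    cols = {"growth": ("agr", "log"), "height": ("height", "none"),
            "sa": ("sa", "log"), "tla": ("tla", "sqrt")}
    ok = np.ones(len(traits), dtype=bool)
    for trait, _ in cols.values():
        ok &= traits[trait].notna().to_numpy()
    sub = traits.loc[ok]
    data = pd.DataFrame({
        name: apply_transform(sub[trait], tf, trait, sub.get("tree_id"))
        for name, (trait, tf) in cols.items()
    })
    sizes = sub.groupby("species").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        logger.warning("species with a single tree center to zero: %s", singletons)
    centered = data.groupby(sub["species"].to_numpy()).transform(
        lambda s: s - s.mean())
    if scale:
        centered = centered / centered.std(ddof=1)

    fit = fit_lm(centered[["height", "sa", "tla"]], centered["growth"])
    paths = pd.DataFrame({
        "coef": fit.params, "se": fit.se, "t": fit.tvalues, "p": fit.pvalues,
    }).drop(index="const")

    pairs = list(itertools.combinations(["height", "sa", "tla"], 2))
    rows = []
    for a, b in pairs:
        r, p = scipy.stats.pearsonr(centered[a], centered[b])
        rows.append({"var1": a, "var2": b, "r": float(r), "p": float(p)})
    return PathResult(paths=paths, correlations=pd.DataFrame(rows), n=len(sub))


# ---------------------------------------------------------------------------
# Trait summary
# ---------------------------------------------------------------------------

SUMMARY_VARIABLES = ["agr", "height", "tla", "sa", "sla", "n_leaf", "n_sapw",
                     "ba", "sapwood_lifespan", "sapwood_growth"]


def summarize_traits(traits: pd.DataFrame,
                     variables: Sequence[str] = SUMMARY_VARIABLES) -> pd.DataFrame:
    """Mean, min, max, sample SD (n-1) and CV = SD/mean per trait variable."""
    if len(traits) < 2:
        raise InferenceError("trait summary needs at least 2 trees")
    rows = {}
    for var in variables:
        vals = traits[var].dropna().astype(float)
        if vals.empty:
            logger.warning("variable %s is all-null; summary is null", var)
            rows[var] = dict.fromkeys(["mean", "min", "max", "sd", "cv"], np.nan)
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rows[var] = {"mean": mean, "min": float(vals.min()),
                     "max": float(vals.max()), "sd": sd,
                     "cv": sd / mean if mean != 0 else np.nan}
    return pd.DataFrame(rows).T[["mean", "min", "max", "sd", "cv"]]
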