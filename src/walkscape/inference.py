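"""Hypothesis-testing stages over the assembled trip table.

The unit of analysis is the individual walking trip, with trips nested
within participants. Three hypothesis-testing stages:

* H1 — four linear mixed-effects models (one per subjective rating
  scale) with a participant random intercept and a set of standardized
  environmental predictors entered jointly.
* H2 — five thematic predictor blocks (noise, temperature, technical
  infrastructure, functional POIs, visual elements), each fitted
  against all 27 physiological indicators; associations are retained
  when both p < 0.05 and |beta| > 0.1.
* H3 — K-means typologies over standardized environmental variables
  (k chosen by the elbow rule), with Kruskal-Wallis rank tests of the
  physiological and subjective outcomes across clusters.

Mixed models are fitted by restricted maximum likelihood
(statsmodels MixedLM) and report Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .physio import PHYSIO_INDICATORS

__all__ = [
    "RATING_COLUMNS",
    "H1_PREDICTORS",
    "H2_BLOCKS",
    "H3_ENV_COLUMNS",
    "ClusterReport",
    "standardize",
    "pearson_matrix",
    "fit_mixed",
    "run_h1",
    "run_h2",
    "choose_k_elbow",
    "run_h3",
]

#: The four post-trip rating scales.
RATING_COLUMNS = ("trip_feeling_env", "unwell_well", "agitated_calm", "tired_awake")

#: Default jointly-entered H1 predictor set: greenery, openness,
#: pedestrian micro-infrastructure, functional POI densities, slope.
H1_PREDICTORS = (
    "ndvi_mean", "ndvi_max",
    "img_vegetation", "img_sky", "img_sidewalk", "img_curbs",
    "poi_leisure", "poi_tourism", "poi_arts", "poi_greenery", "poi_water",
    "slope_mean",
)

#: Default H2 thematic stressor blocks (config-driven; the noise block can
#: be switched to the maximum-Lden variant).
H2_BLOCKS = {
    "noise": ("noise_lden_mean",),
    "temperature": ("t_max", "t_mean"),
    "technical_infrastructure": ("img_curbs", "img_poles"),
    "functional_pois": ("poi_services", "poi_commerce", "poi_public", "poi_leisure"),
    "visual_elements": ("img_cars", "img_pedestrians"),
}

#: Default H3 clustering feature set.
H3_ENV_COLUMNS = (
    "ndvi_mean", "img_sky", "img_vegetation", "noise_lden_mean",
    "poi_leisure", "poi_tourism", "poi_arts", "poi_greenery", "poi_water",
    "poi_services", "poi_commerce", "poi_public",
)

POI_PREFIX = "poi_"


def standardize(table: pd.DataFrame, columns, poi_fill_zero: bool = True):
    """Z-score ``columns`` over all trips pooled (population SD).

    Missing values in POI columns (``poi_*``) are replaced with zero
    *before* standardization (the missing-POI -> zero rule). Columns
    with zero variance are dropped with a warning. Returns
    ``(table_z, scaling)`` where scaling maps column -> (mean, sd) for
    back-transformation; non-listed columns pass through unchanged.
    """
    out = table.copy()
    scaling = {}
    for col in columns:
        x = pd.to_numeric(out[col], errors="coerce")
        if poi_fill_zero and col.startswith(POI_PREFIX):
            x = x.fillna(0.0)
        mu = float(x.mean())
        sd = float(x.std(ddof=0))
        if not np.isfinite(sd) or sd == 0.0:
            warnings.warn(f"column {col!r} has zero variance; dropped", stacklevel=2)
            out = out.drop(columns=[col])
            continue
        out[col] = (x - mu) / sd
        scaling[col] = (mu, sd)
    return out, scaling


def pearson_matrix(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix (diagonal 1).

    Requires at least 3 complete pairs per cell; cells with fewer, or
    involving a constant variable, are NaN.
    """
    sub = table[list(variables)].apply(pd.to_numeric, errors="coerce")
    r = sub.corr(method="pearson", min_periods=3)
    for v in variables:
        if sub[v].notna().sum() >= 1 and sub[v].std(ddof=0) == 0:
            r.loc[v, :] = np.nan
            r.loc[:, v] = np.nan
        else:
            r.loc[v, v] = 1.0
    return r


def fit_mixed(
    table: pd.DataFrame,
    outcome: str,
    predictors,
    group: str = "participant_id",
    reml: bool = True,
):
    """Random-intercept linear mixed model ``outcome ~ predictors + (1|group)``.

    Fitted by REML; returns ``(effect_rows, intercept_variance)`` where
    effect_rows is a DataFrame with one row per predictor (beta, se,
    Wald p, converged flag). Requires at least 2 groups with at least
    2 trips each. Non-convergence is flagged, never silent.
    """
    import statsmodels.formula.api  # noqa: F401  (ensures statsmodels fully loaded)
    from statsmodels.regression.mixed_linear_model import MixedLM

    predictors = list(predictors)
    cols = [outcome, *predictors, group]
    data = table[cols].dropna()
    sizes = data.groupby(group).size()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 participants with >= 2 trips each")
    endog = data[outcome].astype(float)
    exog = data[predictors].astype(float)
    exog = exog.assign(Intercept=1.0)[["Intercept", *predictors]]
    model = MixedLM(endog, exog, groups=data[group])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            converged = False
            res = None
        if res is None or not converged:
            try:
                res = model.fit(reml=reml, method="powell")
                converged = bool(getattr(res, "converged", True))
            except Exception:
                if res is None:
                    raise
    rows = []
    for pred in predictors:
        rows.append(
            {
                "outcome": outcome,
                "predictor": pred,
                "beta": float(res.params[pred]),
                "se": float(res.bse[pred]),
                "p": float(res.pvalues[pred]),
                "converged": converged,
            }
        )
    var_re = float(np.asarray(res.cov_re)[0, 0])
    return pd.DataFrame(rows), var_re


def run_h1(
    table: pd.DataFrame,
    predictors=H1_PREDICTORS,
    outcomes=RATING_COLUMNS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """H1: four rating outcomes on jointly-entered standardized predictors.

    Returns the full effect table with a ``significant`` flag
    (p < alpha); filter on it for the significant-only view.
    """
    missing = [c for c in (*predictors, *outcomes) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    z, _ = standardize(table, predictors)
    kept = [p for p in predictors if p in z.columns]
    frames = []
    for outcome in outcomes:
        rows, var_re = fit_mixed(z, outcome, kept)
        rows["intercept_var"] = var_re
        frames.append(rows)
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p"] < alpha
    return out


def run_h2(
    table: pd.DataFrame,
    blocks=None,
    outcomes=PHYSIO_INDICATORS,
    alpha: float = 0.05,
    beta_gate: float = 0.1,
    fdr: bool = False,
) -> pd.DataFrame:
    """H2: thematic stressor blocks x physiological indicators.

    Each block is fitted in a separate random-intercept model against
    each outcome (5 x 27 = 135 models with the defaults). Associations
    are retained when p < alpha AND |beta| > beta_gate. With
    ``fdr=True`` a Benjamini-Hochberg adjusted p is added and used for
    the significance side of the retention rule.
    """
    blocks = dict(H2_BLOCKS if blocks is None else blocks)
    all_preds = sorted({p for preds in blocks.values() for p in preds})
    missing = [c for c in all_preds if c not in table.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    z, _ = standardize(table, all_preds)
    frames = []
    for block, preds in blocks.items():
        kept = [p for p in preds if p in z.columns]
        if not kept:
            continue
        for outcome in outcomes:
            if outcome not in z.columns or z[outcome].notna().sum() < 10:
                continue
            rows, var_re = fit_mixed(z, outcome, kept)
            rows["block"] = block
            rows["intercept_var"] = var_re
            frames.append(rows)
    out = pd.concat(frames, ignore_index=True)
    pcol = "p"
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        pcol = "p_fdr"
    out["significant"] = out[pcol] < alpha
    out["retained"] = out["significant"] & (out["beta"].abs() > beta_gate)
    return out


def choose_k_elbow(features, k_range=range(2, 9), seed: int = 0, n_init: int = 10):
    """Elbow rule: k with the maximal curvature of the within-cluster SS curve.

    Inertia is computed for every k in ``k_range`` plus one value on
    either side (floored at 1), and the second difference of
    ``log(wcss)`` is maximized over the range. The log scale makes the
    curvature scale-invariant; on the raw scale the k=1 -> 2 drop
    dominates and the rule degenerates to always answering the smallest
    k.
    """
    X = np.asarray(features, dtype=float)
    ks = sorted(set(k_range))
    lo, hi = max(1, ks[0] - 1), ks[-1] + 1
    wcss = {}
    for k in range(lo, hi + 1):
        if k >= len(X):
            break
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        wcss[k] = km.inertia_
    best_k, best_curv = None, -np.inf
    for k in ks:
        if k - 1 not in wcss or k + 1 not in wcss:
            continue
        if wcss[k] <= 0:  # perfect partition: cannot do better
            return k
        curv = (np.log(wcss[k - 1]) - 2.0 * np.log(wcss[k])
                + np.log(wcss[k + 1]))
        if curv > best_curv:
            best_k, best_curv = k, curv
    if best_k is None:
        raise ValueError("k_range too wide for the number of samples")
    return best_k


@dataclass
class ClusterReport:
    """K-means typology of trips plus rank tests of outcomes across clusters."""

    k: int
    assignments: pd.Series  # trip index -> cluster label
    centroids: pd.DataFrame  # standardized feature space
    kw: pd.DataFrame  # variable, chi2, p
    profiles: pd.DataFrame  # per-cluster raw-scale feature means
    scaling: dict = field(default_factory=dict)


def kruskal_by_cluster(table: pd.DataFrame, labels, variables) -> pd.DataFrame:
    """Kruskal-Wallis chi-square (tie-corrected) per variable across clusters."""
    rows = []
    labels = np.asarray(labels)
    for var in variables:
        if var not in table.columns:
            continue
        x = pd.to_numeric(table[var], errors="coerce")
        groups = [x[(labels == g) & x.notna()].to_numpy() for g in np.unique(labels)]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2 or all(np.all(g == groups[0][0]) for g in groups):
            rows.append({"variable": var, "chi2": 0.0, "p": 1.0})
            continue
        try:
            chi2, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            chi2, p = 0.0, 1.0
        rows.append({"variable": var, "chi2": float(chi2), "p": float(p)})
    return pd.DataFrame(rows)


def run_h3(
    table: pd.DataFrame,
    env_columns=H3_ENV_COLUMNS,
    outcome_columns=None,
    k: int = None,
    k_range=range(2, 9),
    seed: int = 0,
    n_init: int = 10,
) -> ClusterReport:
    """H3: environmental typologies and outcome differences across them.

    K-means is run on standardized environmental features (missing POIs
    imputed 0) with ``n_init`` restarts and a fixed seed; ``k`` defaults
    to the elbow choice over ``k_range``. Cluster labels are canonically
    reordered by descending mean noise exposure so reports are
    comparable across runs. Kruskal-Wallis tests compare every outcome
    (physiological indicators + ratings by default) across clusters.
    """
    env_columns = [c for c in env_columns if c in table.columns]
    if not env_columns:
        raise ValueError("no environmental feature columns present")
    z, scaling = standardize(table, env_columns)
    feats = [c for c in env_columns if c in z.columns]
    X = z[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("environmental features contain missing values after imputation")
    if k is None:
        k = choose_k_elbow(X, k_range=k_range, seed=seed, n_init=n_init)
    if len(X) < k:
        raise ValueError(f"fewer trips ({len(X)}) than clusters ({k})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(X)

    # canonical ordering: descending noise mean (falls back to first feature)
    order_col = "noise_lden_mean" if "noise_lden_mean" in feats else feats[0]
    col_idx = feats.index(order_col)
    means = [km.cluster_centers_[g, col_idx] for g in range(k)]
    order = np.argsort(means)[::-1]
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = np.array([relabel[int(g)] for g in raw_labels])
    centroids = pd.DataFrame(
        km.cluster_centers_[order], columns=feats, index=range(k)
    )

    if outcome_columns is None:
        outcome_columns = [
            c for c in (*PHYSIO_INDICATORS, *RATING_COLUMNS) if c in table.columns
        ]
    kw = kruskal_by_cluster(table, labels, outcome_columns)
    prof = table.assign(cluster=labels).groupby("cluster")[feats].mean()
    return ClusterReport(
        k=k,
        assignments=pd.Series(labels, index=table.index, name="cluster"),
        centroids=centroids,
        kw=kw,
        profiles=prof,
        scaling=scaling,
    )
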