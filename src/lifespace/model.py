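"""Within/between-person disaggregated mixed-effects models.

For each daily life-space feature y_id (participant i, day d) the model is

    y_id = b0 + bw * (pain_id - pain_bar_i) + bb * (pain_bar_i - pain_gm)
         + g1 * age_i + g2 * female_i + g3 * lives_alone_i + u_i + e_id

with a participant random intercept u_i ~ N(0, tau^2) and independent
within-participant residuals e_id ~ N(0, sigma^2) (the "independent"
covariance structure).  Person-mean centering around the grand mean
separates the within-person effect bw (does a person's mobility fall on
days their pain is above their own average?) from the between-person
effect bb (do people with higher average pain move less?).  Fitting is by
restricted maximum likelihood; inference uses the normal (z) reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .features import FEATURE_COLUMNS

DEFAULT_COVARIATES = ("age", "female", "lives_alone")
Z_95 = 1.96


def center_within_between(
    values, groups, grand: str = "person_mean"
):
    """Split a time-varying variable into between- and within-person parts.

    Parameters
    ----------
    values, groups
        Aligned 1-D sequences: the raw variable and the participant of
        each observation; missing values are not allowed here (drop first).
    grand
        ``"person_mean"`` (default) centers person means at the unweighted
        mean of person means, so participants with more days do not
        dominate; ``"pooled"`` uses the plain observation mean.

    Returns
    -------
    (between, within, grand_mean): per-observation arrays such that
    ``grand_mean + between + within`` reconstructs the raw values exactly;
    ``between`` is constant within person and ``within`` averages to zero
    within every person.
    """
    s = pd.Series(np.asarray(values, dtype=float), dtype=float)
    g = pd.Series(np.asarray(groups))
    if s.isna().any():
        raise ValueError("missing values must be dropped before centering")
    person_means = s.groupby(g.values).transform("mean")
    unique_means = s.groupby(g.values).mean()
    if len(unique_means) < 2:
        raise ValueError("at least two participants required to disaggregate")
    if grand == "person_mean":
        grand_mean = float(unique_means.mean())
    elif grand == "pooled":
        grand_mean = float(s.mean())
    else:
        raise ValueError("grand must be 'person_mean' or 'pooled'")
    between = person_means.to_numpy() - grand_mean
    within = s.to_numpy() - person_means.to_numpy()
    return between, within, grand_mean


@dataclass
class ModelFit:
    """Per-feature fit: fixed-effect table plus variance components."""

    feature: str
    params: pd.DataFrame  # index: term; columns coef, se, z, p_value, ci_low, ci_high
    re_var: float
    resid_var: float
    n_obs: int
    n_participants: int
    converged: bool
    message: str = ""

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]


def _wald_table(names, coefs, ses) -> pd.DataFrame:
    coefs = np.asarray(coefs, dtype=float)
    ses = np.asarray(ses, dtype=float)
    z = np.divide(coefs, ses, out=np.full_like(coefs, np.nan), where=ses > 0)
    return pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "z": z,
            "p_value": 2.0 * norm.sf(np.abs(z)),
            "ci_low": coefs - Z_95 * ses,
            "ci_high": coefs + Z_95 * ses,
        },
        index=pd.Index(names, name="term"),
    )


def fit_feature_model(
    panel: pd.DataFrame,
    feature: str,
    covariates=DEFAULT_COVARIATES,
    grand: str = "person_mean",
    reml: bool = True,
    random_intercept: bool = True,
) -> ModelFit:
    """Fit the disaggregated model for one feature.

    ``panel`` needs columns ``participant_id, mean_pain``, the feature, and
    the covariates; rows with missing outcome, pain or covariates are
    dropped list-wise.  With ``random_intercept=False`` the identical fixed
    design is fit by OLS (useful as the tau^2 = 0 reference).
    """
    cols = ["participant_id", "mean_pain", feature, *covariates]
    d = panel[cols].dropna().reset_index(drop=True)
    if len(d) < 10:
        raise ValueError(f"only {len(d)} usable rows for {feature}; need >= 10")
    between, within, _ = center_within_between(
        d["mean_pain"], d["participant_id"], grand=grand
    )
    # constant covariates (e.g. nobody lives alone in a small cohort) make
    # the design singular; drop them rather than fail
    kept = [c for c in covariates if d[c].nunique() > 1]
    dropped = [c for c in covariates if c not in kept]
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "pain_within": within,
            "pain_between": between,
            **{c: d[c].to_numpy(dtype=float) for c in kept},
        }
    )
    endog = d[feature].to_numpy(dtype=float)
    groups = d["participant_id"].to_numpy()
    n_groups = len(np.unique(groups))

    if not random_intercept:
        res = sm.OLS(endog, exog).fit()
        table = _wald_table(exog.columns, res.params, res.bse)
        return ModelFit(
            feature, table, 0.0, float(res.scale), len(d), n_groups, True, "ols"
        )

    between_var = float(np.var(d.groupby("participant_id")[feature].mean()))
    message = f"dropped constant covariates: {dropped}" if dropped else ""
    res = None
    # boundary fits (random-intercept variance ~ 0) can defeat individual
    # optimisers; try a short sequence and keep the first that converges
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "lbfgs", "powell", "cg"):
            try:
                candidate = sm.MixedLM(endog, exog, groups=groups).fit(
                    reml=reml, method=method
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res is None:
                res = candidate
            if getattr(candidate, "converged", False):
                res = candidate
                break
    if res is None:
        raise RuntimeError(f"mixed model for {feature} failed with every optimizer")
    converged = bool(getattr(res, "converged", True))
    re_var = float(np.asarray(res.cov_re)[0, 0])
    if re_var <= 1e-10 or between_var <= 1e-12:
        message = (message + "; " if message else "") + (
            "random-intercept variance at boundary (near-singular fit)"
        )
    if not converged:
        message = (message + "; " if message else "") + "optimizer did not converge"
    table = _wald_table(exog.columns, res.fe_params, res.bse_fe)
    return ModelFit(
        feature,
        table,
        re_var,
        float(res.scale),
        len(d),
        n_groups,
        converged,
        message,
    )


def build_panel(
    features_df: pd.DataFrame,
    pain_days: pd.DataFrame,
    demographics: pd.DataFrame,
    require_valid: bool = True,
) -> pd.DataFrame:
    """Join daily features, day-mean pain and person covariates.

    Only days flagged valid (enough fixes) with a non-missing day-mean
    pain survive into the modelling panel.
    """
    feats = features_df
    if require_valid and "valid" in feats.columns:
        feats = feats[feats["valid"].astype(bool)]
    panel = feats.merge(
        pain_days[["participant_id", "local_date", "mean_pain", "n_answered"]],
        on=["participant_id", "local_date"],
        how="inner",
    )
    panel = panel.merge(
        demographics[["participant_id", "age", "female", "lives_alone"]],
        on="participant_id",
        how="left",
    )
    return panel[panel["mean_pain"].notna()].reset_index(drop=True)


def fit_all_features(
    panel: pd.DataFrame,
    features=None,
    covariates=DEFAULT_COVARIATES,
    grand: str = "person_mean",
    reml: bool = True,
) -> pd.DataFrame:
    """Fit every feature and return one tidy coefficient table.

    One row per (feature, term); failures of individual feature models are
    isolated and recorded in the ``status`` column.  No multiplicity
    adjustment is applied.
    """
    features = list(features) if features is not None else list(FEATURE_COLUMNS)
    rows = []
    for feature in features:
        try:
            fit = fit_feature_model(
                panel, feature, covariates=covariates, grand=grand, reml=reml
            )
        except Exception as exc:  # noqa: BLE001 - per-feature isolation
            rows.append(
                {
                    "feature": feature,
                    "term": "pain_within",
                    "status": f"failed: {exc}",
                }
            )
            continue
        status = "ok" if fit.converged else "not converged"
        if fit.message and fit.message != "ols":
            status = f"{status}; {fit.message}" if status != "ok" else fit.message
        for term, row in fit.params.iterrows():
            rows.append(
                {
                    "feature": feature,
                    "term": term,
                    "coef": row["coef"],
                    "se": row["se"],
                    "z": row["z"],
                    "p_value": row["p_value"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "re_var": fit.re_var,
                    "resid_var": fit.resid_var,
                    "n_obs": fit.n_obs,
                    "n_participants": fit.n_participants,
                    "converged": fit.converged,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
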