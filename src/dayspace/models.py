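"""Person-day panel assembly and random-intercept mixed models.

Day-level MVPA minutes (log-transformed) are regressed on the four
daily exposure metrics, each split by person-mean centering into a
between-subject (BS: person mean, grand-mean centered) and a
within-subject (WS: day deviation) term — except the binary park
exposure, whose WS term stays the raw 0/1 for interpretability.
Models are linear mixed models with a participant random intercept;
estimates are exponentiated for reporting on the multiplicative
scale. Effect modification is probed with product terms and simple
slopes at modifier levels (-1 SD / mean / +1 SD when continuous).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .config import ModelSpec

log = logging.getLogger(__name__)

KEY = ["participant_id", "wave", "date"]

__all__ = [
    "VarianceComponents",
    "ModelResult",
    "assemble_panel",
    "transform_outcome",
    "inverse_transform_outcome",
    "person_mean_center",
    "fit_null_icc",
    "fit_main_model",
    "fit_interaction_model",
    "simple_slopes",
    "predicted_trajectories",
]


@dataclass
class VarianceComponents:
    between_var: float
    within_var: float
    converged: bool = True

    @property
    def icc(self) -> float:
        total = self.between_var + self.within_var
        return self.between_var / total if total > 0 else float("nan")


@dataclass
class ModelResult:
    """Fixed effects (log and exponentiated scales), variance components, fit metadata."""

    terms: pd.DataFrame  # index: term; estimate_log, se, estimate_exp, ci_low, ci_high, p
    variance: VarianceComponents
    method: str  # ML | REML
    converged: bool
    n_obs: int
    n_groups: int
    cov_params: pd.DataFrame = field(repr=False, default=None)
    exog_means: pd.Series = field(repr=False, default=None)
    log_offset: float = 1.0


def transform_outcome(mvpa_minutes, offset: float = 1.0):
    """log(minutes + offset); the offset keeps zero-MVPA days finite."""
    m = np.asarray(mvpa_minutes, dtype=float)
    if np.any(m < 0):
        raise ValueError("MVPA minutes must be non-negative")
    return np.log(m + offset)


def inverse_transform_outcome(x, offset: float = 1.0):
    return np.exp(np.asarray(x, dtype=float)) - offset


def assemble_panel(
    exposure_df: pd.DataFrame,
    activity_df: pd.DataFrame,
    roster: pd.DataFrame,
    temperature: pd.DataFrame | None = None,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """Inner-join exposures, day-level activity, covariates and temperature.

    Keeps only person-days valid on both instruments, logging counts
    excluded by each rule; adds the log outcome, weekend indicator and
    wave dummies. Raises on duplicate (participant, wave, date) keys.
    """
    for name, df in (("exposure", exposure_df), ("activity", activity_df)):
        if df.duplicated(KEY).any():
            raise ValueError(f"duplicate {KEY} keys in {name} rows")

    n_accel = len(activity_df)
    act_valid = activity_df[activity_df["valid"].astype(bool)].copy()
    log.info("activity days: %d total, %d removed by the 10-h wear rule", n_accel,
             n_accel - len(act_valid))
    merged = act_valid.merge(exposure_df, on=KEY, how="inner", suffixes=("", "_exp"))
    log.info("removed %d valid-wear days without matched exposure; panel has %d person-days",
             len(act_valid) - len(merged), len(merged))

    panel = merged.merge(roster, on="participant_id", how="left", validate="many_to_one")
    if temperature is not None:
        panel = panel.merge(temperature, on="date", how="left")
    if "day_type" not in panel.columns and "day_type_exp" in panel.columns:
        panel["day_type"] = panel["day_type_exp"]
    panel["weekend"] = (panel["day_type"] == "weekend").astype(int)
    for wave in ("T3", "PP"):
        panel[f"wave_{wave}"] = (panel["wave"] == wave).astype(int)
    if "bmi_category" in panel.columns:
        panel["bmi_overweight"] = (panel["bmi_category"] == "overweight").astype(int)
        panel["bmi_obese"] = (panel["bmi_category"] == "obese").astype(int)
    if "temperature_c" not in panel.columns and temperature is None:
        panel["temperature_c"] = 0.0
    panel["log_mvpa"] = transform_outcome(panel["mvpa_minutes"], offset=log_offset)
    panel["parks_any"] = panel["parks_any"].astype(int)
    return panel.reset_index(drop=True)


def person_mean_center(
    panel: pd.DataFrame,
    variables,
    group: str = "participant_id",
    binary: tuple[str, ...] = ("parks_any",),
) -> pd.DataFrame:
    """Add between-subject (BS) and within-subject (WS) columns.

    Continuous variables: BS = person mean, centered on the grand mean
    of person means; WS = day value minus person mean (so WS sums to 0
    within each person). Binary variables in ``binary``: BS is the
    centered person proportion, WS stays the raw 0/1 indicator.
    """
    out = panel.copy()
    for var in variables:
        if var not in out.columns:
            raise KeyError(f"variable {var!r} not in panel")
        pm = out.groupby(group)[var].transform("mean")
        grand = out.groupby(group)[var].mean().mean()
        out[f"{var}_bs"] = pm - grand
        out[f"{var}_ws"] = out[var] if var in binary else out[var] - pm
    return out


def _mixedlm(panel: pd.DataFrame, outcome: str, fixed: list[str], reml: bool):
    missing = [c for c in fixed + [outcome] if c not in panel.columns]
    if missing:
        raise KeyError(f"panel lacks model columns: {missing}")
    exog = sm.add_constant(panel[fixed].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [exog.columns[i] for i in range(exog.shape[1])
                   if i >= len(diag) or diag[i] < 1e-8]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    model = sm.MixedLM(panel[outcome].astype(float), exog, groups=panel["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError:  # hessian singular near a variance boundary
            res = model.fit(reml=reml, method="powell")
    return res, exog


def _result_from(res, exog, reml: bool, panel: pd.DataFrame, log_offset: float) -> ModelResult:
    fe = res.fe_params
    se = res.bse_fe if hasattr(res, "bse_fe") else res.bse[fe.index]
    z = st.norm.ppf(0.975)
    terms = pd.DataFrame(
        {
            "estimate_log": fe,
            "se": se,
            "estimate_exp": np.exp(fe),
            "ci_low": np.exp(fe - z * se),
            "ci_high": np.exp(fe + z * se),
            "p": 2 * st.norm.sf(np.abs(fe / se)),
        }
    )
    variance = VarianceComponents(
        between_var=float(np.asarray(res.cov_re)[0, 0]),
        within_var=float(res.scale),
        converged=bool(res.converged),
    )
    return ModelResult(
        terms=terms,
        variance=variance,
        method="REML" if reml else "ML",
        converged=bool(res.converged),
        n_obs=int(res.nobs),
        n_groups=panel["participant_id"].nunique(),
        cov_params=res.cov_params().loc[fe.index, fe.index],
        exog_means=exog.mean(),
        log_offset=log_offset,
    )


def fit_null_icc(panel: pd.DataFrame, outcome: str = "log_mvpa") -> VarianceComponents:
    """Intercept-only random-intercept model (REML); ICC = between / total.

    Quantifies how much day-level outcome variation is between
    participants, the justification for multilevel modelling.
    """
    counts = panel.groupby("participant_id").size()
    if len(counts) < 2 or counts.max() < 2:
        raise ValueError("need >= 2 participants with >= 2 days for variance components")
    model = sm.MixedLM(
        panel[outcome].astype(float),
        np.ones((len(panel), 1)),
        groups=panel["participant_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    if not res.converged:
        log.warning("null ICC model did not converge")
    return VarianceComponents(
        between_var=float(np.asarray(res.cov_re)[0, 0]),
        within_var=float(res.scale),
        converged=bool(res.converged),
    )


def model_terms(spec: ModelSpec, panel: pd.DataFrame) -> list[str]:
    fixed = [f"{e}_{side}" for e in spec.exposures for side in ("bs", "ws")]
    return fixed + [c for c in spec.covariates if c in panel.columns]


def fit_main_model(panel: pd.DataFrame, spec: ModelSpec | None = None,
                   outcome: str = "log_mvpa") -> ModelResult:
    """The main model: all four exposures (BS + WS) plus covariates, random intercept."""
    spec = spec or ModelSpec()
    fixed = model_terms(spec, panel)
    res, exog = _mixedlm(panel, outcome, fixed, spec.reml)
    return _result_from(res, exog, spec.reml, panel, spec.log_offset)


def fit_interaction_model(
    panel: pd.DataFrame,
    exposure_term: str,
    modifier: str,
    spec: ModelSpec | None = None,
    outcome: str = "log_mvpa",
) -> ModelResult:
    """Main model plus exposure x modifier product term(s).

    A non-numeric modifier is expanded to dummy indicators (first
    level as reference), each interacted with the exposure term.
    Interaction p-values are screened at p < 0.05 with no multiplicity
    correction.
    """
    spec = spec or ModelSpec()
    work = panel.copy()
    if modifier not in work.columns:
        raise KeyError(f"modifier {modifier!r} not in panel")
    if work[modifier].nunique() < 2:
        raise ValueError(f"modifier {modifier!r} is constant")
    if pd.api.types.is_numeric_dtype(work[modifier]):
        mod_cols = [modifier]
    else:
        dummies = pd.get_dummies(work[modifier], prefix=modifier, drop_first=True, dtype=float)
        work[list(dummies.columns)] = dummies
        mod_cols = list(dummies.columns)
    fixed = model_terms(spec, work)
    for mc in mod_cols:
        if mc not in fixed:
            fixed.append(mc)
        inter = f"{exposure_term}:{mc}"
        work[inter] = work[exposure_term].astype(float) * work[mc].astype(float)
        fixed.append(inter)
    res, exog = _mixedlm(work, outcome, fixed, spec.reml)
    return _result_from(res, exog, spec.reml, work, spec.log_offset)


def modifier_levels(panel: pd.DataFrame, modifier: str) -> dict[str, float]:
    """-1 SD / mean / +1 SD of a continuous modifier, from the panel."""
    m, s = float(panel[modifier].mean()), float(panel[modifier].std())
    return {"-1SD": m - s, "mean": m, "+1SD": m + s}


def simple_slopes(
    result: ModelResult,
    exposure_term: str,
    modifier: str,
    levels: dict[str, float],
    observed_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Exposure slope at given modifier levels, with delta-method 95% CIs.

    slope(level) = b_exposure + b_interaction * level;
    var = v_ee + level^2 v_ii + 2 level v_ei. Estimates are
    exponentiated for the multiplicative scale.
    """
    inter = f"{exposure_term}:{modifier}"
    if inter not in result.terms.index:
        raise KeyError(f"result has no interaction term {inter!r}")
    be = result.terms.loc[exposure_term, "estimate_log"]
    bi = result.terms.loc[inter, "estimate_log"]
    cov = result.cov_params
    vee = cov.loc[exposure_term, exposure_term]
    vii = cov.loc[inter, inter]
    vei = cov.loc[exposure_term, inter]
    z = st.norm.ppf(0.975)
    rows = []
    for name, level in levels.items():
        if observed_range is not None and not (observed_range[0] <= level <= observed_range[1]):
            log.warning("modifier level %s=%.3g outside observed range %s", name, level,
                        observed_range)
        slope = be + bi * level
        se = float(np.sqrt(vee + level**2 * vii + 2 * level * vei))
        rows.append(
            {
                "level": name,
                "modifier_value": level,
                "slope_log": slope,
                "se": se,
                "slope_exp": np.exp(slope),
                "ci_low": np.exp(slope - z * se),
                "ci_high": np.exp(slope + z * se),
                "p": 2 * st.norm.sf(abs(slope / se)) if se > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def predicted_trajectories(
    result: ModelResult,
    exposure_term: str,
    exposure_grid,
    modifier: str | None = None,
    levels: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Model-predicted MVPA minutes over an exposure grid at modifier levels.

    Other fixed effects are held at their sample means; predictions
    are back-transformed via exp(x) - offset.
    """
    means = result.exog_means.copy()
    levels = levels or {"": 0.0}
    rows = []
    for name, level in levels.items():
        for x in np.asarray(exposure_grid, dtype=float):
            v = means.copy()
            v[exposure_term] = x
            if modifier is not None:
                v[modifier] = level
                inter = f"{exposure_term}:{modifier}"
                if inter in v.index:
                    v[inter] = x * level
            pred_log = float((result.terms["estimate_log"] * v[result.terms.index]).sum())
            rows.append(
                {
                    "level": name,
                    "modifier_value": level,
                    "exposure": x,
                    "pred_log": pred_log,
                    "pred_mvpa_minutes": max(
                        0.0, float(np.exp(pred_log) - result.log_offset)
                    ),
                }
            )
    return pd.DataFrame(rows)
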