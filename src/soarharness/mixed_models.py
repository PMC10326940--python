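"""Linear mixed-model battery for the segment-level analysis.

Each flight parameter (mean vertical speed, airspeed, glide ratio, maximum
height a.s.l., mean VeDBA) is modelled per flight phase with harness type
and species as interacting categorical fixed effects, hour of day (centred
at 12:00 UTC) and segment length as covariates, and crossed random
intercepts for individual and date. Glide ratio is square-root transformed;
height and VeDBA are log transformed. Temporal autocorrelation is reduced
by keeping every k-th segment within a session (k = 2 for airspeed, 4 for
height, 3 for VeDBA). The harness×species interaction is tested with a
likelihood-ratio test on ML refits and dropped when non-significant at
α = 0.05; coefficients are reported from the REML fit of the retained
structure, with Nakagawa marginal/conditional R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "LRTResult",
    "ModelFit",
    "default_specs",
    "prepare_model_frame",
    "fit_lmm",
    "run_model_battery",
    "percent_change_from_log_coef",
    "net_species_effect",
    "glide_gain_backtransform",
]

ALPHA_INTERACTION = 0.05

REFERENCE_HARNESS = "backpack"
REFERENCE_SPECIES = "black_kite"

TRANSFORMS = {
    "identity": lambda x: x,
    "sqrt": np.sqrt,
    "log": np.log,
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one segment-level mixed model."""

    name: str
    response: str                 # segment-table column
    phase: str                    # 'soaring', 'gliding' or 'passive'
    transform: str = "identity"   # 'identity', 'sqrt' or 'log'
    interaction: bool = True      # harness x species interaction candidate
    subsample_every: int = 1      # keep every k-th segment within a session
    vspeed_max: float | None = None   # optional mean-vert-speed ceiling (m/s)
    exclude_active: bool = False  # drop active-flight segments

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.phase not in ("soaring", "gliding", "passive"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.subsample_every < 1:
            raise ValueError("subsample_every must be >= 1")


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between nested ML fits."""

    chi2: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    """Estimates and derived quantities of one fitted mixed model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    random_sd: dict
    n_obs: int
    marginal_r2: float
    conditional_r2: float
    lrt_interaction: LRTResult | None
    lrt_harness: LRTResult | None
    interaction_retained: bool
    converged: bool


def default_specs() -> list:
    """The seven-model battery of the segment-level analysis."""
    return [
        ModelSpec("vert_speed_soaring", "mean_vert_speed", "soaring"),
        ModelSpec("vert_speed_gliding", "mean_vert_speed", "gliding"),
        ModelSpec("airspeed_soaring", "airspeed", "soaring", subsample_every=2),
        ModelSpec("airspeed_gliding", "airspeed", "gliding", subsample_every=2),
        ModelSpec("glide_ratio", "glide_ratio", "gliding", transform="sqrt", vspeed_max=-0.2),
        ModelSpec("max_height_soaring", "max_height", "soaring", transform="log", subsample_every=4),
        ModelSpec("vedba_passive", "mean_vedba", "passive", transform="log", exclude_active=True),
    ]


def prepare_model_frame(segments: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Filter, transform and subsample the segment table for one model.

    Rows are restricted to the spec's flight phase (``passive`` keeps both
    soaring and gliding but only passive activity), optionally filtered on
    mean vertical speed, the response transformed, and every
    ``subsample_every``-th row kept within each session (ordered by segment
    start). Raises a ``ValueError`` naming the filter that emptied the
    frame.
    """
    df = segments.copy()
    beh = df["behaviour"].astype(str)
    if spec.phase in ("soaring", "gliding"):
        df = df.loc[beh.str.endswith(spec.phase)]
    else:  # passive: both movement phases, passive activity only
        df = df.loc[beh.str.startswith("passive")]
    if spec.exclude_active:
        df = df.loc[df["behaviour"].astype(str).str.startswith("passive")]
    if len(df) == 0:
        raise ValueError(f"model {spec.name}: no rows after phase filter '{spec.phase}'")

    if spec.vspeed_max is not None:
        df = df.loc[df["mean_vert_speed"] < spec.vspeed_max]
        if len(df) == 0:
            raise ValueError(f"model {spec.name}: no rows after vertical-speed filter")

    df = df.loc[df[spec.response].notna()]
    if spec.transform == "log":
        df = df.loc[df[spec.response] > 0]
    elif spec.transform == "sqrt":
        df = df.loc[df[spec.response] >= 0]
    if len(df) == 0:
        raise ValueError(f"model {spec.name}: no rows with a valid response '{spec.response}'")

    df = df.sort_values(["session_id", "start"], kind="stable")
    if spec.subsample_every > 1:
        pos = df.groupby("session_id", sort=False).cumcount()
        df = df.loc[pos % spec.subsample_every == 0]

    out = df.reset_index(drop=True).copy()
    out["y"] = TRANSFORMS[spec.transform](out[spec.response].to_numpy(dtype=float))
    return out


def _fixed_formula(frame: pd.DataFrame, interaction: bool, harness: bool = True) -> str:
    """Build the fixed-effects formula for the data at hand.

    Reference levels are backpack for harness and the species baseline for
    species (the level absent from the reported contrasts); terms are
    dropped automatically when a factor has a single level in the frame.
    """
    terms = []
    n_harness = frame["harness"].nunique()
    n_species = frame["species"].nunique()
    if harness and n_harness > 1:
        terms.append(f"C(harness, Treatment('{REFERENCE_HARNESS}'))")
    if n_species > 1:
        ref = REFERENCE_SPECIES if (frame["species"] == REFERENCE_SPECIES).any() \
            else sorted(frame["species"].unique())[0]
        terms.append(f"C(species, Treatment('{ref}'))")
        if harness and interaction and n_harness > 1:
            terms.append(f"C(harness, Treatment('{REFERENCE_HARNESS}'))"
                         f":C(species, Treatment('{ref}'))")
    terms += ["hour_centred", "n_fixes"]
    return "y ~ " + " + ".join(terms)


def _fit_mixed(formula: str, frame: pd.DataFrame, reml: bool):
    vc = {"individual": "0 + C(individual_id)", "date": "0 + C(date)"}
    model = smf.mixedlm(formula, data=frame, groups=np.ones(len(frame)),
                        vc_formula=vc, re_formula="0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return model.fit(reml=reml, method="lbfgs", maxiter=500)
        except Exception:
            return model.fit(reml=reml, maxiter=500)


def _lrt(full, reduced) -> LRTResult:
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = int(len(full.fe_params) - len(reduced.fe_params))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return LRTResult(float(chi2), df, p)


def _nakagawa_r2(result) -> tuple:
    """Variance-partition (marginal, conditional) R² of a mixed fit."""
    fe_pred = result.model.exog @ result.fe_params
    var_f = float(np.var(fe_pred))
    var_re = float(np.sum(result.vcomp))
    var_eps = float(result.scale)
    total = var_f + var_re + var_eps
    return var_f / total, (var_f + var_re) / total


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec, alpha: float = ALPHA_INTERACTION) -> ModelFit:
    """Fit one mixed model with the interaction decision tree.

    The full model (with harness×species interaction, when both factors
    vary) and its no-interaction reduction are compared with a
    likelihood-ratio test on ML refits; a non-significant interaction
    (p ≥ α) is excluded and coefficients are reported from the REML fit of
    the reduced model. A second LRT drops harness entirely from the
    retained structure to test the overall harness effect. Random
    intercept standard deviations, Nakagawa marginal/conditional R² and
    fixed-effect tables come from the reported REML fit.
    """
    if len(frame) == 0:
        raise ValueError("empty model frame")
    for grouping in ("individual_id", "date"):
        if frame[grouping].nunique() < 2:
            warnings.warn(f"random grouping '{grouping}' has a single level", stacklevel=2)

    can_interact = spec.interaction and frame["harness"].nunique() > 1 and frame["species"].nunique() > 1

    lrt_inter = None
    retained = False
    if can_interact:
        full_ml = _fit_mixed(_fixed_formula(frame, interaction=True), frame, reml=False)
        red_ml = _fit_mixed(_fixed_formula(frame, interaction=False), frame, reml=False)
        lrt_inter = _lrt(full_ml, red_ml)
        retained = lrt_inter.p_value < alpha

    formula = _fixed_formula(frame, interaction=retained)
    reported = _fit_mixed(formula, frame, reml=True)

    lrt_harness = None
    if frame["harness"].nunique() > 1:
        with_h = _fit_mixed(formula, frame, reml=False)
        without_h = _fit_mixed(_fixed_formula(frame, interaction=False, harness=False),
                               frame, reml=False)
        lrt_harness = _lrt(with_h, without_h)

    fe_names = list(reported.fe_params.index)
    params = reported.params[fe_names]
    marginal, conditional = _nakagawa_r2(reported)
    vc_names = list(reported.model.exog_vc.names)
    random_sd = {name: float(np.sqrt(v)) for name, v in zip(vc_names, reported.vcomp)}

    if not reported.converged:
        warnings.warn(
            f"model {spec.name}: REML fit did not converge; variance components "
            f"{dict(zip(vc_names, np.round(reported.vcomp, 6)))}, scale {reported.scale:.6g}",
            stacklevel=2,
        )

    return ModelFit(
        spec=spec,
        params=params.rename(index=_clean_term),
        bse=reported.bse[fe_names].rename(index=_clean_term),
        pvalues=reported.pvalues[fe_names].rename(index=_clean_term),
        conf_int=reported.conf_int().loc[fe_names].rename(index=_clean_term),
        random_sd=random_sd,
        n_obs=len(frame),
        marginal_r2=marginal,
        conditional_r2=conditional,
        lrt_interaction=lrt_inter,
        lrt_harness=lrt_harness,
        interaction_retained=retained,
        converged=bool(reported.converged),
    )


def _clean_term(term: str) -> str:
    """Shorten patsy term names: C(harness, ...)[T.leg-loop] -> harness[leg-loop]."""
    out = term
    for factor in ("harness", "species"):
        marker = f"C({factor}, Treatment("
        while marker in out:
            start = out.index(marker)
            lb = out.index("[T.", start)
            rb = out.index("]", lb)
            level = out[lb + 3:rb]
            out = out[:start] + f"{factor}[{level}]" + out[rb + 1:]
    return out


def run_model_battery(segments: pd.DataFrame, specs=None) -> dict:
    """Prepare and fit every model of the battery; returns name -> ModelFit."""
    fits = {}
    for spec in specs or default_specs():
        frame = prepare_model_frame(segments, spec)
        fits[spec.name] = fit_lmm(frame, spec)
    return fits


def percent_change_from_log_coef(beta: float) -> float:
    """Percent change in the response implied by a log-scale coefficient.

    ``100 * (exp(beta) - 1)``: the multiplicative effect of a one-level
    contrast in a log-transformed model, expressed in percent.
    """
    return float(100.0 * np.expm1(beta))


def net_species_effect(beta_main: float, beta_interaction: float) -> float:
    """Species-specific contrast: main effect plus that species' interaction."""
    return float(beta_main + beta_interaction)


def glide_gain_backtransform(intercept: float, beta: float) -> float:
    """Response-scale gain implied by a coefficient of a sqrt-scale model.

    For a square-root-transformed glide ratio, the change in glide ratio at
    the contrast level relative to baseline is
    ``(intercept + beta)**2 - intercept**2`` — the extra metres of
    horizontal distance per metre of height drop.
    """
    return float((intercept + beta) ** 2 - intercept ** 2)


def summary_table(fit: ModelFit) -> str:
    """Human-readable coefficient table of one fitted model."""
    lines = [f"Model: {fit.spec.name}  (response: {fit.spec.response}, "
             f"transform: {fit.spec.transform}, phase: {fit.spec.phase})"]
    lines.append(f"{'term':<42}{'estimate':>10}{'(St.Err.)':>12}{'p':>11}")
    for term in fit.params.index:
        star = _stars(fit.pvalues[term])
        lines.append(f"{term:<42}{fit.params[term]:>10.3f}{fit.bse[term]:>12.3f}"
                     f"{fit.pvalues[term]:>11.3g}{star}")
    for name, sd in fit.random_sd.items():
        lines.append(f"random intercept SD ({name}): {sd:.3f}")
    lines.append(f"Observations: {fit.n_obs}")
    lines.append(f"Marginal R2: {fit.marginal_r2:.2f}   Conditional R2: {fit.conditional_r2:.2f}")
    if fit.lrt_interaction is not None:
        lines.append(f"LRT interaction: chi2={fit.lrt_interaction.chi2:.2f}, "
                     f"df={fit.lrt_interaction.df}, p={fit.lrt_interaction.p_value:.3g} "
                     f"({'retained' if fit.interaction_retained else 'excluded'})")
    if fit.lrt_harness is not None:
        lines.append(f"LRT harness: chi2={fit.lrt_harness.chi2:.2f}, "
                     f"df={fit.lrt_harness.df}, p={fit.lrt_harness.p_value:.3g}")
    return "\n".join(lines)


def _stars(p: float) -> str:
    if p < 0.001:
        return " ***"
    if p < 0.01:
        return " **"
    if p < 0.05:
        return " *"
    if p < 0.1:
        return " ."
    return ""
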