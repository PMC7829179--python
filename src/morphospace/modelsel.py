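"""Information-theoretic model comparison: AICc, Akaike weights,
summed-weight variable importance over the ΔAICc < 2 candidate set,
and Nakagawa–Schielzeth marginal/conditional R² for mixed models.

The numerical fitting of (mixed) models is delegated to statsmodels
behind a thin fitter contract that produces :class:`ModelSummary`
objects; everything above that layer — the comparison design — lives
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class ModelSummary:
    """Minimal fitted-model record for information-theoretic comparison."""

    model_id: str
    predictors: tuple[str, ...]
    loglik: float
    k: int  # number of estimated parameters
    n: int  # sample size
    var_fixed: float | None = None
    var_random: float | None = None
    var_resid: float | None = None

    @property
    def marginal_r2(self) -> float | None:
        if None in (self.var_fixed, self.var_random, self.var_resid):
            return None
        return nakagawa_r2(self.var_fixed, self.var_random, self.var_resid)[0]


@dataclass
class ImportanceTable:
    importance: dict[str, float]
    retained_models: list[str]
    retained_weights: dict[str, float]
    mean_marginal_r2: float | None
    delta_cut: float
    renormalized: bool


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

        AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized relative likelihoods exp(-Δi/2) / Σ exp(-Δj/2)."""
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def nakagawa_r2(var_fixed: float, var_random: float, var_resid: float):
    """Marginal and conditional R² of a mixed model.

    marginal = fixed / (fixed + random + residual);
    conditional = (fixed + random) / (fixed + random + residual).
    """
    if min(var_fixed, var_random, var_resid) < 0:
        raise ValueError("variance components must be nonnegative")
    total = var_fixed + var_random + var_resid
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random) / total


def variable_importance(
    models: list[ModelSummary], delta_cut: float = 2.0, renormalize: bool = True
) -> ImportanceTable:
    """Summed Akaike weights per predictor over the ΔAICc < cut set.

    Weights are computed over the full candidate set, the ΔAICc < cut
    models are retained (the best model always is), and by default the
    retained weights are renormalized to sum to 1 before summation.
    The mean marginal R² over retained models is attached when variance
    components are available.
    """
    if not models:
        raise ValueError("empty model set")
    a = np.array([aicc(m.loglik, m.k, m.n) for m in models])
    delta = a - a.min()
    w = akaike_weights(a)
    keep = delta < delta_cut
    wk = w[keep]
    if renormalize:
        wk = wk / wk.sum()
    retained = [m for m, k_ in zip(models, keep) if k_]
    predictors = sorted({p for m in retained for p in m.predictors})
    imp = {
        p: float(sum(wi for m, wi in zip(retained, wk) if p in m.predictors))
        for p in predictors
    }
    r2s = [m.marginal_r2 for m in retained if m.marginal_r2 is not None]
    return ImportanceTable(
        importance=imp,
        retained_models=[m.model_id for m in retained],
        retained_weights={m.model_id: float(wi) for m, wi in zip(retained, wk)},
        mean_marginal_r2=float(np.mean(r2s)) if r2s else None,
        delta_cut=delta_cut,
        renormalized=renormalize,
    )


def all_subsets(predictors: list[str], max_models: int = 64) -> list[tuple[str, ...]]:
    """Every predictor subset (dredge-style), including the null model."""
    subs = [
        combo
        for r in range(len(predictors) + 1)
        for combo in combinations(predictors, r)
    ]
    if len(subs) > max_models:
        raise ValueError(f"{len(subs)} candidate models exceed cap {max_models}")
    return subs


def fit_lmm_summaries(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    group: str,
    max_models: int = 64,
) -> list[ModelSummary]:
    """Fit random-intercept linear mixed models for every predictor
    subset and summarize them for AICc comparison.

    Fixed-effect variance for the Nakagawa R² is the variance of the
    fixed-effect linear predictor, following the standard definition.
    Fitting uses maximum likelihood (not REML) so log-likelihoods are
    comparable across fixed-effect structures.
    """
    import statsmodels.formula.api as smf

    out: list[ModelSummary] = []
    for combo in all_subsets(predictors, max_models):
        rhs = " + ".join(combo) if combo else "1"
        formula = f"{response} ~ {rhs}"
        fit = smf.mixedlm(formula, data, groups=data[group]).fit(reml=False)
        fe_pred = fit.predict(data)  # fixed-effects-only linear predictor
        var_f = float(np.var(fe_pred, ddof=0))
        var_r = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
        var_e = float(fit.scale)
        k = len(fit.fe_params) + 2  # fixed effects + RE variance + residual
        out.append(
            ModelSummary(
                model_id=rhs, predictors=combo, loglik=float(fit.llf), k=k,
                n=len(data), var_fixed=var_f, var_random=var_r, var_resid=var_e,
            )
        )
    return out


def packing_richness_logistic(packing_pct, richness, delta_s=None):
    """Binomial contrast of packing proportion against log richness.

    Models the per-pair packing fraction (packing / ΔS) as a logistic
    function of log species richness; returns the fitted GLM result and
    the likelihood-ratio χ²(1) statistic against the intercept-only
    model with its p-value.
    """
    import statsmodels.api as sm
    from scipy import stats as sps

    p = np.clip(np.asarray(packing_pct, dtype=float) / 100.0, 0.0, 1.0)
    x = np.log(np.asarray(richness, dtype=float))
    exog = sm.add_constant(x)
    w = None if delta_s is None else np.asarray(delta_s, dtype=float)
    full = sm.GLM(p, exog, family=sm.families.Binomial(), var_weights=w).fit()
    null = sm.GLM(p, np.ones_like(x), family=sm.families.Binomial(), var_weights=w).fit()
    chi2 = 2.0 * (full.llf - null.llf)
    pval = float(sps.chi2.sf(chi2, df=1))
    return full, float(chi2), pval
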