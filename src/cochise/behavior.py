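"""Playback-experiment aggression scoring and treatment comparison.

Territorial males are exposed to broadcast song from four treatments (Local,
Distant same-desert, Across-Barrier, and a heterospecific Control), and five
aggression measures are recorded per 3-minute period: flybys, alarm-call
presence, songs inside the site ("close"), songs outside ("far"), and the
distance-to-speaker time series in field-estimated bins.  The five measures
for the Response period (Playback and Post-Playback pooled) are reduced to a
single composite by PCA on the correlation matrix; the same loadings applied
to Pre-Playback data give a pre-treatment aggression covariate.  Treatment
effects on the composite are assessed with Gaussian linear mixed models
(random intercepts for site and stimulus set, full maximum likelihood)
compared by small-sample-corrected AIC, with Wald chi-square tests and all
pairwise treatment contrasts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TREATMENTS = ("LOCAL", "DISTANT", "ACROSS", "CONTROL")
PERIODS = ("PRE", "PLAYBACK", "POST")

#: Distance bins as estimated in the field, and the scalar (midpoint) each
#: maps to when the series is reduced to a mean distance.  The open-ended
#: ">24" bin has no midpoint; its code defaults to 28 m and is configurable.
DISTANCE_BINS = ("0-1", "1-2", "2-4", "4-8", "8-16", "16-24", ">24")
BIN_MIDPOINTS = {
    "0-1": 0.5,
    "1-2": 1.5,
    "2-4": 3.0,
    "4-8": 6.0,
    "8-16": 12.0,
    "16-24": 20.0,
}
FAR_BIN_CODE = 28.0

MEASURES = ("flybys", "calls", "close_songs", "far_songs", "mean_distance")


def bin_to_meters(label: str, far_code: float = FAR_BIN_CODE) -> float:
    if label == ">24":
        return far_code
    if label not in BIN_MIDPOINTS:
        raise ValueError(f"unknown distance bin {label!r}")
    return BIN_MIDPOINTS[label]


def mean_distance(series: str | list[str], far_code: float = FAR_BIN_CODE) -> float:
    """Mean of the bin midpoints over a distance series.

    ``series`` is either a semicolon-joined string of bin labels (the trial
    table encoding) or a list of labels.
    """
    labels = series.split(";") if isinstance(series, str) else list(series)
    labels = [l for l in labels if l]
    if not labels:
        raise ValueError("empty distance series")
    return float(np.mean([bin_to_meters(l, far_code) for l in labels]))


def territory_radius(area_hectares: float) -> float:
    """Radius (m, to 0.1) of a circular territory of the given area in hectares."""
    if area_hectares <= 0:
        raise ValueError("territory area must be positive")
    return round(math.sqrt(area_hectares * 10_000.0 / math.pi), 1)


def pool_response(trials: pd.DataFrame) -> pd.DataFrame:
    """Pool Playback and Post-Playback rows into one RESPONSE row per trial.

    Counts are summed, call presence is OR-ed, and the distance series are
    concatenated; the Pre-Playback rows pass through unchanged.
    """
    pre = trials[trials["period"] == "PRE"].copy()
    resp = trials[trials["period"].isin(("PLAYBACK", "POST"))]
    keys = ["site_id", "desert", "treatment", "stimulus_set_id"]
    pooled = (
        resp.groupby(keys, as_index=False)
        .agg(
            flybys=("flybys", "sum"),
            calls_present=("calls_present", "max"),
            close_songs=("close_songs", "sum"),
            far_songs=("far_songs", "sum"),
            distance_series=("distance_series", lambda s: ";".join(x for x in s if isinstance(x, str))),
        )
        .assign(period="RESPONSE")
    )
    return pd.concat([pre, pooled], ignore_index=True)


def reduce_measures(trials: pd.DataFrame, far_code: float = FAR_BIN_CODE) -> pd.DataFrame:
    """Reduce each trial-period row to the 5-vector entering the PCA.

    Returns the grouping keys plus (flybys, calls, close_songs, far_songs,
    mean_distance), with calls coded 0/1 and the distance series collapsed
    to its bin-midpoint mean.  The closest distance bin is retained for
    reporting.
    """
    out = trials.copy()
    out["calls"] = out["calls_present"].astype(float).clip(0, 1)
    out["mean_distance"] = out["distance_series"].map(lambda s: mean_distance(s, far_code))
    out["closest_distance"] = out["distance_series"].map(
        lambda s: min(bin_to_meters(l, far_code) for l in str(s).split(";") if l)
    )
    keys = ["site_id", "desert", "treatment", "stimulus_set_id", "period"]
    return out[keys + list(MEASURES) + ["closest_distance"]]


@dataclass
class AggressionScore:
    """First-principal-component composite aggression.

    ``loadings`` are the unit-norm PC1 loadings over ``measures``; ``pc1``
    scores the Response-period rows and ``pre_score`` projects the
    Pre-Playback rows standardized with the Response means and scales.  The
    raw PC orientation is preserved; ``orientation_sign`` is +1 when higher
    pc1 means more aggression (pc1 negatively correlated with mean
    distance), -1 otherwise.
    """

    loadings: np.ndarray
    measures: tuple[str, ...]
    pc1: np.ndarray
    pre_score: np.ndarray
    var_explained: float
    orientation_sign: int
    center: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)


def aggression_pca(
    response: pd.DataFrame, pre: pd.DataFrame, measures: tuple[str, ...] = MEASURES
) -> AggressionScore:
    """PCA of the Response-period measures; project Pre-Playback a posteriori.

    The PCA is computed on the correlation matrix (measures mix counts,
    flags and meters).  Zero-variance measures are dropped with a warning
    and re-padded with zero loadings.
    """
    X = response[list(measures)].to_numpy(float)
    if X.shape[0] < 6:
        raise ValueError("need at least 6 response rows for a stable PCA")
    P = pre[list(measures)].to_numpy(float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    degenerate = scale <= 0
    if degenerate.any():
        dropped = [m for m, d in zip(measures, degenerate) if d]
        warnings.warn(f"zero-variance measures dropped from PCA: {dropped}")
    keep = ~degenerate
    Z = (X[:, keep] - center[keep]) / scale[keep]
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    lead = eigvec[:, -1]
    loadings = np.zeros(len(measures))
    loadings[keep] = lead
    pc1 = Z @ lead
    Zp = (P[:, keep] - center[keep]) / scale[keep]
    pre_score = Zp @ lead
    dist_idx = list(measures).index("mean_distance")
    r = np.corrcoef(pc1, -X[:, dist_idx])[0, 1]
    return AggressionScore(
        loadings=loadings,
        measures=tuple(measures),
        pc1=pc1,
        pre_score=pre_score,
        var_explained=float(eigval[-1] / keep.sum()),
        orientation_sign=int(np.sign(r)) if not np.isnan(r) else 1,
        center=center,
        scale=scale,
    )


def score_trials(trials: pd.DataFrame, far_code: float = FAR_BIN_CODE) -> pd.DataFrame:
    """Full scoring pipeline from a raw trial table to per-trial PC1 scores.

    Sites with no detected male (missing measures) are excluded, Playback
    and Post-Playback are pooled into the Response period, the PCA is run
    on Response vectors, and Pre-Playback vectors are projected with the
    Response loadings.  Returns one row per trial with pc1, pre_score and
    the mixed-model covariates.
    """
    detected = trials.dropna(subset=["flybys", "distance_series"])
    n_excluded = trials["site_id"].nunique() - detected["site_id"].nunique()
    if n_excluded:
        logger.info("excluded %d sites without detections", n_excluded)
    reduced = reduce_measures(pool_response(detected), far_code)
    keys = ["site_id", "desert", "treatment", "stimulus_set_id"]
    resp = reduced[reduced["period"] == "RESPONSE"].sort_values(keys).reset_index(drop=True)
    pre = reduced[reduced["period"] == "PRE"].sort_values(keys).reset_index(drop=True)
    if len(resp) != len(pre) or not resp[keys].equals(pre[keys]):
        raise ValueError("response and pre-playback rows do not pair one-to-one")
    score = aggression_pca(resp, pre)
    out = resp[keys].copy()
    out["pc1"] = score.pc1
    out["pre_score"] = score.pre_score
    out.attrs["aggression_score"] = score
    return out


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class BehaviorComparison:
    """Null-vs-full mixed-model comparison for the aggression composite.

    The null model is pc1 ~ pre_score with random intercepts for stimulus
    set and site; the full model adds the Treatment fixed effect.  Both are
    fitted by full maximum likelihood so the AICc comparison across fixed
    effects is valid.  ``delta_aicc`` = aicc_null - aicc_full (positive
    favors the full model).
    """

    aicc_null: float
    aicc_full: float
    delta_aicc: float
    loglik_null: float
    loglik_full: float
    k_null: int
    k_full: int
    n: int
    wald: pd.DataFrame
    contrasts: pd.DataFrame
    variance_components: dict
    treatment_effects: dict


def _fit_mixed(formula: str, data: pd.DataFrame, label: str):
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = smf.mixedlm(
        formula,
        data,
        groups=np.ones(len(data)),
        vc_formula={"site": "0 + C(site_id)", "stimulus_set": "0 + C(stimulus_set_id)"},
        re_formula="0",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=400)
        except Exception as exc:
            raise RuntimeError(f"mixed model {label!r} failed to converge: {exc}") from exc
    if not np.isfinite(res.llf):
        raise RuntimeError(f"mixed model {label!r} failed to converge")
    return res


def compare_models(scores: pd.DataFrame) -> BehaviorComparison:
    """Compare the null and full aggression mixed models under AICc.

    Requires >=2 sites, >=2 stimulus sets and all four treatments.  Wald
    chi-square tests cover Treatment (3 df) and the pre-treatment
    aggression slope (1 df); all six pairwise treatment contrasts are
    reported without multiplicity correction.
    """
    for col, minimum in (("site_id", 2), ("stimulus_set_id", 2)):
        if scores[col].nunique() < minimum:
            raise ValueError(f"need at least {minimum} distinct {col}")
    present = set(scores["treatment"])
    if not set(TREATMENTS) <= present:
        raise ValueError(f"missing treatments: {sorted(set(TREATMENTS) - present)}")
    data = scores.copy()
    data["treatment"] = pd.Categorical(
        data["treatment"], categories=["CONTROL", "ACROSS", "DISTANT", "LOCAL"]
    )
    n = len(data)
    full = _fit_mixed("pc1 ~ treatment + pre_score", data, "full")
    null = _fit_mixed("pc1 ~ pre_score", data, "null")

    # fixed effects + two variance components + residual variance
    k_full, k_null = 5 + 3, 2 + 3
    a_full = aicc(full.llf, k_full, n)
    a_null = aicc(null.llf, k_null, n)

    names = list(full.params.index)
    treat_terms = [nm for nm in names if nm.startswith("treatment[")]
    cov = full.cov_params()
    beta = full.params

    def wald_joint(terms: list[str]) -> tuple[float, int, float]:
        idx = [names.index(t) for t in terms]
        b = beta.iloc[idx].to_numpy()
        V = cov.iloc[idx, idx].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        return stat, df, float(stats.chi2.sf(stat, df))

    w_treat = wald_joint(treat_terms)
    w_pre = wald_joint(["pre_score"])
    wald = pd.DataFrame(
        [
            {"effect": "treatment", "statistic": w_treat[0], "df": w_treat[1], "p": w_treat[2]},
            {"effect": "pre_score", "statistic": w_pre[0], "df": w_pre[1], "p": w_pre[2]},
        ]
    )

    # treatment effects relative to CONTROL (reference level absorbed in the
    # intercept), then all pairwise contrasts on the common scale
    effect = {"CONTROL": 0.0}
    evar = {"CONTROL": 0.0}
    for t in ("ACROSS", "DISTANT", "LOCAL"):
        term = f"treatment[T.{t}]"
        effect[t] = float(beta[term])
        evar[t] = float(cov.loc[term, term])
    rows = []
    for i, t1 in enumerate(TREATMENTS):
        for t2 in TREATMENTS[i + 1 :]:
            d = effect[t1] - effect[t2]
            if t1 == "CONTROL" or t2 == "CONTROL":
                other = t2 if t1 == "CONTROL" else t1
                se = math.sqrt(evar[other])
            else:
                a, b = f"treatment[T.{t1}]", f"treatment[T.{t2}]"
                se = math.sqrt(
                    max(evar[t1] + evar[t2] - 2 * float(cov.loc[a, b]), 0.0)
                )
            z = d / se if se > 0 else np.nan
            rows.append(
                {
                    "pair": f"{t1}-{t2}",
                    "estimate": d,
                    "se": se,
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                }
            )
    contrasts = pd.DataFrame(rows)
    vc_names = list(full.model.exog_vc.names)
    vc = {name: float(v) for name, v in zip(vc_names, full.vcomp)}
    vc["residual"] = float(full.scale)
    return BehaviorComparison(
        aicc_null=a_null,
        aicc_full=a_full,
        delta_aicc=a_null - a_full,
        loglik_null=float(null.llf),
        loglik_full=float(full.llf),
        k_null=k_null,
        k_full=k_full,
        n=n,
        wald=wald,
        contrasts=contrasts,
        variance_components=vc,
        treatment_effects=effect,
    )
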