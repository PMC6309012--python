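"""Composite-likelihood demographic inference on joint SFS data.

The observed unfolded joint SFS is treated as multinomial over its unmasked
entries, with cell probabilities given by the normalized Monte-Carlo
expected SFS of a candidate model (the standard SFS composite likelihood,
sites assumed independent).  Maximization uses prior sampling followed by
coordinate-wise log-scale hill climbing with common random numbers, model
choice uses AIC with ΔAIC support thresholds of 2 (significant) and 10
(highly significant), and uncertainty comes from a parametric bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import coalescent as co
from .sfs import JointSFS

logger = logging.getLogger(__name__)

#: Weight of the uniform mixture component that keeps cell probabilities
#: strictly positive.  A Monte-Carlo expected SFS leaves genuinely small
#: cells empty at finite replicate counts; a hard floor would then penalize
#: candidate parameters by an amount that depends on how widely they spread
#: their mass, which systematically distorts the fit.  Mixing in a small
#: uniform mass instead gives every unresolved cell the same finite
#: probability under every candidate.
SMOOTHING_DEFAULT = 1e-3

DELTA_AIC_SIGNIFICANT = 2.0
DELTA_AIC_HIGHLY_SIGNIFICANT = 10.0


def composite_loglik(
    obs: JointSFS, expected: JointSFS, smoothing: float = SMOOTHING_DEFAULT
) -> float:
    """Multinomial composite log-likelihood of ``obs`` under ``expected``.

    ``expected`` is normalized over unmasked entries (so any overall scale,
    e.g. the mutation rate, cancels) and mixed with a uniform distribution
    of weight ``smoothing`` so zero cells stay finite.
    """
    if obs.counts.shape != expected.counts.shape:
        raise ValueError("observed and expected SFS shapes differ")
    if not np.array_equal(obs.mask, expected.mask):
        raise ValueError("observed and expected SFS masks differ")
    keep = ~obs.mask
    e = expected.counts[keep]
    total = e.sum()
    if total <= 0:
        raise ValueError("expected SFS has no unmasked mass")
    p = (1.0 - smoothing) * (e / total) + smoothing / e.size
    o = obs.counts[keep]
    return float((o[o > 0] * np.log(p[o > 0])).sum())


@dataclass
class FitSettings:
    """Search-effort knobs for :func:`fit_model`.

    ``n_prior_draws`` prior-sampled starting points (screened at a third of
    ``reps_per_eval``), of which the best ``n_starts`` seed downhill-simplex
    searches in log-parameter space at ``reps_per_eval`` genealogies per
    likelihood evaluation (``n_refine`` evaluations each); the leader is
    then polished and finally re-scored at ``final_factor`` times as many
    replicates.
    """

    n_prior_draws: int = 300
    n_refine: int = 100
    reps_per_eval: int = 2000
    final_factor: int = 6
    n_starts: int = 4
    polish_evals: int = 600
    start_separation: float = 1.5  # min log-distance between simplex starts
    final_reps: int | None = None  # replicates for the final score (default: reps_per_eval * final_factor)


@dataclass
class FitResult:
    """Maximum composite-likelihood fit of one model."""

    model_id: str
    mle: co.ParameterVector
    mle_draw: dict  # prior-unit values of the free parameters
    loglik: float
    k: int
    aic: float
    n_evaluations: int
    seed: int


# soft upper bounds may be exceeded during refinement, but not without limit;
# T_D additionally must stay below the fixed outgroup split
_SOFT_UPPER_FACTOR = 10.0
_T_D_CEILING = 0.95 * co.T_ANCESTRAL_YEARS


def _clamp_draw(model: co.ModelSpec, draw: dict, prior_spec: dict) -> dict:
    out = dict(draw)
    for name, value in out.items():
        spec = prior_spec[name]
        value = max(value, spec.lower)
        cap = spec.upper * _SOFT_UPPER_FACTOR if spec.soft_upper else spec.upper
        out[name] = min(value, cap)
    if "T_D" in out:
        out["T_D"] = min(out["T_D"], _T_D_CEILING)
    if "T_SC" in out:
        out["T_SC"] = min(out["T_SC"], out["T_D"])
    return out


def fit_model(
    obs: JointSFS,
    model: co.ModelSpec,
    priors: co.PriorSet,
    settings: FitSettings,
    seed: int,
    extra_starts: list[dict] | None = None,
) -> FitResult:
    """Staged maximum composite-likelihood search.

    Prior draws are screened at reduced replicates; the best-scoring,
    mutually distant draws seed downhill-simplex runs in log-parameter
    space; the leader is polished with a long high-replicate simplex run,
    which is what pins the nearly flat ridge directions of this surface.
    ``extra_starts`` adds warm starts (e.g. a nested model's optimum;
    unspecified free parameters are filled with prior-floor values).  All
    evaluations in a stage reuse one simulation seed (common random
    numbers), so Monte-Carlo noise is a fixed landscape distortion rather
    than per-evaluation jitter; the returned log-likelihood is re-evaluated
    at elevated replicates with a seed shared across models fitted with
    the same user seed, keeping AIC comparisons between models on common
    ground.
    """
    if settings.n_prior_draws < 1 or settings.reps_per_eval < 1:
        raise ValueError("settings must be positive")
    config = co.SampleConfig(*obs.sample_sizes)
    prior_spec = priors.for_model(model)
    rng = np.random.default_rng(seed)
    eval_seed = (31 * seed + 17) & 0x7FFFFFFF
    final_seed = (31 * seed + 1009) & 0x7FFFFFFF
    n_eval = 0

    def score(draw: dict, reps: int, sim_seed: int) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            params = co.draw_to_params(model, draw, priors.migration_unit)
        except ValueError:
            return -math.inf
        exp = co.expected_sfs(model, params, config, reps, sim_seed)
        return composite_loglik(obs, exp)

    names = model.free_parameters
    floor = 1e-30  # keeps log-space finite for T_SC draws near zero

    def to_x(draw: dict) -> np.ndarray:
        return np.array([math.log(max(draw[n], floor)) for n in names])

    screen_reps = max(settings.reps_per_eval // 4, 200)
    scored = []
    for _ in range(settings.n_prior_draws):
        draw = co.draw_prior_space(model, priors, rng)
        scored.append((score(draw, screen_reps, eval_seed), draw))
    scored.sort(key=lambda t: t[0], reverse=True)

    # greedy diverse multi-start: the composite-likelihood surface has
    # well-separated secondary modes (e.g. migration trading off against
    # divergence time), so the starts must cover distinct basins rather
    # than resample the single best-scoring neighborhood
    starts: list[dict] = []
    for extra in extra_starts or []:
        # warm starts (e.g. a nested model's optimum) are filled out with
        # prior-floor values for any free parameter they do not set
        draw = dict(extra)
        for name in model.free_parameters:
            draw.setdefault(name, max(prior_spec[name].lower, 1e-12))
        starts.append(_clamp_draw(model, {n: draw[n] for n in model.free_parameters}, prior_spec))
    n_target = max(1, settings.n_starts) + len(starts)
    for _, draw in scored:
        if len(starts) >= n_target:
            break
        x = to_x(draw)
        if all(
            np.linalg.norm(x - to_x(s)) >= settings.start_separation for s in starts
        ):
            starts.append(draw)
    if not starts:
        starts = [scored[0][1]]

    def from_x(x: np.ndarray) -> dict:
        draw = {n: math.exp(v) for n, v in zip(names, x)}
        return _clamp_draw(model, draw, prior_spec)

    def neg(x: np.ndarray, reps: int, sim_seed: int) -> float:
        return -score(from_x(x), reps, sim_seed)

    def simplex(start: dict, maxfev: int, reps: int, sim_seed: int):
        res = minimize(
            neg,
            to_x(start),
            args=(reps, sim_seed),
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 5e-4, "fatol": 0.1, "adaptive": True},
        )
        return from_x(res.x), -res.fun

    high_reps = settings.reps_per_eval * settings.final_factor
    candidates = [
        simplex(start, settings.n_refine, settings.reps_per_eval, eval_seed)
        for start in starts
    ]
    # re-score endpoints at high replicates before choosing: the winner by
    # low-replicate score is not always the winner on the sharper surface
    rescored = [(score(d, high_reps, eval_seed), d) for d, _ in candidates]
    best_ll, best_draw = max(rescored, key=lambda t: t[0])
    if settings.polish_evals > 0:
        # high-replicate polish sharpens the flat directions of the surface
        best_draw, _ = simplex(best_draw, settings.polish_evals, high_reps, eval_seed)

    final_reps = settings.final_reps or settings.reps_per_eval * settings.final_factor
    final_ll = score(best_draw, final_reps, final_seed)
    for name, spec in prior_spec.items():
        if spec.dist == "log-uniform" and best_draw[name] <= spec.lower * 1.01:
            logger.warning(
                "fit of %s: %s sits on its hard lower bound %g",
                model.model_id,
                name,
                spec.lower,
            )
    mle = co.draw_to_params(model, best_draw, priors.migration_unit)
    aic = 2 * model.k - 2 * final_ll
    return FitResult(
        model.model_id, mle, dict(best_draw), final_ll, model.k, aic, n_eval, seed
    )


def select_model(fits: list[FitResult]) -> pd.DataFrame:
    """ΔAIC comparison table across fitted models.

    Labels: the best model, then per ΔAIC thresholds not_significant (<2),
    significant (>=2), highly_significant (>=10).
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    ids = [f.model_id for f in fits]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model_id among fits")
    aics = np.array([f.aic for f in fits])
    best = int(np.argmin(aics))
    deltas = aics - aics[best]
    labels = []
    for i, d in enumerate(deltas):
        if i == best:
            labels.append("best")
        elif d < DELTA_AIC_SIGNIFICANT:
            labels.append("not_significant")
        elif d < DELTA_AIC_HIGHLY_SIGNIFICANT:
            labels.append("significant")
        else:
            labels.append("highly_significant")
    return pd.DataFrame(
        {
            "model_id": ids,
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": aics,
            "delta_aic": deltas,
            "support": labels,
        }
    )


@dataclass
class BootstrapSummary:
    """Parametric-bootstrap means and 95% percentile intervals per parameter."""

    table: pd.DataFrame  # columns: parameter, mean, ci_low, ci_high
    B: int
    n_failed: int
    replicates: pd.DataFrame = field(repr=False, default=None)


def _free_param_value(model: co.ModelSpec, mle: co.ParameterVector, name: str) -> float:
    return float(getattr(mle, "m_S" if name == "m" else name))


def parametric_bootstrap(
    model: co.ModelSpec,
    mle: co.ParameterVector,
    sample_config: co.SampleConfig,
    B: int,
    n_snps: int,
    seed: int,
    priors: co.PriorSet,
    settings: FitSettings,
) -> BootstrapSummary:
    """Simulate B observed SFS under ``mle``, refit, summarize percentiles.

    Replicates whose refit raises are recorded and excluded; more than 20%
    failures is an error.  Parameters are reported on the canonical scale
    (haploid sizes, years, backward per-lineage migration rates).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rows = []
    n_failed = 0
    for b in range(B):
        rep_seed = (seed + 7907 * (b + 1)) & 0x7FFFFFFF
        try:
            obs_b = co.sample_sfs(model, mle, sample_config, n_snps, rep_seed)
            fit_b = fit_model(obs_b, model, priors, settings, rep_seed)
            rows.append(
                {name: _free_param_value(model, fit_b.mle, name) for name in model.free_parameters}
            )
        except Exception as exc:  # refit failures are data, not fatal (up to a point)
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > 0.2 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    reps = pd.DataFrame(rows)
    # order-statistic percentiles: with B replicates the 2.5th/97.5th fall on
    # actual replicate values (min/max when B = 2)
    table = pd.DataFrame(
        {
            "parameter": reps.columns,
            "mean": reps.mean().to_numpy(),
            "ci_low": np.percentile(reps, 2.5, axis=0, method="closest_observation"),
            "ci_high": np.percentile(reps, 97.5, axis=0, method="closest_observation"),
        }
    )
    return BootstrapSummary(table, B, n_failed, replicates=reps)
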