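"""Maximum-likelihood estimation and fitted-table generation.

Quasi-Newton maximization of the panel likelihood with multi-start jitter,
covariance from the numerically differenced observed information, hazard
ratio reporting, and the jump/sojourn and interval-probability tables with
parametric-bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from . import reference
from .markov import (
    IntensityMatrix,
    SojournTimes,
    TRANSITIONS,
    TransitionTable,
    expm_stack,
    jump_chain_probabilities,
    mean_sojourn_times,
)
from .likelihood import (
    CovariateModel,
    ParamLayout,
    extract_pairs,
    gradient_from_params,
    loglik_from_params,
    pack_params,
    unpack_params,
)
from .panel import PanelDataset, observed_transition_table

__all__ = [
    "FitConfig",
    "FitResult",
    "HazardRatioEntry",
    "HazardRatioReport",
    "IntervalProbabilityTable",
    "fit_mle",
    "hazard_ratio_report",
    "fitted_summary_table",
    "interval_probability_table",
]

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054  # 97.5% normal quantile


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_mle`."""

    n_starts: int = 3
    jitter_sd: float = 0.3
    seed: int = 0
    gtol: float = 1e-5
    maxiter: int = 500
    rate_floor: float = 1e-4  # per week, floor for count-based initial rates
    hessian_step: float = 1e-4


@dataclass(frozen=True)
class FitResult:
    """MLE output: estimates, covariance, log-likelihood, diagnostics."""

    model: CovariateModel
    loglik: float
    covariance: np.ndarray | None
    converged: bool
    n_iter: int
    n_subjects: int
    n_pairs: int
    trace: tuple[dict, ...] = ()
    flags: tuple[str, ...] = ()
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def params(self) -> np.ndarray:
        return pack_params(self.model)

    @property
    def param_names(self) -> list[str]:
        return self._layout().names()

    def _layout(self) -> ParamLayout:
        return ParamLayout(
            allowed=self.model.allowed,
            covariates=self.model.covariates,
            centering=self.model.centering,
        )

    def standard_errors(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("covariance unavailable (singular information or failed fit)")
        return np.sqrt(np.diag(self.covariance))

    def to_json_dict(self) -> dict:
        return {
            "param_names": self.param_names,
            "params": self.params.tolist(),
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_subjects": self.n_subjects,
            "n_pairs": self.n_pairs,
            "covariates": list(self.model.covariates),
            "centering": np.asarray(self.model.centering).tolist(),
            "allowed_transitions": [list(TRANSITIONS[k]) for k in self.model.allowed],
            "flags": list(self.flags),
            "seed": self.config.seed,
            "baseline_q": self.model.baseline_intensity().q.tolist(),
            "trace": list(self.trace),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), indent=2, **kwargs)


def _initial_log_rates(
    data: PanelDataset, allowed: Sequence[int], floor: float
) -> np.ndarray:
    """Crude count-based starting rates: n_ij / (n_i. * mean dt), floored."""
    counts = observed_transition_table(data).values
    row_tot = counts.sum(axis=1)
    dts = [dt for _, _, _, dt in data.pairs()]
    mean_dt = float(np.mean(dts)) if dts else 1.0
    rates = []
    for k in allowed:
        i, j = TRANSITIONS[k]
        denom = max(row_tot[i], 1.0) * mean_dt
        rates.append(max(counts[i, j] / denom, floor))
    return np.log(np.array(rates))


def _safe_gradient(x, layout, pairs):
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            g = gradient_from_params(x, layout, pairs)
    except (ValueError, FloatingPointError):
        return np.full(len(x), np.nan)
    return g


def _numeric_hessian(x, layout, pairs, step):
    """Central difference of the complex-step gradient."""
    n = len(x)
    hess = np.zeros((n, n))
    for k in range(n):
        h = step * max(1.0, abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        gp = _safe_gradient(xp, layout, pairs)
        gm = _safe_gradient(xm, layout, pairs)
        hess[:, k] = (gp - gm) / (2 * h)
    return 0.5 * (hess + hess.T)


def fit_mle(
    data: PanelDataset,
    covariates: Sequence[str] = (),
    allowed: Sequence[int] | None = None,
    config: FitConfig | None = None,
    fixed: Mapping[int, float] | None = None,
) -> FitResult:
    """Maximize the panel likelihood over rates (and betas if covariates given).

    Parameters
    ----------
    data:
        Validated panel dataset.
    covariates:
        Covariate names to model with proportional intensities (centered at
        their sample means; hazard ratios are per raw unit).
    allowed:
        Indices into :data:`~panelmarkov.markov.TRANSITIONS` of the free
        transitions; defaults to all six. Disallowed rates are fixed at 0.
    fixed:
        Optional ``{param index: value}`` constraints in packed order (used
        mainly for profile/oracle checks).
    """
    config = config or FitConfig()
    covariates = tuple(covariates)
    allowed = tuple(allowed) if allowed is not None else tuple(range(len(TRANSITIONS)))

    flags = []
    counts = observed_transition_table(data).values
    for k in allowed:
        i, j = TRANSITIONS[k]
        if counts[i, j] == 0:
            flags.append(f"no observed support for transition {i + 1}->{j + 1}")

    centering = (
        data.covariate_means(covariates) if covariates else np.zeros(0)
    )
    layout = ParamLayout(allowed=allowed, covariates=covariates, centering=centering)
    pairs = extract_pairs(data, layout)
    if pairs.n_pairs == 0:
        raise ValueError("dataset contains no consecutive-visit pairs")

    x0 = np.concatenate(
        [_initial_log_rates(data, allowed, config.rate_floor), np.zeros(len(allowed) * len(covariates))]
    )

    fixed = dict(fixed or {})
    free = np.array([k for k in range(layout.n_params) if k not in fixed], dtype=int)

    def embed(xf):
        x = np.empty(layout.n_params)
        x[free] = xf
        for k, v in fixed.items():
            x[k] = v
        return x

    # overflow in exp() during aggressive line-search steps is treated as an
    # effectively -inf likelihood so the optimizer backs off
    def nll(xf):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                v = -float(np.real(loglik_from_params(embed(xf), layout, pairs)))
        except (ValueError, FloatingPointError):
            return 1e300
        return v if np.isfinite(v) else 1e300

    def njac(xf):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                g = -gradient_from_params(embed(xf), layout, pairs)[free]
        except (ValueError, FloatingPointError):
            return np.zeros(free.size)
        return np.where(np.isfinite(g), g, 0.0)

    rng = np.random.default_rng(config.seed)
    starts = [x0[free]]
    for _ in range(config.n_starts - 1):
        starts.append(x0[free] + rng.normal(0.0, config.jitter_sd, size=free.size))

    # log rates are boxed well past any data-supported magnitude; a lower
    # bound keeps boundary MLEs (rate -> 0) from stalling the line search
    # betas are boxed too: when a rate sits at ~0 the likelihood is flat in
    # its betas, and an unbounded drift there overflows exp() elsewhere
    n_rates_free = int(np.sum(free < len(allowed)))
    box_lo = np.r_[np.full(n_rates_free, -15.0), np.full(free.size - n_rates_free, -30.0)]
    box_hi = np.r_[np.full(n_rates_free, 5.0), np.full(free.size - n_rates_free, 30.0)]
    bounds = list(zip(box_lo, box_hi))

    best = None
    trace = []
    for s, start in enumerate(starts):
        res = scipy.optimize.minimize(
            nll,
            start,
            jac=njac,
            method="BFGS",
            options={"gtol": config.gtol, "maxiter": config.maxiter},
        )
        # polish inside the box: rescues boundary MLEs (a rate -> 0) where
        # the unbounded line search stalls with "precision loss"
        interior = np.all(res.x > box_lo + 0.5) and np.all(res.x < box_hi - 0.5)
        if not (res.success and interior):
            res2 = scipy.optimize.minimize(
                nll,
                np.clip(res.x, box_lo, box_hi),
                jac=njac,
                method="L-BFGS-B",
                bounds=bounds,
                options={"gtol": config.gtol, "maxiter": config.maxiter},
            )
            if res2.fun <= res.fun or not res.success:
                res2.nit += res.nit
                res = res2
        trace.append(
            {"start": s, "fun": float(res.fun), "nit": int(res.nit), "status": int(res.status),
             "success": bool(res.success), "message": str(res.message)}
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res

    x_hat = embed(best.x)
    grad_norm = float(np.max(np.abs(njac(best.x)))) if free.size else 0.0
    converged = bool(best.success or grad_norm < 1e-3 * max(1.0, abs(best.fun)))
    if not converged:
        flags.append(f"optimizer did not converge (grad max {grad_norm:.3g})")
        logger.warning("fit did not converge: %s", best.message)

    covariance = None
    if converged and free.size:
        hess = _numeric_hessian(x_hat, layout, pairs, config.hessian_step)[np.ix_(free, free)]
        info = -hess  # observed information of the free parameters
        if not np.all(np.isfinite(info)):
            # a non-finite row means the curvature is unmeasurable there
            # (typically a rate at its lower bound); drop those directions
            bad_rows = ~np.isfinite(info).all(axis=1)
            info = info.copy()
            info[bad_rows, :] = 0.0
            info[:, bad_rows] = 0.0
        cov_free = None
        try:
            cov_free = np.linalg.inv(info)
            eigmin = float(np.linalg.eigvalsh(cov_free).min())
            if not np.all(np.isfinite(cov_free)) or eigmin < -1e-8 * abs(cov_free).max():
                raise np.linalg.LinAlgError("information not positive definite")
        except np.linalg.LinAlgError:
            # boundary MLEs (a rate driven to ~0) leave a flat direction; the
            # pseudo-inverse still gives usable variances for the rest
            eigvals, eigvecs = np.linalg.eigh(0.5 * (info + info.T))
            if np.any(eigvals > 0):
                inv_vals = np.where(eigvals > 1e-10 * eigvals.max(), 1.0 / eigvals, 0.0)
                cov_free = (eigvecs * inv_vals) @ eigvecs.T
                flags.append("covariance from pseudo-inverse: observed information singular")
                logger.warning("observed information singular; covariance from pseudo-inverse")
            else:
                flags.append("covariance unavailable: observed information not positive")
                logger.warning("observed information not positive; covariance unavailable")
        if cov_free is not None:
            covariance = np.zeros((layout.n_params, layout.n_params))
            covariance[np.ix_(free, free)] = 0.5 * (cov_free + cov_free.T)

    model = unpack_params(x_hat, layout)
    return FitResult(
        model=model,
        loglik=-float(best.fun),
        covariance=covariance,
        converged=converged,
        n_iter=int(best.nit),
        n_subjects=len(data),
        n_pairs=pairs.n_pairs,
        trace=tuple(trace),
        flags=tuple(flags),
        config=config,
    )


@dataclass(frozen=True)
class HazardRatioEntry:
    transition: str  # e.g. "1->3"
    covariate: str
    hr: float
    lo: float
    hi: float

    @property
    def significant(self) -> bool:
        return self.lo > 1.0 or self.hi < 1.0


@dataclass(frozen=True)
class HazardRatioReport:
    entries: tuple[HazardRatioEntry, ...]

    def significant(self) -> "HazardRatioReport":
        return HazardRatioReport(tuple(e for e in self.entries if e.significant))

    def to_text(self) -> str:
        lines = [f"{'transition':<12}{'covariate':<24}{'HR':>8}  95% CI"]
        for e in self.entries:
            lines.append(
                f"{e.transition:<12}{e.covariate:<24}{e.hr:>8.2f}  ({e.lo:.2f}, {e.hi:.2f})"
            )
        lines.append("HRs are per raw covariate unit, from separate unadjusted fits "
                     "unless stated otherwise; no multiplicity correction.")
        return "\n".join(lines)


def hazard_ratio_report(fit: FitResult) -> HazardRatioReport:
    """Per (transition, covariate) hazard ratios ``exp(beta)`` with 95% CIs."""
    if fit.covariance is None:
        raise ValueError("hazard ratios need a parameter covariance; fit has none")
    if not fit.model.covariates:
        return HazardRatioReport(())
    se = fit.standard_errors()
    m = len(fit.model.allowed)
    p = len(fit.model.covariates)
    entries = []
    # SEs from a flat direction (a rate at ~0) can be enormous; exp() may
    # overflow to inf, which is the honest "unbounded CI" answer
    with np.errstate(over="ignore"):
        for row, k in enumerate(fit.model.allowed):
            i, j = TRANSITIONS[k]
            for c, name in enumerate(fit.model.covariates):
                idx = m + row * p + c
                beta = float(fit.model.betas[row, c])
                entries.append(
                    HazardRatioEntry(
                        transition=f"{i + 1}->{j + 1}",
                        covariate=name,
                        hr=float(np.exp(beta)),
                        lo=float(np.exp(beta - _Z975 * se[idx])),
                        hi=float(np.exp(beta + _Z975 * se[idx])),
                    )
                )
    return HazardRatioReport(tuple(entries))


@dataclass(frozen=True)
class SummaryTable:
    """Jump probabilities plus mean sojourn times (fitted-model summary)."""

    jump: TransitionTable
    sojourn: SojournTimes

    def to_text(self) -> str:
        txt = self.jump.to_text(title="next-state probabilities (given a transition)")
        soj = "    ".join(
            f"{lab}: {w:.2f}" for lab, w in zip(self.sojourn.states.labels, self.sojourn.weeks)
        )
        return f"{txt}\nmean sojourn time (weeks)   {soj}"


def fitted_summary_table(fit: FitResult) -> SummaryTable:
    """Jump-probability table and sojourn times of the fitted baseline Q."""
    if not fit.converged:
        raise ValueError("fit did not converge; summary table unavailable")
    q = fit.model.baseline_intensity()
    return SummaryTable(jump=jump_chain_probabilities(q), sojourn=mean_sojourn_times(q))


#: Default reported transitions (1-based from/to), worst-case and recovery paths.
DEFAULT_INTERVAL_TRANSITIONS = ((1, 3), (2, 3), (3, 1), (2, 1))


@dataclass(frozen=True)
class IntervalProbabilityTable:
    """Interval transition probabilities by follow-up horizon, with CIs."""

    horizons: tuple[str, ...]
    transitions: tuple[tuple[int, int], ...]  # 1-based
    point: np.ndarray  # (n_horizons, n_transitions)
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def to_text(self) -> str:
        head = "horizon".ljust(10) + "".join(
            f"{i}->{j}".center(24) for i, j in self.transitions
        )
        lines = [head]
        for r, hz in enumerate(self.horizons):
            cells = []
            for c in range(len(self.transitions)):
                cell = f"{self.point[r, c]:.3f}"
                if self.lo is not None:
                    cell += f" ({self.lo[r, c]:.3f}, {self.hi[r, c]:.3f})"
                cells.append(cell.center(24))
            lines.append(hz.ljust(10) + "".join(cells))
        return "\n".join(lines)

    def cell(self, horizon: str, transition: tuple[int, int]) -> float:
        return float(
            self.point[self.horizons.index(horizon), self.transitions.index(transition)]
        )


def _points_from_q(qmat: np.ndarray, weeks: np.ndarray, transitions) -> np.ndarray:
    pmats = expm_stack(qmat[None, :, :] * weeks[:, None, None])
    return np.stack([pmats[:, i - 1, j - 1] for i, j in transitions], axis=1)


def interval_probability_table(
    source: FitResult | IntensityMatrix,
    horizons: Sequence[str] = reference.INTERVAL_HORIZONS,
    transitions: Sequence[tuple[int, int]] = DEFAULT_INTERVAL_TRANSITIONS,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    ci: bool = True,
) -> IntervalProbabilityTable:
    """Interval transition probabilities ``P(t)`` at follow-up horizons.

    Horizons are tokens like ``"3m"`` / ``"1y"`` (months at 52/12 weeks).
    When ``source`` is a converged fit with a covariance, 95% CIs come from a
    parametric bootstrap: parameter vectors drawn from the asymptotic normal,
    each mapped through the matrix exponential, with 2.5/97.5 percentiles.
    """
    horizons = tuple(horizons)
    transitions = tuple((int(i), int(j)) for i, j in transitions)
    weeks = np.array([reference.horizon_to_weeks(h) for h in horizons])

    if isinstance(source, IntensityMatrix):
        qmat = source.q
        cov = None
        layout = None
        x_hat = None
    else:
        qmat = source.model.baseline_intensity().q
        cov = source.covariance
        layout = source._layout()
        x_hat = source.params

    point = _points_from_q(qmat, weeks, transitions)

    lo = hi = None
    if ci and cov is not None:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(x_hat, cov, size=bootstrap_reps, method="svd")
        m = len(layout.allowed)
        # weakly identified rates can have enormous SEs; keep draws in a range
        # where exp() and the matrix exponential stay finite
        draws[:, :m] = np.clip(draws[:, :m], -30.0, 8.0)
        sims = np.empty((bootstrap_reps, len(horizons), len(transitions)))
        rates = np.zeros((bootstrap_reps, len(TRANSITIONS)))
        rates[:, list(layout.allowed)] = np.exp(draws[:, :m])
        from .likelihood import _generator_from_rates

        qs = _generator_from_rates(rates)  # (B, 3, 3)
        for r, w in enumerate(weeks):
            pm = expm_stack(qs * w)
            for c, (i, j) in enumerate(transitions):
                sims[:, r, c] = pm[:, i - 1, j - 1]
        lo = np.percentile(sims, 2.5, axis=0)
        hi = np.percentile(sims, 97.5, axis=0)
    elif ci and cov is None:
        logger.warning("CIs requested but no covariance available; returning points only")

    return IntervalProbabilityTable(
        horizons=horizons, transitions=transitions, point=point, lo=lo, hi=hi
    )
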