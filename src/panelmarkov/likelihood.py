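"""Panel-observed CTMC log-likelihood with proportional-intensity covariates.

Each consecutive visit pair contributes ``log P_{s_k, s_{k+1}}(dt; Q(z))``
where ``Q(z)`` has off-diagonals ``q0_ij * exp(beta_ij . (z - ref))``. The
first observed state of every subject is conditioned on, not modelled.

Internally the likelihood is evaluated on packed parameter vectors (log
baseline rates, then per-transition covariate coefficients) over
pre-extracted pair arrays; the gradient uses complex-step differentiation,
which is exact to machine precision and independent of the finite-difference
oracles used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .markov import IntensityMatrix, N_STATES, TRANSITIONS, expm_stack
from .panel import PanelDataset

__all__ = [
    "CovariateModel",
    "LogLikelihood",
    "ParamLayout",
    "PairArrays",
    "intensity_at",
    "panel_loglik",
    "loglik_gradient",
    "extract_pairs",
    "pack_params",
    "unpack_params",
    "loglik_from_params",
]

_ALL_TRANSITIONS = tuple(range(len(TRANSITIONS)))

#: log of the per-week intensity cap used inside the likelihood (see below).
_LOG_RATE_CAP = float(np.log(1e4))


@dataclass(frozen=True)
class CovariateModel:
    """Baseline log-intensities plus per-transition log-hazard-ratios.

    ``log_baseline[k]`` is the log intensity of transition ``allowed[k]``
    (an index into :data:`~panelmarkov.markov.TRANSITIONS`) at covariate
    values equal to ``centering``. ``betas[k, c]`` is the log hazard ratio
    of covariate ``covariates[c]`` on that transition, per raw unit.
    """

    log_baseline: np.ndarray
    covariates: tuple[str, ...] = ()
    betas: np.ndarray | None = None
    centering: np.ndarray | None = None
    allowed: tuple[int, ...] = _ALL_TRANSITIONS

    def __post_init__(self) -> None:
        log_baseline = np.asarray(self.log_baseline)
        if log_baseline.shape != (len(self.allowed),):
            raise ValueError(
                f"log_baseline must have one entry per allowed transition "
                f"({len(self.allowed)}), got shape {log_baseline.shape}"
            )
        p = len(self.covariates)
        betas = self.betas
        betas = np.zeros((len(self.allowed), p)) if betas is None else np.asarray(betas)
        if betas.shape != (len(self.allowed), p):
            raise ValueError(f"betas must have shape ({len(self.allowed)}, {p}), got {betas.shape}")
        centering = self.centering
        centering = np.zeros(p) if centering is None else np.asarray(centering, dtype=float)
        if centering.shape != (p,):
            raise ValueError(f"centering must have shape ({p},)")
        if sorted(set(self.allowed)) != sorted(self.allowed) or not set(self.allowed) <= set(
            _ALL_TRANSITIONS
        ):
            raise ValueError(f"allowed must be distinct indices into TRANSITIONS, got {self.allowed}")
        object.__setattr__(self, "log_baseline", log_baseline)
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "centering", centering)

    @classmethod
    def from_intensity(
        cls,
        q: IntensityMatrix | np.ndarray,
        covariates: Sequence[str] = (),
        betas: np.ndarray | None = None,
        centering: np.ndarray | None = None,
    ) -> "CovariateModel":
        """Homogeneous baseline from a generator (all six transitions free)."""
        qm = np.asarray(q, dtype=float)
        rates = np.array([qm[i, j] for i, j in TRANSITIONS])
        if np.any(rates <= 0):
            raise ValueError("from_intensity requires strictly positive off-diagonal rates")
        return cls(
            log_baseline=np.log(rates),
            covariates=tuple(covariates),
            betas=betas,
            centering=centering,
        )

    @property
    def n_params(self) -> int:
        return len(self.allowed) * (1 + len(self.covariates))

    def baseline_intensity(self) -> IntensityMatrix:
        """Generator at the centering point (covariate effects switched off)."""
        rates = np.zeros(len(TRANSITIONS))
        rates[list(self.allowed)] = np.exp(np.real(self.log_baseline))
        return IntensityMatrix.from_rates(rates)


def intensity_at(model: CovariateModel, z: Mapping[str, float]) -> IntensityMatrix:
    """Subject-specific generator at covariate values ``z``.

    Off-diagonals are ``q0_ij * exp(beta_ij . (z - centering))``; the empty
    covariate schema reduces exactly to the baseline generator.
    """
    missing = [name for name in model.covariates if name not in z]
    if missing:
        raise KeyError(f"missing covariate value(s): {', '.join(missing)}")
    zc = np.array([float(z[name]) for name in model.covariates]) - model.centering
    rates = np.zeros(len(TRANSITIONS))
    rates[list(model.allowed)] = np.exp(model.log_baseline + model.betas @ zc)
    return IntensityMatrix.from_rates(rates)


@dataclass(frozen=True)
class LogLikelihood:
    """Panel log-likelihood value with per-subject contributions."""

    value: float
    per_subject: Mapping[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("log-likelihood is not finite")


@dataclass(frozen=True)
class ParamLayout:
    """Packing order of the free parameters: log rates, then betas row-major."""

    allowed: tuple[int, ...]
    covariates: tuple[str, ...]
    centering: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.allowed) * (1 + len(self.covariates))

    def names(self) -> list[str]:
        labels = [f"logq_{i + 1}{j + 1}" for k, (i, j) in enumerate(TRANSITIONS) if k in self.allowed]
        for k in self.allowed:
            i, j = TRANSITIONS[k]
            labels.extend(f"beta_{i + 1}{j + 1}:{c}" for c in self.covariates)
        return labels


def pack_params(model: CovariateModel) -> np.ndarray:
    return np.concatenate([np.asarray(model.log_baseline, float), np.asarray(model.betas, float).ravel()])


def unpack_params(x: np.ndarray, layout: ParamLayout) -> CovariateModel:
    m = len(layout.allowed)
    p = len(layout.covariates)
    x = np.asarray(x)
    if x.shape != (layout.n_params,):
        raise ValueError(f"expected {layout.n_params} parameters, got shape {x.shape}")
    return CovariateModel(
        log_baseline=np.real(x[:m]),
        covariates=layout.covariates,
        betas=np.real(x[m:]).reshape(m, p),
        centering=layout.centering,
        allowed=layout.allowed,
    )


@dataclass(frozen=True)
class PairArrays:
    """Flat arrays over all consecutive-visit pairs, likelihood-sufficient."""

    frm: np.ndarray  # 0-based from-state
    to: np.ndarray  # 0-based to-state
    dt: np.ndarray  # weeks
    z: np.ndarray  # (n_pairs, p) centered covariates
    subject_index: np.ndarray  # pair -> subject position
    subject_ids: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.frm)


def extract_pairs(data: PanelDataset, layout: ParamLayout) -> PairArrays:
    frm, to, dt, zrows, sidx = [], [], [], [], []
    sids = []
    for pos, series in enumerate(data.subjects):
        sids.append(series.subject_id)
        if series.n_pairs == 0:
            continue
        missing = [c for c in layout.covariates if c not in series.covariates]
        if missing:
            raise KeyError(
                f"subject {series.subject_id} lacks covariate(s): {', '.join(missing)}"
            )
        zc = np.array([series.covariates[c] for c in layout.covariates], float) - layout.centering
        for k in range(series.n_pairs):
            d = series.times[k + 1] - series.times[k]
            if d <= 0:
                raise ValueError(f"subject {series.subject_id}: non-positive interval {d}")
            frm.append(series.states[k] - 1)
            to.append(series.states[k + 1] - 1)
            dt.append(d)
            zrows.append(zc)
            sidx.append(pos)
    p = len(layout.covariates)
    return PairArrays(
        frm=np.array(frm, dtype=int),
        to=np.array(to, dtype=int),
        dt=np.array(dt, dtype=float),
        z=np.array(zrows, dtype=float).reshape(len(frm), p),
        subject_index=np.array(sidx, dtype=int),
        subject_ids=tuple(sids),
    )


def _pair_log_probs(x: np.ndarray, layout: ParamLayout, pairs: PairArrays) -> np.ndarray:
    """log P_{frm,to}(dt) per pair; complex-safe for complex-step gradients.

    ``x`` may be a single packed vector or a (B, n_params) batch of vectors
    (used to evaluate all complex-step perturbations in one vectorized pass);
    the result has a matching leading batch axis.
    """
    x = np.asarray(x)
    batched = x.ndim == 2
    xb = x if batched else x[None, :]
    nb = xb.shape[0]
    m = len(layout.allowed)
    p = len(layout.covariates)
    n = pairs.n_pairs
    log_q0 = xb[:, :m]
    betas = xb[:, m:].reshape(nb, m, p)

    def capped_exp(log_rates):
        # cap rates at 1e4/week (sojourn ~1 minute): far beyond anything a
        # weekly-scale panel can estimate, but keeps exp() and the matrix
        # exponential well-conditioned when the optimizer probes extreme
        # covariate effects. Applied to value and gradient paths alike.
        capped = np.where(np.real(log_rates) > _LOG_RATE_CAP, _LOG_RATE_CAP, log_rates)
        return np.exp(capped)

    if p == 0 or n == 0:
        # homogeneous: one generator per batch, one expm per interval length
        rates = np.zeros((nb, len(TRANSITIONS)), dtype=xb.dtype)
        rates[:, list(layout.allowed)] = capped_exp(log_q0)
        q = _generator_from_rates(rates)  # (B, 3, 3)
        uniq, inverse = np.unique(pairs.dt, return_inverse=True)
        pmats = expm_stack(q[:, None, :, :] * uniq[None, :, None, None])  # (B, U, 3, 3)
        probs = pmats[:, inverse, pairs.frm, pairs.to]
    else:
        log_rates = log_q0[:, None, :] + np.einsum("np,bmp->bnm", pairs.z, betas)
        rates = np.zeros((nb, n, len(TRANSITIONS)), dtype=log_rates.dtype)
        rates[:, :, list(layout.allowed)] = capped_exp(log_rates)
        q = _generator_from_rates(rates)  # (B, n, 3, 3)
        pmats = expm_stack(q * pairs.dt[None, :, None, None])
        probs = pmats[:, np.arange(n), pairs.frm, pairs.to]
    if not np.iscomplexobj(probs):
        probs = np.maximum(probs, 1e-300)
    return np.log(probs) if batched else np.log(probs[0])


def _generator_from_rates(rates: np.ndarray) -> np.ndarray:
    """(..., 6) off-diagonal rates -> (..., 3, 3) generator stack."""
    shape = rates.shape[:-1] + (N_STATES, N_STATES)
    q = np.zeros(shape, dtype=rates.dtype)
    for k, (i, j) in enumerate(TRANSITIONS):
        q[..., i, j] = rates[..., k]
    diag = -q.sum(axis=-1)
    for i in range(N_STATES):
        q[..., i, i] = diag[..., i]
    return q


def loglik_from_params(x: np.ndarray, layout: ParamLayout, pairs: PairArrays):
    """Total log-likelihood at a packed parameter vector (scalar, or per-row
    for a (B, n_params) batch)."""
    return _pair_log_probs(np.asarray(x), layout, pairs).sum(axis=-1)


def _layout_for(model: CovariateModel) -> ParamLayout:
    return ParamLayout(
        allowed=model.allowed, covariates=model.covariates, centering=model.centering
    )


def panel_loglik(model: CovariateModel, data: PanelDataset) -> LogLikelihood:
    """Evaluate the panel log-likelihood of ``model`` on ``data``."""
    layout = _layout_for(model)
    pairs = extract_pairs(data, layout)
    logs = _pair_log_probs(pack_params(model), layout, pairs)
    if not np.all(np.isfinite(logs)):
        bad = int(np.flatnonzero(~np.isfinite(logs))[0])
        sid = pairs.subject_ids[pairs.subject_index[bad]]
        raise FloatingPointError(
            f"non-finite log-likelihood contribution for subject {sid} "
            f"(pair {pairs.frm[bad] + 1}->{pairs.to[bad] + 1}, dt={pairs.dt[bad]})"
        )
    per_subject = {sid: 0.0 for sid in pairs.subject_ids}
    contrib = np.zeros(len(pairs.subject_ids))
    np.add.at(contrib, pairs.subject_index, logs)
    for pos, sid in enumerate(pairs.subject_ids):
        per_subject[sid] = float(contrib[pos])
    return LogLikelihood(value=float(logs.sum()), per_subject=per_subject, n_pairs=pairs.n_pairs)


def gradient_from_params(
    x: np.ndarray, layout: ParamLayout, pairs: PairArrays, h: float = 1e-20
) -> np.ndarray:
    """Complex-step gradient of the log-likelihood, exact to machine precision."""
    x = np.asarray(x, dtype=float)
    xc = np.tile(x.astype(complex), (len(x), 1))
    xc[np.diag_indices(len(x))] += 1j * h
    return np.asarray(loglik_from_params(xc, layout, pairs)).imag / h


def loglik_gradient(model: CovariateModel, data: PanelDataset) -> np.ndarray:
    """Gradient of :func:`panel_loglik` in packed-parameter order."""
    layout = _layout_for(model)
    pairs = extract_pairs(data, layout)
    return gradient_from_params(pack_params(model), layout, pairs)
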