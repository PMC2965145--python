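"""Whole-model negative log-likelihoods and maximum-likelihood fitting.

A candidate model's negative log-likelihood (NLL) is the sum of the NLLs
of its component functions evaluated on the sites each component covers.
Counts are Poisson, or negative-binomial in the mean–dispersion
parameterisation (variance = mu + mu^2/k; Poisson is the k -> infinity
limit).  Expected counts come from the component mean functions on the
model's link scale, times a known multiplicative offset (1 for
abundance, 2 for the two-year richness response).

Fitting strategy
----------------
* Models whose components are all constant have closed-form mean MLEs
  (the per-component sample mean, for Poisson and negative-binomial
  alike); the NB dispersion is then profiled by a 1-D bounded Brent
  search on log k.
* All other models are fitted by Nelder–Mead simplex with multiple
  starts jittered around moment estimates; the moment start itself is
  always included, so the fitted NLL never exceeds the moment-based
  value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .candidate_models import CandidateModel, ComponentFunction
from .data_model import RICHNESS_OFFSET, SiteResponse, Study

__all__ = [
    "OptimizerConfig",
    "FitData",
    "FittedModel",
    "mean_function",
    "nll_poisson",
    "nll_negbin",
    "model_nll",
    "fit_model",
    "build_fit_data",
]

_EPS_MU = 1e-9
_PARAM_BOUND = 30.0  # box for coefficients (and log-dispersion) during search


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the simplex search.

    ``n_starts`` multistarts are jittered around the moment estimates
    (the unjittered moment start is always start 0); ``tol`` is the
    convergence tolerance on the NLL; ``link`` is ``"log"`` (default;
    guarantees positive means) or ``"identity"`` (the literal
    straight-line reading, with means floored at a small epsilon).
    """

    n_starts: int = 5
    tol: float = 1e-8
    max_iter: int = 2000
    link: str = "log"
    jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.link not in ("log", "identity"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass(frozen=True)
class FitData:
    """Per-site arrays for one guild x response, fragmented sites only."""

    site_ids: tuple[str, ...]
    y: np.ndarray  # observed counts
    log10_area: np.ndarray
    landscape_ids: tuple[str, ...]
    offset: float  # 1 for abundance, 2 for the richness response

    @property
    def n(self) -> int:
        return len(self.y)

    def component_mask(self, comp: ComponentFunction) -> np.ndarray:
        lids = set(comp.landscape_ids)
        return np.array([lid in lids for lid in self.landscape_ids], dtype=bool)


@dataclass(frozen=True)
class FittedModel:
    """MLE fit of one candidate model."""

    model: CandidateModel
    params: np.ndarray  # ordered as model.param_names (+ log k if negbin)
    logL: float
    K: int
    n: int
    converged: bool
    degenerate: bool = False  # a component had all-zero counts

    @property
    def param_dict(self) -> dict[str, float]:
        names = list(self.model.param_names)
        out = dict(zip(names, self.params[: len(names)]))
        if self.model.distribution == "negbin":
            out["log_k"] = float(self.params[-1])
        return out


def build_fit_data(
    study: Study, responses: Sequence[SiteResponse], response_kind: str
) -> FitData:
    """Assemble fitting arrays from fragmented sites only.

    Control sites sit in continuous forest, carry no patch area, and are
    used for diversity statistics, not model fitting.
    """
    frag = study.fragmented_sites.set_index("site_id")
    resp = {r.site_id: r for r in responses}
    site_ids, ys, xs, lids = [], [], [], []
    for site_id, row in frag.iterrows():
        r = resp[str(site_id)]
        y = r.abundance if response_kind == "abundance" else r.richness_response
        site_ids.append(str(site_id))
        ys.append(int(y))
        xs.append(float(np.log10(row["patch_area_ha"])))
        lids.append(str(row["landscape_id"]))
    offset = 1.0 if response_kind == "abundance" else float(RICHNESS_OFFSET)
    return FitData(
        site_ids=tuple(site_ids),
        y=np.asarray(ys, dtype=float),
        log10_area=np.asarray(xs, dtype=float),
        landscape_ids=tuple(lids),
        offset=offset,
    )


# ---------------------------------------------------------------------------
# mean functions and likelihood kernels
# ---------------------------------------------------------------------------

def mean_function(
    form: str,
    coefs: Sequence[float],
    log10_area: np.ndarray | float,
    offset: float = 1.0,
    link: str = "log",
) -> np.ndarray | float:
    """Expected count mu of one component at given log10 patch areas.

    Log link (default): constant mu = offset*exp(c); linear
    mu = offset*exp(a + b*log10_area).  Identity link: the linear
    predictor is used directly, floored at 1e-9 to keep mu positive.
    """
    x = np.asarray(log10_area, dtype=float)
    if form == "constant":
        eta = np.full_like(x, float(coefs[0]), dtype=float)
    elif form == "linear":
        a, b = float(coefs[0]), float(coefs[1])
        eta = a + b * x
    else:
        raise ValueError(f"unknown component form {form!r}")
    if link == "log":
        mu = offset * np.exp(eta)
    elif link == "identity":
        mu = offset * np.maximum(eta, _EPS_MU)
    else:
        raise ValueError(f"unknown link {link!r}")
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError(
            f"non-finite expected count from {form} component with coefs {coefs}"
        )
    return mu if np.ndim(log10_area) else float(mu)


def nll_poisson(counts: np.ndarray, mus: np.ndarray) -> float:
    """Poisson negative log-likelihood: sum(mu - y*log(mu) + log(y!))."""
    y = np.asarray(counts, dtype=float)
    mu = np.asarray(mus, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("counts and mus must have equal length")
    if y.size == 0:
        return 0.0
    if np.any(mu <= 0):
        raise ValueError("Poisson means must be positive")
    return float(np.sum(mu - y * np.log(mu) + gammaln(y + 1.0)))


def nll_negbin(counts: np.ndarray, mus: np.ndarray, k: float) -> float:
    """Negative-binomial NLL, mean-dispersion form (variance mu + mu^2/k).

    Written with log1p so the Poisson limit k -> infinity is numerically
    clean.
    """
    if not (k > 0):
        raise ValueError("dispersion k must be positive")
    y = np.asarray(counts, dtype=float)
    mu = np.asarray(mus, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("counts and mus must have equal length")
    if y.size == 0:
        return 0.0
    if np.any(mu <= 0):
        raise ValueError("negative-binomial means must be positive")
    ll = (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        - k * np.log1p(mu / k)
        + y * (np.log(mu) - np.log(k + mu))
    )
    return float(-np.sum(ll))


def model_nll(
    model: CandidateModel,
    params: np.ndarray,
    data: FitData,
    link: str = "log",
) -> float:
    """Whole-model NLL: sum of component NLLs over the sites they cover."""
    params = np.asarray(params, dtype=float)
    n_coef = len(model.param_names)
    expected = n_coef + (1 if model.distribution == "negbin" else 0)
    if params.size != expected:
        raise ValueError(
            f"model {model.model_id} expects {expected} parameters, got {params.size}"
        )
    values = dict(zip(model.param_names, params[:n_coef]))
    k = float(np.exp(params[-1])) if model.distribution == "negbin" else None

    covered = np.zeros(data.n, dtype=bool)
    total = 0.0
    for comp in model.components:
        mask = data.component_mask(comp)
        covered |= mask
        coefs = [values[name] for name in comp.param_names]
        mu = mean_function(comp.form, coefs, data.log10_area[mask], data.offset, link)
        if model.distribution == "poisson":
            total += nll_poisson(data.y[mask], np.asarray(mu))
        else:
            total += nll_negbin(data.y[mask], np.asarray(mu), k)
    if not covered.all():
        missing = [s for s, c in zip(data.site_ids, covered) if not c]
        raise ValueError(
            f"model {model.model_id} assigns no component to sites {missing}"
        )
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _moment_start(model: CandidateModel, data: FitData, link: str) -> np.ndarray:
    """Moment-based starting values, averaging estimates of shared names."""
    acc: dict[str, list[float]] = {name: [] for name in model.param_names}
    for comp in model.components:
        mask = data.component_mask(comp)
        y = data.y[mask]
        x = data.log10_area[mask]
        rate = y / data.offset
        mean_rate = max(float(np.mean(rate)), _EPS_MU)
        if comp.form == "constant":
            c0 = np.log(mean_rate) if link == "log" else mean_rate
            acc[comp.param_names[0]].append(c0)
        else:
            if link == "log":
                z = np.log((y + 0.5) / data.offset)
            else:
                z = rate
            if len(np.unique(x)) >= 2:
                b0, a0 = np.polyfit(x, z, 1)
            else:
                b0, a0 = 0.0, (np.log(mean_rate) if link == "log" else mean_rate)
            acc[comp.param_names[0]].append(float(a0))
            acc[comp.param_names[1]].append(float(b0))
    start = [float(np.mean(acc[name])) for name in model.param_names]
    if model.distribution == "negbin":
        m = float(np.mean(data.y))
        v = float(np.var(data.y, ddof=1)) if data.n > 1 else m
        k0 = m * m / (v - m) if v > m * 1.001 and m > 0 else 10.0
        start.append(float(np.log(np.clip(k0, 1e-3, 1e4))))
    return np.clip(np.asarray(start, dtype=float), -_PARAM_BOUND, _PARAM_BOUND)


def _check_preconditions(model: CandidateModel, data: FitData) -> None:
    for comp in model.components:
        mask = data.component_mask(comp)
        if mask.sum() < 1:
            raise ValueError(
                f"model {model.model_id}: component over {comp.landscape_ids} "
                "covers no sites"
            )
        if comp.form == "linear" and len(np.unique(data.log10_area[mask])) < 2:
            raise ValueError(
                f"model {model.model_id}: linear component over "
                f"{comp.landscape_ids} needs >=2 distinct patch areas"
            )


def _fit_all_constant(
    model: CandidateModel, data: FitData, config: OptimizerConfig
) -> FittedModel:
    """Closed-form means; NB dispersion profiled by 1-D Brent on log k.

    For a constant component the likelihood score in the mean is zero at
    the sample mean for any fixed dispersion, so the mean MLEs are exact.
    """
    values: dict[str, float] = {}
    degenerate = False
    for comp in model.components:
        mask = data.component_mask(comp)
        mean_rate = float(np.mean(data.y[mask])) / data.offset
        if mean_rate <= 0:
            degenerate = True
            mean_rate = _EPS_MU
        values[comp.param_names[0]] = (
            float(np.log(mean_rate)) if config.link == "log" else mean_rate
        )
    coefs = np.array([values[name] for name in model.param_names])

    if model.distribution == "poisson":
        params = coefs
        nll = model_nll(model, params, data, config.link)
        return FittedModel(
            model=model, params=params, logL=-nll, K=model.K, n=data.n,
            converged=True, degenerate=degenerate,
        )

    def profile(log_k: float) -> float:
        return model_nll(model, np.append(coefs, log_k), data, config.link)

    res = minimize_scalar(
        profile, bounds=(-10.0, 16.0), method="bounded",
        options={"xatol": 1e-10},
    )
    params = np.append(coefs, float(res.x))
    return FittedModel(
        model=model, params=params, logL=-float(res.fun), K=model.K, n=data.n,
        converged=bool(res.success), degenerate=degenerate,
    )


def fit_model(
    model: CandidateModel,
    data: FitData,
    config: OptimizerConfig | None = None,
) -> FittedModel:
    """Maximum-likelihood fit of one candidate model.

    Returns a :class:`FittedModel` with an honest ``converged`` flag;
    non-converged fits are excluded from model selection downstream.
    """
    config = config or OptimizerConfig()
    _check_preconditions(model, data)

    if all(c.form == "constant" for c in model.components):
        return _fit_all_constant(model, data, config)

    degenerate = any(
        float(np.sum(data.y[data.component_mask(c)])) == 0.0 for c in model.components
    )

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, -_PARAM_BOUND, _PARAM_BOUND)
        try:
            val = model_nll(model, x, data, config.link)
        except (FloatingPointError, ValueError, OverflowError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    x0 = _moment_start(model, data, config.link)
    rng = np.random.default_rng(config.seed)
    starts = [x0]
    scale = config.jitter_sd * np.maximum(1.0, np.abs(x0))
    for _ in range(config.n_starts - 1):
        starts.append(x0 + rng.normal(0.0, scale))

    best = None
    best_success = False
    for s in starts:
        res = minimize(
            objective, s, method="Nelder-Mead",
            options={
                "fatol": config.tol, "xatol": config.tol,
                "maxiter": config.max_iter, "maxfev": 4 * config.max_iter,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
            best_success = bool(res.success)
    assert best is not None
    params = np.clip(np.asarray(best.x, dtype=float), -_PARAM_BOUND, _PARAM_BOUND)
    nll = objective(params)
    return FittedModel(
        model=model, params=params, logL=-float(nll), K=model.K, n=data.n,
        converged=best_success and np.isfinite(nll), degenerate=degenerate,
    )
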