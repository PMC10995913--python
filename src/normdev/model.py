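"""Warped Bayesian linear regression normative models.

Per region, the model is

    warp((y - y_shift) / y_scale)  ~  Normal(X w, 1 / beta),
    w ~ Normal(0, I / alpha),

where ``warp`` is the two-parameter sinh-arcsinh transform, ``X`` contains
a clamped cubic age B-spline, a 0/1 sex indicator, an intercept and
(during reference fitting only) mean-centered site indicator columns, and
``(y_shift, y_scale)`` are the reference mean and SD of the raw response.
Hyperparameters ``(alpha, beta, eps, delta)`` are chosen by maximizing the
type-II objective: the Gaussian marginal likelihood of the warped response
plus the log-Jacobian of the warp.

Transfer to a new site never refits population parameters.  Residuals of
the site's controls in warped space define an additive offset ``m_s`` and
a multiplicative scale ``s_s`` relative to the model's predictive SD; a
participant's deviation z-score is

    z = (warp(y~) - x w - m_s) / (s_s * sqrt(1/beta + x S x')),

so that controls from a correctly calibrated site are standard normal.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .basis import BasisSpec, build_design_matrix
from .exceptions import CalibrationError, DataError, FittingError
from .regions import region_names
from .warp import WarpParams, log_warp_derivative, warp

__all__ = [
    "SiteCorrection",
    "RegionModel",
    "NormativeModel",
    "gaussian_blr_evidence",
    "fit_region_model",
    "fit_normative_model",
    "recalibrate_site",
    "predict_zscores",
    "save_model",
    "load_model",
]

#: fixed hyperparameter starting points (log alpha, log beta, eps, log delta)
_STARTS = (
    (0.0, 0.0, 0.0, 0.0),
    (np.log(0.1), 0.0, 0.3, np.log(1.2)),
    (np.log(10.0), 0.0, -0.3, np.log(0.8)),
)
_BOUNDS = ((-10.0, 10.0), (-10.0, 10.0), (-3.0, 3.0), (np.log(0.25), np.log(4.0)))


class SiteCorrection(NamedTuple):
    """Additive offset and residual scale for one site, in warped space."""

    offset: float
    scale: float


def gaussian_blr_evidence(X: np.ndarray, t: np.ndarray, alpha: float, beta: float):
    """Log marginal likelihood of a Gaussian Bayesian linear regression.

    Returns ``(log_evidence, posterior_mean, posterior_precision_chol)``
    for targets ``t`` with prior ``w ~ N(0, I/alpha)`` and noise precision
    ``beta``.
    """
    n, d = X.shape
    A = alpha * np.eye(d) + beta * (X.T @ X)
    try:
        chol = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    m = beta * cho_solve(chol, X.T @ t)
    resid = t - X @ m
    energy = 0.5 * beta * float(resid @ resid) + 0.5 * alpha * float(m @ m)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    lml = (
        0.5 * d * np.log(alpha)
        + 0.5 * n * np.log(beta)
        - energy
        - 0.5 * logdet
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return lml, m, chol


def warped_blr_objective(params, y_std: np.ndarray, X: np.ndarray) -> float:
    """Negative (evidence + warp log-Jacobian) at hyperparameters ``params``.

    ``params`` is ``(log alpha, log beta, eps, log delta)``; ``y_std`` is the
    standardized response.
    """
    log_alpha, log_beta, eps, log_delta = params
    p = WarpParams(eps=float(eps), delta=float(np.exp(log_delta)))
    t = warp(y_std, p)
    if not np.all(np.isfinite(t)):
        return 1e12
    lml, _, _ = gaussian_blr_evidence(X, t, np.exp(log_alpha), np.exp(log_beta))
    if not np.isfinite(lml):
        return 1e12
    jac = float(np.sum(log_warp_derivative(y_std, p)))
    return -(lml + jac)


@dataclass
class RegionModel:
    """Fitted normative model for one region."""

    name: str
    weights: np.ndarray
    post_cov: np.ndarray
    alpha: float
    beta: float
    warp: WarpParams
    y_shift: float
    y_scale: float
    basis: BasisSpec
    site_names: tuple[str, ...]
    site_props: np.ndarray
    site_corrections: dict[str, SiteCorrection] = field(default_factory=dict)

    # -- design helpers ------------------------------------------------
    def design(self, age, sex, site: Sequence[str] | None = None) -> np.ndarray:
        """Full-width design rows; site columns are zero unless ``site``
        names reference sites (mean-centered one-hot coding)."""
        X0 = build_design_matrix(age, sex, self.basis)
        S = np.zeros((X0.shape[0], len(self.site_names)))
        if site is not None:
            idx = {s: j for j, s in enumerate(self.site_names)}
            for i, s in enumerate(site):
                if s in idx:
                    S[i, idx[s]] = 1.0
            S -= self.site_props
        return np.column_stack([X0, S])

    def standardize(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_shift) / self.y_scale

    def predictive_variance(self, X: np.ndarray) -> np.ndarray:
        """Warped-space predictive variance 1/beta + x S x' per row."""
        return 1.0 / self.beta + np.einsum("ij,jk,ik->i", X, self.post_cov, X)

    def warped_residuals(self, y, age, sex) -> np.ndarray:
        """warp(standardized y) minus the site-free linear predictor."""
        t = warp(self.standardize(y), self.warp)
        X = self.design(age, sex)
        return t - X @ self.weights


def _check_reference(y, age, site, min_controls: int, name: str, ids=None) -> None:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = np.flatnonzero(~np.isfinite(y))
        who = [str(ids[i]) for i in bad[:5]] if ids is not None else [str(i) for i in bad[:5]]
        raise DataError(f"non-finite responses in region {name!r} for participants {who}")
    if len(y) < min_controls:
        raise FittingError(
            f"region {name!r}: {len(y)} reference controls < required minimum {min_controls}"
        )
    if len(np.unique(np.asarray(age, dtype=float))) < 2:
        raise FittingError(f"region {name!r}: reference ages must span >= 2 distinct values")
    sites, counts = np.unique(np.asarray(site), return_counts=True)
    thin = sites[counts < 2]
    if thin.size:
        raise FittingError(f"region {name!r}: sites with < 2 controls: {list(thin)}")


def _fit_given_design(
    name: str,
    y: np.ndarray,
    X: np.ndarray,
    basis: BasisSpec,
    site_names: tuple[str, ...],
    site_props: np.ndarray,
) -> RegionModel:
    y = np.asarray(y, dtype=float)
    y_shift = float(y.mean())
    y_scale = float(y.std(ddof=0))
    if y_scale <= 0:
        raise FittingError(f"region {name!r}: response has zero variance")
    y_std = (y - y_shift) / y_scale

    best = None
    for x0 in _STARTS:
        res = minimize(
            warped_blr_objective,
            x0=np.asarray(x0),
            args=(y_std, X),
            method="L-BFGS-B",
            bounds=_BOUNDS,
            options={"ftol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    log_alpha, log_beta, eps, log_delta = best.x
    alpha, beta = float(np.exp(log_alpha)), float(np.exp(log_beta))
    wp = WarpParams(eps=float(eps), delta=float(np.exp(log_delta)))
    t = warp(y_std, wp)
    _, m, chol = gaussian_blr_evidence(X, t, alpha, beta)
    post_cov = cho_solve(chol, np.eye(X.shape[1]))

    model = RegionModel(
        name=name,
        weights=np.asarray(m, dtype=float),
        post_cov=np.asarray(post_cov, dtype=float),
        alpha=alpha,
        beta=beta,
        warp=wp,
        y_shift=y_shift,
        y_scale=y_scale,
        basis=basis,
        site_names=site_names,
        site_props=np.asarray(site_props, dtype=float),
    )
    # Reference sites are calibrated by construction: the fitted site column
    # contributes a fixed offset relative to the site-free predictor.
    w_site = model.weights[-len(site_names):] if site_names else np.empty(0)
    base = float(w_site @ site_props) if site_names else 0.0
    for j, s in enumerate(site_names):
        model.site_corrections[s] = SiteCorrection(offset=float(w_site[j] - base), scale=1.0)
    return model


def fit_region_model(
    y,
    age,
    sex,
    site,
    *,
    name: str = "region",
    basis: BasisSpec | None = None,
    n_interior_knots: int = 3,
    min_controls: int = 50,
    ids=None,
) -> RegionModel:
    """Fit a warped BLR normative model for one region on reference controls.

    ``site`` labels become mean-centered fixed-effect columns; the
    returned model carries a built-in :class:`SiteCorrection` for every
    reference site.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    site = np.asarray(site)
    _check_reference(y, age, site, min_controls, name, ids=ids)
    if basis is None:
        basis = BasisSpec.from_ages(age, n_interior=n_interior_knots)
    site_names = tuple(pd.unique(site))
    onehot = np.column_stack([(site == s).astype(float) for s in site_names])
    site_props = onehot.mean(axis=0)
    X = np.column_stack([build_design_matrix(age, sex, basis), onehot - site_props])
    return _fit_given_design(name, y, X, basis, site_names, site_props)


@dataclass
class NormativeModel:
    """Collection of per-region models sharing one basis and site coding."""

    basis: BasisSpec
    site_names: tuple[str, ...]
    models: dict[str, RegionModel]

    @property
    def regions(self) -> list[str]:
        return list(self.models)

    def calibrated_sites(self) -> set[str]:
        sets = [set(m.site_corrections) for m in self.models.values()]
        return set.intersection(*sets) if sets else set()


def fit_normative_model(
    reference: pd.DataFrame,
    regions: Sequence[str] | None = None,
    *,
    n_interior_knots: int = 3,
    min_controls: int = 50,
) -> NormativeModel:
    """Fit per-region models on a reference cohort table.

    ``reference`` must contain ``participant_id, age, sex, site`` plus one
    column per requested region.
    """
    if regions is None:
        regions = [c for c in region_names() if c in reference.columns]
        missing = set(region_names()) - set(regions)
        if missing:
            raise DataError(f"reference table is missing region columns: {sorted(missing)[:5]}")
    age = reference["age"].to_numpy(float)
    sex = reference["sex"].to_numpy(float)
    site = reference["site"].to_numpy()
    ids = reference["participant_id"].to_numpy()

    basis = BasisSpec.from_ages(age, n_interior=n_interior_knots)
    site_names = tuple(pd.unique(site))
    onehot = np.column_stack([(site == s).astype(float) for s in site_names])
    site_props = onehot.mean(axis=0)
    X = np.column_stack([build_design_matrix(age, sex, basis), onehot - site_props])

    models: dict[str, RegionModel] = {}
    for r in regions:
        y = reference[r].to_numpy(float)
        _check_reference(y, age, site, min_controls, r, ids=ids)
        models[r] = _fit_given_design(r, y, X, basis, site_names, site_props)
    return NormativeModel(basis=basis, site_names=site_names, models=models)


# ---------------------------------------------------------------------------
# transfer / prediction
# ---------------------------------------------------------------------------

def recalibrate_region(
    model: RegionModel,
    y,
    age,
    sex,
    site: str,
    *,
    min_controls: int = 10,
    warn_below: int = 20,
) -> RegionModel:
    """Return a copy of ``model`` with offset/scale corrections for ``site``.

    Population weights, warp and hyperparameters are frozen; only the
    warped-space residual mean and scale of the target-site controls are
    estimated.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_controls:
        raise CalibrationError(
            f"region {model.name!r}: {n} controls at site {site!r} < minimum {min_controls}"
        )
    if n < warn_below:
        warnings.warn(
            f"site {site!r}: only {n} controls available for recalibration; "
            "corrections may be unstable",
            stacklevel=2,
        )
    if not np.all(np.isfinite(y)):
        raise DataError(f"non-finite responses for region {model.name!r} at site {site!r}")
    r = model.warped_residuals(y, np.asarray(age, float), np.asarray(sex, float))
    X = model.design(age, sex)
    sd_pred = float(np.sqrt(model.predictive_variance(X).mean()))
    new = copy.deepcopy(model)
    new.site_corrections[site] = SiteCorrection(
        offset=float(r.mean()), scale=float(r.std(ddof=1) / sd_pred)
    )
    return new


def recalibrate_site(
    model: NormativeModel,
    controls: pd.DataFrame,
    *,
    min_controls: int = 10,
    warn_below: int = 20,
) -> NormativeModel:
    """Recalibrate every region of ``model`` to one new site.

    ``controls`` must be rows for a single site.  Returns an updated copy;
    the input model is not mutated.  Calling twice with the same controls
    yields identical corrections.
    """
    sites = pd.unique(controls["site"])
    if len(sites) != 1:
        raise CalibrationError(f"recalibration expects controls from exactly one site, got {list(sites)}")
    site = str(sites[0])
    missing = [r for r in model.models if r not in controls.columns]
    if missing:
        raise CalibrationError(f"control table is missing region columns: {missing[:5]}")
    age = controls["age"].to_numpy(float)
    sex = controls["sex"].to_numpy(float)
    out = {
        r: recalibrate_region(
            m, controls[r].to_numpy(float), age, sex, site,
            min_controls=min_controls, warn_below=warn_below,
        )
        for r, m in model.models.items()
    }
    return NormativeModel(basis=model.basis, site_names=model.site_names, models=out)


def predict_zscores(model: NormativeModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Deviation z-scores (participants x regions) for ``cohort``.

    Every participant's site must have a site correction, either from the
    reference fit or from :func:`recalibrate_site`.
    """
    missing_regions = [r for r in model.models if r not in cohort.columns]
    if missing_regions:
        raise DataError(f"cohort table is missing region columns: {missing_regions[:5]}")
    sites = pd.unique(cohort["site"])
    calibrated = model.calibrated_sites()
    unknown = [s for s in sites if s not in calibrated]
    if unknown:
        raise CalibrationError(
            f"no site correction for site(s) {unknown}; run recalibrate_site with "
            "control data from each new site before predicting z-scores"
        )
    age = cohort["age"].to_numpy(float)
    sex = cohort["sex"].to_numpy(float)
    site = cohort["site"].astype(str).to_numpy()

    z = np.empty((len(cohort), len(model.models)))
    first = next(iter(model.models.values()))
    X = first.design(age, sex)  # shared across regions (same basis/site coding)
    for j, (r, m) in enumerate(model.models.items()):
        t = warp(m.standardize(cohort[r].to_numpy(float)), m.warp)
        mu = X @ m.weights
        sigma = np.sqrt(m.predictive_variance(X))
        offs = np.array([m.site_corrections[s].offset for s in site])
        scal = np.array([m.site_corrections[s].scale for s in site])
        z[:, j] = (t - mu - offs) / (scal * sigma)
    out = pd.DataFrame(z, index=pd.Index(cohort["participant_id"], name="participant_id"),
                       columns=list(model.models))
    if not np.all(np.isfinite(out.to_numpy())):
        raise DataError("non-finite z-scores produced; check input responses")
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _region_to_dict(m: RegionModel) -> dict:
    return {
        "weights": m.weights.tolist(),
        "post_cov": m.post_cov.tolist(),
        "alpha": m.alpha,
        "beta": m.beta,
        "eps": m.warp.eps,
        "delta": m.warp.delta,
        "y_shift": m.y_shift,
        "y_scale": m.y_scale,
        "site_corrections": {s: [c.offset, c.scale] for s, c in m.site_corrections.items()},
    }


def save_model(model: NormativeModel, path) -> None:
    """Serialize a fitted model collection to a documented JSON file."""
    payload = {
        "format": "normdev-model",
        "version": 1,
        "basis": {
            "lo": model.basis.lo,
            "hi": model.basis.hi,
            "interior_knots": list(model.basis.interior_knots),
            "degree": model.basis.degree,
        },
        "site_names": list(model.site_names),
        "site_props": next(iter(model.models.values())).site_props.tolist() if model.models else [],
        "regions": {r: _region_to_dict(m) for r, m in model.models.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> NormativeModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "normdev-model":
        raise DataError(f"{path} is not a normdev model file")
    basis = BasisSpec(
        lo=payload["basis"]["lo"],
        hi=payload["basis"]["hi"],
        interior_knots=tuple(payload["basis"]["interior_knots"]),
        degree=payload["basis"]["degree"],
    )
    site_names = tuple(payload["site_names"])
    site_props = np.asarray(payload["site_props"], dtype=float)
    models = {}
    for r, d in payload["regions"].items():
        models[r] = RegionModel(
            name=r,
            weights=np.asarray(d["weights"], dtype=float),
            post_cov=np.asarray(d["post_cov"], dtype=float),
            alpha=d["alpha"],
            beta=d["beta"],
            warp=WarpParams(eps=d["eps"], delta=d["delta"]),
            y_shift=d["y_shift"],
            y_scale=d["y_scale"],
            basis=basis,
            site_names=site_names,
            site_props=site_props,
            site_corrections={
                s: SiteCorrection(offset=v[0], scale=v[1])
                for s, v in d["site_corrections"].items()
            },
        )
    return NormativeModel(basis=basis, site_names=site_names, models=models)
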