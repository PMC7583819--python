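"""Crown-profile equations, nonlinear least-squares fitting and validation.

Four reparameterized equation families describe the outer crown radius
OR (m) as a function of relative depth into the crown x = RDINC, with
the tree's largest crown radius L = LCR entering as a covariate.  All
families pass through the origin (no intercept): a conifer crown has
zero radius at its tip.

    parabola      OR = (a1 + a2·L)·x + b·x²
    mitscherlich  OR = a·(1 − e^(−(b1 + b2·L)·x))
    power         OR = (a1 + a2·L)·x^(b1 + b2·L)
    beta          OR = (c1 + c2·L)·(1−x)^(a−1)·x^(b−1) / B(a, b),
                  b = b1 + b2·L,  B the Euler beta function

Fitting minimizes Σ(OR_obs − OR_model)² by trust-region least squares
from five deterministic starts; goodness of fit is reported as R² and
RMSE, predictive skill by leave-one-out cross-validation (MPE, MAE,
MAE%).  A field-based reference profile (a Kozak-type equation driven by
DBH, CH = CL/TH and HD = TH/DBH with user-supplied coefficients) is
exposed as a pluggable callable for external validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import betaln

from .profile_points import split_upper_crown

logger = logging.getLogger(__name__)

FTOL = 1e-12
MAX_ITER = 500


# ---------------------------------------------------------------- families

def _parabola(theta, x, L):
    a1, a2, b = theta
    return (a1 + a2 * L) * x + b * x**2


def _mitscherlich(theta, x, L):
    a, b1, b2 = theta
    return a * (1.0 - np.exp(-(b1 + b2 * L) * x))


def _power(theta, x, L):
    a1, a2, b1, b2 = theta
    x = np.asarray(x, dtype=float)
    expo = b1 + b2 * L
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a1 + a2 * L) * np.power(np.maximum(x, 0.0), expo)
    return np.where(x == 0.0, 0.0, out)


def _beta(theta, x, L):
    a, b1, b2, c1, c2 = theta
    x = np.asarray(x, dtype=float)
    L = np.broadcast_to(np.asarray(L, dtype=float), x.shape)
    b = b1 + b2 * L
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("beta family requires a > 0 and b1 + b2*LCR > 0")
    scale = (c1 + c2 * L) / np.exp(betaln(a, b))
    out = np.zeros_like(x, dtype=float)
    interior = (x > 0) & (x < 1)
    xi, bi = x[interior], b[interior]
    out[interior] = scale[interior] * np.exp(
        (a - 1.0) * np.log1p(-xi) + (bi - 1.0) * np.log(xi)
    )
    # continuity limits at the ends of the support
    at0, at1 = x == 0.0, x == 1.0
    out[at0] = np.where(b[at0] > 1, 0.0, np.where(b[at0] == 1, scale[at0], np.inf))
    out[at1] = np.where(a > 1, 0.0, np.inf if a < 1 else scale[at1])
    return out


@dataclass(frozen=True)
class ModelFamily:
    name: str
    param_names: tuple
    fn: callable

    @property
    def n_params(self) -> int:
        return len(self.param_names)


FAMILIES = {
    "parabola": ModelFamily("parabola", ("a1", "a2", "b"), _parabola),
    "mitscherlich": ModelFamily("mitscherlich", ("a", "b1", "b2"), _mitscherlich),
    "power": ModelFamily("power", ("a1", "a2", "b1", "b2"), _power),
    "beta": ModelFamily("beta", ("a", "b1", "b2", "c1", "c2"), _beta),
}


def get_family(name) -> ModelFamily:
    if isinstance(name, ModelFamily):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def evaluate_profile(family, params, rdinc, lcr):
    """OR (m) for one family at RDINC ∈ [0, 1] with covariate LCR.

    ``params`` may be a vector in family order or a name→value mapping.
    """
    fam = get_family(family)
    theta = _theta(fam, params)
    rdinc = np.asarray(rdinc, dtype=float)
    if np.any((rdinc < 0) | (rdinc > 1)):
        raise ValueError("RDINC must lie in [0, 1]")
    return fam.fn(theta, rdinc, np.asarray(lcr, dtype=float))


def _theta(fam: ModelFamily, params) -> np.ndarray:
    if isinstance(params, dict):
        return np.array([params[p] for p in fam.param_names], dtype=float)
    theta = np.asarray(params, dtype=float)
    if theta.size != fam.n_params:
        raise ValueError(f"{fam.name} expects {fam.n_params} parameters")
    return theta


# ----------------------------------------------------------------- fitting

@dataclass
class ProfileFit:
    """NLS fit of one family to profile points (entire or upper crown)."""

    family: str
    scope: str
    params: dict
    std_errors: dict
    r2: float
    rmse: float
    n: int
    sse: float
    singular: bool = field(default=False)

    def predict(self, rdinc, lcr):
        return evaluate_profile(self.family, self.params, rdinc, lcr)

    def to_dict(self) -> dict:
        return {
            "family": self.family, "scope": self.scope, "params": self.params,
            "std_errors": self.std_errors, "r2": self.r2, "rmse": self.rmse,
            "n": self.n,
        }


def _initial_values(fam: ModelFamily, x, y, L):
    """Five deterministic starting vectors per family.

    Linear(izable) structure is exploited where it exists: the parabola
    is linear in its parameters, and the power/beta radial scales are
    linear given fixed shape exponents.
    """
    ymax = float(np.max(y)) if y.size else 1.0
    Lbar = float(np.mean(L)) if np.size(L) else 1.0
    if fam.name == "parabola":
        design = np.column_stack([x, L * x, x**2])
        base, *_ = np.linalg.lstsq(design, y, rcond=None)
        return [base, base * 1.5, base * 0.5,
                np.array([1.0, 1.0, -1.0]), np.array([0.5, 0.5, 0.5])]
    if fam.name == "mitscherlich":
        a0 = 1.2 * ymax
        return [np.array([a0, 0.5, 0.5]), np.array([a0, 1.5, 0.1]),
                np.array([a0, -0.3, 1.1]), np.array([2 * a0, 0.2, 0.3]),
                np.array([a0, 1.0, 1.0])]
    if fam.name == "power":
        def scale_given(b1, b2):
            w = np.power(np.maximum(x, 1e-9), b1 + b2 * L)
            design = np.column_stack([w, L * w])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            return np.array([coef[0], coef[1], b1, b2])

        return [scale_given(1.0, 0.0), scale_given(0.5, 0.1),
                scale_given(0.4, 0.12), np.array([0.1, 1.0, 0.5, 0.1]),
                np.array([1.0, 0.5, 1.0, 0.0])]
    if fam.name == "beta":
        def scale_given(a, b1, b2):
            b = b1 + b2 * L
            w = np.exp((a - 1) * np.log1p(-np.minimum(x, 1 - 1e-9))
                       + (b - 1) * np.log(np.maximum(x, 1e-9)) - betaln(a, b))
            design = np.column_stack([w, L * w])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            return np.array([a, b1, b2, coef[0], coef[1]])

        return [scale_given(1.1, 1.4, 0.2), scale_given(1.05, 1.2, 0.3),
                scale_given(1.5, 2.0, 0.1), scale_given(2.0, 1.5, 0.5),
                np.array([1.1, 1.4, 0.2, 0.2, 0.7])]
    raise ValueError(fam.name)


_BETA_LOWER = np.array([1.0 + 1e-6, -np.inf, -np.inf, -np.inf, -np.inf])


def _fit_arrays(fam: ModelFamily, x, y, L) -> ProfileFit:
    if x.size < 2 * fam.n_params:
        raise ValueError(
            f"need at least {2 * fam.n_params} points to fit {fam.name}"
        )
    bounds = (-np.inf, np.inf)
    if fam.name == "beta":
        bounds = (_BETA_LOWER, np.inf)

    def residuals(theta):
        return fam.fn(theta, x, L) - y

    best = None
    for start in _initial_values(fam, x, y, L):
        start = np.asarray(start, dtype=float)
        if fam.name == "beta":
            start = np.maximum(start, _BETA_LOWER + 1e-9)
        try:
            res = least_squares(residuals, start, bounds=bounds, method="trf",
                                ftol=FTOL, xtol=FTOL, gtol=FTOL,
                                max_nfev=MAX_ITER * fam.n_params)
        except (ValueError, FloatingPointError) as exc:
            logger.debug("start %s failed: %s", start, exc)
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"nonlinear least squares failed to converge for {fam.name} "
            f"from all starts (n={x.size})"
        )
    sse = float(2 * best.cost)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    rmse = float(np.sqrt(sse / x.size))
    se, singular = _standard_errors(best.jac, sse, x.size, fam.n_params)
    return ProfileFit(
        family=fam.name, scope="entire",
        params=dict(zip(fam.param_names, best.x.tolist())),
        std_errors=dict(zip(fam.param_names, se.tolist())),
        r2=r2, rmse=rmse, n=int(x.size), sse=sse, singular=singular,
    )


def _standard_errors(jac, sse, n, p):
    """Asymptotic SEs from the Jacobian at the optimum; a singular
    normal matrix is flagged and yields NaN errors."""
    dof = max(n - p, 1)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (sse / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return se, False
    except np.linalg.LinAlgError:
        logger.warning("singular Jacobian: standard errors unavailable")
        return np.full(p, np.nan), True


def fit_profile(points: pd.DataFrame, family, scope: str = "entire") -> ProfileFit:
    """Fit one family to profile points (columns RDINC, OR, LCR).

    ``scope='upper'`` restricts the data to the upper (light) crown —
    the points above the depth of the largest observed radius of each
    tree — before fitting.
    """
    fam = get_family(family)
    if scope not in ("entire", "upper"):
        raise ValueError("scope must be 'entire' or 'upper'")
    data = split_upper_crown(points) if scope == "upper" else points
    x = data["RDINC"].to_numpy(dtype=float)
    y = data["OR"].to_numpy(dtype=float)
    L = data["LCR"].to_numpy(dtype=float)
    fit = _fit_arrays(fam, x, y, L)
    fit.scope = scope
    return fit


def fit_by_group(points: pd.DataFrame, family, group_col: str,
                 scope: str = "entire") -> dict:
    """Refit one family per subset (e.g. plot or DBH class)."""
    out = {}
    for key, g in points.groupby(group_col, sort=True):
        try:
            out[key] = fit_profile(g, family, scope)
        except (ValueError, RuntimeError) as exc:
            logger.warning("group %r: fit failed (%s)", key, exc)
    return out


# ---------------------------------------------------------- cross-validation

@dataclass
class CVStats:
    """Leave-one-out prediction errors."""

    MPE: float  # mean prediction error (m); sign = bias direction
    MAE: float  # mean absolute error (m)
    MAE_pct: float  # mean |error|/observed ×100, over positive observations
    n: int
    n_folds: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {"MPE": self.MPE, "MAE": self.MAE, "MAE%": self.MAE_pct,
                "n": self.n, "n_folds": self.n_folds, "n_failed": self.n_failed}


def cross_validate(points: pd.DataFrame, family, scope: str = "entire",
                   mode: str = "by_tree") -> CVStats:
    """Leave-one-out CV: hold out one tree (default) or one point,
    refit on the remainder, predict the held-out unit."""
    fam = get_family(family)
    if mode not in ("by_tree", "by_point"):
        raise ValueError("mode must be 'by_tree' or 'by_point'")
    data = split_upper_crown(points) if scope == "upper" else points
    data = data.reset_index(drop=True)
    if mode == "by_tree":
        groups = [idx.to_numpy() for _, idx in data.groupby("tree_id").groups.items()]
    else:
        groups = [np.array([i]) for i in range(len(data))]
    if len(groups) < 3:
        raise ValueError("need at least 3 held-out units for cross-validation")
    x = data["RDINC"].to_numpy(dtype=float)
    y = data["OR"].to_numpy(dtype=float)
    L = data["LCR"].to_numpy(dtype=float)
    errors, observed = [], []
    n_failed = 0
    for hold in groups:
        train = np.setdiff1d(np.arange(len(data)), hold)
        try:
            fit = _fit_arrays(fam, x[train], y[train], L[train])
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            logger.warning("CV fold skipped: %s", exc)
            continue
        pred = fam.fn(_theta(fam, fit.params), x[hold], L[hold])
        errors.append(y[hold] - pred)
        observed.append(y[hold])
    if not errors:
        raise RuntimeError("all cross-validation folds failed")
    e = np.concatenate(errors)
    obs = np.concatenate(observed)
    pos = obs > 0
    return CVStats(
        MPE=float(e.mean()), MAE=float(np.abs(e).mean()),
        MAE_pct=float((np.abs(e[pos]) / obs[pos]).mean() * 100.0),
        n=int(e.size), n_folds=len(groups) - n_failed, n_failed=n_failed,
    )


# ----------------------------------------------------------- reference model

def reference_profile(params: dict, rdinc, dbh, ch, hd):
    """Kozak-type field-based crown profile (coefficients a1…a6 supplied
    by the user; this package does not estimate them).

    OR = (a1·DBH^a2) · X^E with
    X = (1 − (1 − RDINC)^0.5) / (1 − (a3·CH^a4)^0.5) and
    E = a5·(1 − RDINC) + a6·exp(1/HD)·(1 − RDINC).

    DBH in cm; CH = CL/TH in (0, 1); HD = TH/DBH.  Any alternative
    reference can be injected wherever a profile callable is expected.
    """
    a1, a2, a3, a4, a5, a6 = (params[f"a{i}"] for i in range(1, 7))
    rdinc = np.asarray(rdinc, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    ch = np.asarray(ch, dtype=float)
    hd = np.asarray(hd, dtype=float)
    if np.any(dbh <= 0) or np.any((ch <= 0) | (ch >= 1)) or np.any(hd <= 0):
        raise ValueError("requires DBH > 0, 0 < CH < 1, HD > 0")
    denom = 1.0 - np.sqrt(a3 * np.power(ch, a4))
    X = (1.0 - np.sqrt(1.0 - rdinc)) / denom
    if np.any(X < 0):
        raise ValueError("reference profile undefined: X < 0")
    E = a5 * (1.0 - rdinc) + a6 * np.exp(1.0 / hd) * (1.0 - rdinc)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = a1 * np.power(dbh, a2) * np.power(X, E)
    return np.where(X == 0.0, 0.0, out)
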