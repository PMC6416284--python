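"""Exponential dose-response fits and the composed prediction surface.

Candidate regression forms for a response y against phosphate solubility x
(%P2O5):

* ``exp``           y = a * exp(b x)           — monotone exponential
* ``exp_offset``    y = a * exp(b x) + c
* ``peaked``        y = a * x * exp(b x)       — interior maximum at x = -1/b
* ``peaked_offset`` y = a * x * exp(b x) + c

The monotone form alone cannot place an optimum inside the dose range, so
the family carries the peaked variants; the best form per dataset is chosen
by residual standard error (RSE), the same criterion used for the model
selection this stage reports.  Fits are damped nonlinear least squares
(Levenberg-Marquardt via scipy) with log-linear initialization, falling back
to a grid search over the rate when the log transform is unavailable.

The composed surface evaluates the dry-matter fit and the bacteria-fungi
edge-count fit on a shared %P2O5 grid; its argmax locates the phosphate
solubility with the largest predicted dry matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import ValidationError
from .phenostats import LinearFit

__all__ = [
    "ExponentialFit",
    "ExponentialModel",
    "SurfaceGrid",
    "OptimumEstimate",
    "fit_exponential",
    "select_by_rse",
    "compose_surface",
    "find_optimum",
]

_FORMS: dict[str, tuple[int, callable]] = {
    "exp": (2, lambda x, a, b: a * np.exp(b * x)),
    "exp_offset": (3, lambda x, a, b, c: a * np.exp(b * x) + c),
    "peaked": (2, lambda x, a, b: a * x * np.exp(b * x)),
    "peaked_offset": (3, lambda x, a, b, c: a * x * np.exp(b * x) + c),
}


@dataclass
class ExponentialFit:
    """Converged (or failed) nonlinear least-squares fit of one form."""

    form: str
    params: tuple[float, ...]
    r_squared: float
    rse: float
    p_value: float
    n: int
    success: bool = True
    message: str = ""
    stderr: tuple[float, ...] = ()

    def conf_int(self, level: float = 0.95) -> list[tuple[float, float]]:
        """Per-parameter linearized (Wald) intervals, t quantile with n-k df."""
        if not self.stderr:
            raise ValidationError("no standard errors available for this fit")
        tq = stats.t.ppf(0.5 + level / 2.0, self.n - self.n_params)
        return [(p - tq * se, p + tq * se) for p, se in zip(self.params, self.stderr)]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, x) -> np.ndarray:
        _, fn = _FORMS[self.form]
        return fn(np.asarray(x, dtype=float), *self.params)

    def summary(self) -> str:
        names = ("a", "b", "c")[: self.n_params]
        pars = ", ".join(f"{k}={v:.6g}" for k, v in zip(names, self.params))
        return (
            f"{self.form} fit: {pars} "
            f"(R2={self.r_squared:.4f}, RSE={self.rse:.4g}, p={self.p_value:.3g}, n={self.n})"
        )


def _initial_guess(x: np.ndarray, y: np.ndarray, form: str) -> list[float]:
    """Log-linear initialization; grid-search fallback for nonpositive y."""
    offset = form.endswith("offset")
    c0 = float(y.min()) - 0.05 * float(np.ptp(y) or 1.0) if offset else 0.0
    yy = y - c0
    if form.startswith("peaked"):
        ok = (x > 0) & (yy > 0)
        if ok.sum() >= 2:
            coef = np.polyfit(x[ok], np.log(yy[ok] / x[ok]), 1)
            guess = [float(np.exp(coef[1])), float(coef[0])]
        else:
            guess = None
    else:
        ok = yy > 0
        if ok.sum() >= 2:
            coef = np.polyfit(x[ok], np.log(yy[ok]), 1)
            guess = [float(np.exp(coef[1])), float(coef[0])]
        else:
            guess = None
    if guess is None:
        # grid search over the rate; amplitude by least squares at each rate
        _, fn = _FORMS["peaked" if form.startswith("peaked") else "exp"]
        best = (np.inf, [1.0, -0.1])
        span = max(np.ptp(x), 1.0)
        for b in np.linspace(-5.0 / span, 5.0 / span, 41):
            basis = fn(x, 1.0, b)
            denom = float(basis @ basis)
            a = float(basis @ yy) / denom if denom > 0 else 0.0
            ss = float(((yy - a * basis) ** 2).sum())
            if ss < best[0]:
                best = (ss, [a, b])
        guess = best[1]
    return guess + ([c0] if offset else [])


def fit_exponential(x, y, form: str = "peaked_offset", max_iter: int = 500) -> ExponentialFit:
    """Fit one exponential form by damped least squares.

    Returns a failed-fit result (``success=False``) rather than raising when
    the optimizer does not converge.  R2 is 1 - SS_res/SS_tot (0 for
    degenerate constant data), RSE is sqrt(SS_res/(n-k)), and the p-value is
    the F test of the fitted model against the constant (mean-only) model.
    """
    if form not in _FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {sorted(_FORMS)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k, fn = _FORMS[form]
    if len(x) < k + 1:
        raise ValidationError(f"need at least {k + 1} points for form {form!r}")

    guess = _initial_guess(x, y, form)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            params, pcov = optimize.curve_fit(
                fn, x, y, p0=guess, maxfev=max_iter * (k + 1), xtol=1e-12, ftol=1e-12
            )
    except RuntimeError as exc:
        return ExponentialFit(form, tuple(guess), 0.0, float("inf"), 1.0, len(x),
                              success=False, message=str(exc))
    with np.errstate(invalid="ignore"):
        stderr = tuple(float(v) for v in np.sqrt(np.diag(pcov)))
    resid = y - fn(x, *params)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = max(0.0, 1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    rse = float(np.sqrt(ss_res / (len(x) - k)))
    if ss_res <= 1e-300:
        p = 0.0
    elif ss_tot <= ss_res:
        p = 1.0
    else:
        f = ((ss_tot - ss_res) / (k - 1)) / (ss_res / (len(x) - k))
        p = float(stats.f.sf(f, k - 1, len(x) - k))
    return ExponentialFit(form, tuple(float(v) for v in params), r2, rse, p, len(x),
                          stderr=stderr)


class ExponentialModel:
    """Dose-response model over a family of exponential forms.

    ``fit()`` fits every form in ``family`` and returns the RSE-best
    :class:`ExponentialFit`; ``fit_all()`` returns every candidate.
    """

    def __init__(self, x, y, family: tuple[str, ...] = tuple(_FORMS)):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.family = tuple(family)

    def fit_all(self) -> list[ExponentialFit]:
        fits = []
        for form in self.family:
            if len(self.x) < _FORMS[form][0] + 1:
                continue
            fits.append(fit_exponential(self.x, self.y, form))
        return fits

    def fit(self) -> ExponentialFit:
        return select_by_rse(self.fit_all())


def select_by_rse(fits) -> ExponentialFit | LinearFit:
    """The candidate with minimal RSE; ties go to the fewer-parameter form."""
    ok = [f for f in fits if getattr(f, "success", True) and np.isfinite(f.rse)]
    if not ok:
        raise ValidationError("no successful fit to select from")
    return min(ok, key=lambda f: (f.rse, getattr(f, "n_params", 2)))


@dataclass
class SurfaceGrid:
    """Composed (%P2O5, predicted bf edges, predicted dry matter) grid."""

    grid: pd.DataFrame  # columns: p2o5, bf_edges, dry_matter
    step: float
    trend: ExponentialFit

    def __post_init__(self) -> None:
        if not np.isfinite(self.grid.to_numpy()).all():
            raise ValidationError("surface predictions must be finite")


@dataclass
class OptimumEstimate:
    p2o5: float
    bf_edges: float
    dry_matter: float


def compose_surface(fit_dm, fit_edges, x_max: float = 18.0, step: float = 0.01) -> SurfaceGrid:
    """Evaluate both fits on a shared %P2O5 grid covering [0, x_max].

    Also fits an exponential trend of predicted dry matter against predicted
    edge count over the grid (RSE-selected form) and reports its R2/p.
    """
    n_points = int(round(x_max / step)) + 1
    if n_points < 10:
        raise ValidationError("surface grid needs at least 10 points")
    p = np.linspace(0.0, x_max, n_points)
    edges = np.asarray(fit_edges.predict(p), dtype=float)
    dm = np.asarray(fit_dm.predict(p), dtype=float)
    grid = pd.DataFrame({"p2o5": p, "bf_edges": edges, "dry_matter": dm})
    if np.ptp(edges) > 0 and np.ptp(dm) > 0:
        trend = ExponentialModel(edges, dm).fit()
    else:
        trend = ExponentialFit("exp", (float(dm.mean()), 0.0), 0.0,
                               float(np.std(dm)), 1.0, n_points)
    return SurfaceGrid(grid, step, trend)


def find_optimum(surface: SurfaceGrid) -> OptimumEstimate:
    """Grid argmax of predicted dry matter; ties resolve to the lowest %P2O5."""
    df = surface.grid
    if df.empty:
        raise ValidationError("empty surface")
    dm = df["dry_matter"].to_numpy()
    idx = int(np.argmax(dm))  # argmax takes the first (lowest p2o5) maximum
    row = df.iloc[idx]
    return OptimumEstimate(
        p2o5=float(row["p2o5"]),
        bf_edges=float(row["bf_edges"]),
        dry_matter=float(row["dry_matter"]),
    )
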