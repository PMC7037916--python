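"""PLS regression of the composite value on field descriptors, with the full
validation battery: leave-one-out q2, fit statistics (R2, SEE, F), external
prediction (r2_pred, SEP), per-field contribution percentages, progressive
response scrambling, and StDev*Coeff contour extraction.

The PLS core is a plain NIPALS implementation for a single response: columns
are mean-centered (no per-column autoscaling; block scaling happens upstream
in the field assembly), latent components are extracted iteratively, and the
regression vector is reconstructed as B = W (P'W)^-1 q.

Degrees-of-freedom conventions, stated once here because different QSAR
programs disagree: SEE = sqrt(SS_res / (n - a - 1)) and
F = (R2/a) / ((1 - R2)/(n - a - 1)) with a = number of components;
SEP = sqrt(PRESS_test / n_test); cSDEP = sqrt(PRESS / n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import UsageError
from .fields import DescriptorMatrix, Grid
from .prepare import FIELD_NAMES

MAX_COMPONENTS = 10  # conventional cap for the component scan


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Fitted NIPALS model (mean-centered X, single y)."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray  # regression vector on centered X
    x_weights: np.ndarray  # W, (p, a)
    x_loadings: np.ndarray  # P, (p, a)
    y_loadings: np.ndarray  # q, (a,)
    scores: np.ndarray  # T, (n, a)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a NIPALS PLS1 model with ``n_components`` latent components.

    If the matrix runs out of rank before the requested number of components,
    the extraction stops early with a warning.  A constant response yields a
    zero-coefficient model (R2 reported as 0 downstream, by convention).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise UsageError("X and y disagree on the number of observations")
    if n_components < 1:
        raise UsageError("n_components must be >= 1")
    if n < n_components + 1:
        raise UsageError(f"need at least n_components+1={n_components + 1} observations, got {n}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))

    eps = np.finfo(float).eps
    x_scale = float(np.abs(Xc).max()) or 1.0
    y_scale = float(np.abs(yc).max()) or 1.0
    actual = 0
    for a in range(n_components):
        w = Xc.T @ yc
        norm_w = np.linalg.norm(w)
        if norm_w <= eps * 100 * x_scale * y_scale:
            warnings.warn(
                f"rank exhausted after {actual} components (requested {n_components})",
                stacklevel=2,
            )
            break
        w /= norm_w
        t = Xc @ w
        tt = float(t @ t)
        if tt <= eps * 100:
            warnings.warn(
                f"rank exhausted after {actual} components (requested {n_components})",
                stacklevel=2,
            )
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        actual += 1

    W, P, q, T = W[:, :actual], P[:, :actual], q[:actual], T[:, :actual]
    if actual == 0:
        coef = np.zeros(p)
    else:
        coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=actual,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
    )


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


@dataclass
class FitStatistics:
    r2: float
    see: float
    f_stat: float
    y_hat: np.ndarray


def fit_statistics(model: PLSModel, X: np.ndarray, y: np.ndarray) -> FitStatistics:
    """Non-cross-validated R2, standard error of estimate, and F value."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = model.predict(X)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - y_hat) ** 2))
    a = max(model.n_components, 1)
    dof = len(y) - a - 1
    if ss_tot == 0:
        return FitStatistics(r2=0.0, see=0.0, f_stat=0.0, y_hat=y_hat)
    r2 = 1.0 - ss_res / ss_tot
    see = float(np.sqrt(ss_res / dof)) if dof > 0 else float("nan")
    if dof > 0 and r2 < 1.0:
        f_stat = (r2 / a) / ((1.0 - r2) / dof)
    else:
        f_stat = float("inf")
    return FitStatistics(r2=r2, see=see, f_stat=f_stat, y_hat=y_hat)


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[float, float]:
    """Leave-one-out q2 = 1 - PRESS/SS_tot and cSDEP = sqrt(PRESS/n)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise UsageError("leave-one-out validation needs at least 3 observations")
    press = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = fit_pls(X[mask], y[mask], n_components)
            press += float((y[i] - model.predict(X[i : i + 1])[0]) ** 2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0, float(np.sqrt(press / n))
    return 1.0 - press / ss_tot, float(np.sqrt(press / n))


def component_scan(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = MAX_COMPONENTS,
    criterion: str = "q2",
) -> tuple[int, list[dict]]:
    """Scan 1..max_components and pick the optimum.

    ``criterion='q2'`` maximizes leave-one-out q2 (ties -> smaller n);
    ``criterion='sep'`` minimizes cSDEP.
    """
    if criterion not in ("q2", "sep"):
        raise UsageError("criterion must be 'q2' or 'sep'")
    n = len(np.asarray(y).ravel())
    upper = min(max_components, n - 2)
    rows = []
    for a in range(1, upper + 1):
        q2, csdep = loo_q2(X, y, a)
        rows.append({"n_components": a, "q2": q2, "csdep": csdep})
    if criterion == "q2":
        best = max(rows, key=lambda r: (r["q2"], -r["n_components"]))
    else:
        best = min(rows, key=lambda r: (r["csdep"], r["n_components"]))
    return best["n_components"], rows


def external_validation(
    model: PLSModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    training_mean: float,
) -> tuple[float, float]:
    """r2_pred = (SD - PRESS)/SD against the training mean, and SEP.

    SD = sum (y_test - training_mean)^2, PRESS = sum (y_test - y_hat)^2,
    SEP = sqrt(PRESS / n_test).  SD = 0 is flagged as undefined.
    """
    y_test = np.asarray(y_test, dtype=float).ravel()
    if len(y_test) < 2:
        raise UsageError("external validation needs at least 2 test rows")
    y_hat = model.predict(X_test)
    sd = float(np.sum((y_test - training_mean) ** 2))
    press = float(np.sum((y_test - y_hat) ** 2))
    sep = float(np.sqrt(press / len(y_test)))
    if sd == 0:
        return float("nan"), sep
    return (sd - press) / sd, sep


def field_contributions(model: PLSModel, X: np.ndarray, column_field: np.ndarray) -> dict[str, float]:
    """Per-field share of total |coef|*SD mass, in percent (sums to 100)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    mass = np.abs(model.coef) * sd
    total = float(mass.sum())
    out = {}
    for name in FIELD_NAMES:
        cols = np.flatnonzero(np.asarray(column_field) == name)
        out[name] = 100.0 * float(mass[cols].sum()) / total if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# progressive scrambling
# ---------------------------------------------------------------------------


@dataclass
class ScramblingReport:
    q2_scr: float  # q2 interpolated at the critical correlation
    csdep: float  # cSDEP interpolated at the critical correlation
    slope: float  # dq2/dr2yy
    critical_r2yy: float
    baseline_q2: float
    levels: list[dict] = dc_field(default_factory=list)  # level, r2yy, q2, csdep


def _partial_permute(y: np.ndarray, level: float, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Scramble the response within rank bins; higher levels coarsen the bins.

    At level t the sorted responses are split into max(1, round(n_bins*(1-t)))
    contiguous rank bins and fully permuted within each bin, so small levels
    shuffle only near-neighbours in rank (high residual correlation with the
    original) and level 1 collapses to one bin, i.e. a full random permutation.
    """
    if level <= 0:
        return y.copy()
    n_bins_eff = max(1, round(n_bins * (1.0 - level)))
    order = np.argsort(y, kind="stable")
    out = y.copy()
    for b in np.array_split(order, n_bins_eff):
        out[b] = out[rng.permutation(b)]
    return out


def progressive_scrambling(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    seed: int = 0,
    n_bins: int = 10,
    n_repeats: int = 20,
    critical_r2yy: float = 0.85,
) -> ScramblingReport:
    """Progressive response scrambling.

    For each perturbation level, the response is partially permuted within
    rank bins (``n_repeats`` seeded draws), the squared correlation r2yy'
    between original and perturbed responses and the leave-one-out q2 of the
    perturbed model are averaged, the slope dq2/dr2yy is the least-squares
    slope of mean q2 against mean r2yy', and the reported Q2/cSDEP are
    interpolated at ``critical_r2yy``.
    """
    if len(levels) < 3:
        raise UsageError("progressive scrambling needs at least 3 perturbation levels")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    baseline_q2, baseline_csdep = loo_q2(X, y, n_components)

    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        if level == 0:
            rows.append(
                {"level": 0.0, "r2yy": 1.0, "q2": baseline_q2, "csdep": baseline_csdep}
            )
            continue
        r2s, q2s, cs = [], [], []
        for _ in range(n_repeats):
            y_p = _partial_permute(y, level, n_bins, rng)
            r = np.corrcoef(y, y_p)[0, 1]
            q2_p, csdep_p = loo_q2(X, y_p, n_components)
            r2s.append(r * r)
            q2s.append(q2_p)
            cs.append(csdep_p)
        rows.append(
            {
                "level": float(level),
                "r2yy": float(np.mean(r2s)),
                "q2": float(np.mean(q2s)),
                "csdep": float(np.mean(cs)),
            }
        )

    rows.sort(key=lambda r: r["r2yy"])
    r2yy = np.array([r["r2yy"] for r in rows])
    q2s = np.array([r["q2"] for r in rows])
    csdeps = np.array([r["csdep"] for r in rows])
    slope = float(np.polyfit(r2yy, q2s, 1)[0]) if np.ptp(r2yy) > 0 else float("nan")

    # interpolate at the critical correlation; the baseline anchors r2yy = 1
    xs = np.concatenate([r2yy, [1.0]])
    order = np.argsort(xs)
    q2_at = float(np.interp(critical_r2yy, xs[order], np.concatenate([q2s, [baseline_q2]])[order]))
    csdep_at = float(
        np.interp(critical_r2yy, xs[order], np.concatenate([csdeps, [baseline_csdep]])[order])
    )
    return ScramblingReport(
        q2_scr=q2_at,
        csdep=csdep_at,
        slope=slope,
        critical_r2yy=critical_r2yy,
        baseline_q2=baseline_q2,
        levels=rows,
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------


@dataclass
class ContourSet:
    """Per-field favored/disfavored grid masks from StDev*Coeff values."""

    grid: Grid
    stdev_coeff: dict[str, np.ndarray]  # full flattened grid, zeros off kept columns
    favored: dict[str, np.ndarray]  # boolean masks, flattened grid
    disfavored: dict[str, np.ndarray]
    favored_pct: float
    disfavored_pct: float


def extract_contours(
    model: PLSModel,
    descriptors: DescriptorMatrix,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> ContourSet:
    """StDev*Coeff contour masks per field.

    Favored cells have positive StDev*Coeff at or above the ``favored_pct``
    percentile of the field's kept-column values; disfavored cells have
    negative StDev*Coeff at or below the ``disfavored_pct`` percentile.  The
    two masks are disjoint by construction.
    """
    if not favored_pct > disfavored_pct:
        raise UsageError("favored percentile must exceed the disfavored percentile")
    sd = descriptors.X.std(axis=0, ddof=0)
    sc = model.coef * sd
    grid = descriptors.grid
    stdev_coeff, favored, disfavored = {}, {}, {}
    for name in FIELD_NAMES:
        full = np.zeros(grid.n_points)
        cols = descriptors.columns_of(name)
        fav = np.zeros(grid.n_points, dtype=bool)
        dis = np.zeros(grid.n_points, dtype=bool)
        if cols.size == 0:
            warnings.warn(f"field {name} has no kept columns; empty contour masks", stacklevel=2)
        else:
            vals = sc[cols]
            pts = descriptors.column_point[cols]
            full[pts] = vals
            hi = np.percentile(vals, favored_pct)
            lo = np.percentile(vals, disfavored_pct)
            fav[pts[(vals >= hi) & (vals > 0)]] = True
            dis[pts[(vals <= lo) & (vals < 0)]] = True
        stdev_coeff[name] = full
        favored[name] = fav
        disfavored[name] = dis
    return ContourSet(
        grid=grid,
        stdev_coeff=stdev_coeff,
        favored=favored,
        disfavored=disfavored,
        favored_pct=favored_pct,
        disfavored_pct=disfavored_pct,
    )


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------


@dataclass
class PLSModelReport:
    """Everything the model evaluation tables report, in one place."""

    n_components: int
    q2: float
    csdep_loo: float
    r2: float
    see: float
    f_stat: float
    r2_pred: float | None
    sep: float | None
    contributions: dict[str, float]
    training_mean: float
    component_scan: list[dict]
    model: PLSModel

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "q2": self.q2,
            "csdep_loo": self.csdep_loo,
            "r2": self.r2,
            "see": self.see,
            "f_stat": self.f_stat,
            "r2_pred": self.r2_pred,
            "sep": self.sep,
            "contributions": self.contributions,
            "training_mean": self.training_mean,
            "component_scan": self.component_scan,
        }


def build_model_report(
    descriptors: DescriptorMatrix,
    y_train: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    n_components: int | None = None,
    max_components: int = MAX_COMPONENTS,
    criterion: str = "q2",
) -> PLSModelReport:
    """Fit on the training rows, validate, and collect every statistic."""
    X = descriptors.X
    X_train = X[train_rows]
    y_train = np.asarray(y_train, dtype=float).ravel()
    if n_components is None:
        n_components, scan = component_scan(X_train, y_train, max_components, criterion)
    else:
        scan = []
    q2, csdep = loo_q2(X_train, y_train, n_components)
    model = fit_pls(X_train, y_train, n_components)
    stats = fit_statistics(model, X_train, y_train)
    r2_pred = sep = None
    if test_rows is not None and y_test is not None and len(test_rows) >= 2:
        r2_pred, sep = external_validation(model, X[test_rows], y_test, float(y_train.mean()))
    contributions = field_contributions(model, X_train, descriptors.column_field)
    return PLSModelReport(
        n_components=model.n_components,
        q2=q2,
        csdep_loo=csdep,
        r2=stats.r2,
        see=stats.see,
        f_stat=stats.f_stat,
        r2_pred=r2_pred,
        sep=sep,
        contributions=contributions,
        training_mean=float(y_train.mean()),
        component_scan=scan,
        model=model,
    )
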