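"""Distance-sampling detection-probability estimation for camera traps.

Observation distances are binned into equally spaced intervals between a
left and right truncation distance, and a detection function ``g(r)`` is
fitted by maximum likelihood on the binned counts.  Point-transect geometry
applies: the density of observable distances is proportional to
``r * g(r)`` (the annulus area element), and the camera's angular field of
view cancels from the multinomial bin probabilities.

Two parametric families are provided:

* ``uniform`` key with cosine adjustments:
  ``g(r) = (1 + sum_j a_j cos(j*pi*r_s)) / (1 + sum_j a_j)`` with the
  left-truncation-shifted scaled distance ``r_s = (r - w_l)/(w_r - w_l)``,
  so ``g(w_l) = 1`` by construction.
* ``half-normal``: ``g(r) = exp(-r^2 / (2*sigma^2))``.

Fits constrain ``0 <= g <= 1`` on a 512-point grid across the truncation
range; monotonicity is deliberately not enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DistanceDataset",
    "DetectionFunctionModel",
    "DetectionFit",
    "bin_distances",
    "detection_g",
    "expected_bin_probabilities",
    "average_detection_probability",
    "fit_detection_function",
    "simulate_distances",
]

_CONSTRAINT_GRID_N = 512
_SIMPSON_TOL = 1e-8


@dataclass(frozen=True)
class DistanceDataset:
    """Observation distances plus the binning design.

    ``n_bins`` equally spaced intervals between the left truncation ``w_l``
    and right truncation ``w_r``; distances outside ``[w_l, w_r]`` are
    discarded before analysis.
    """

    distances_m: np.ndarray
    left_trunc: float = 3.0
    right_trunc: float = 11.0
    n_bins: int = 7

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "distances_m", np.asarray(self.distances_m, dtype=np.float64)
        )
        if not 0 <= self.left_trunc < self.right_trunc:
            raise ValueError("need 0 <= left_trunc < right_trunc")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.left_trunc, self.right_trunc, self.n_bins + 1)


@dataclass(frozen=True)
class DetectionFunctionModel:
    """A detection function: key family, parameters, truncation range."""

    key: str  # "uniform" | "half-normal"
    left_trunc: float
    right_trunc: float
    cosine_orders: tuple[int, ...] = ()
    adjustment_coefficients: tuple[float, ...] = ()
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.key not in ("uniform", "half-normal"):
            raise ValueError(f"unknown key {self.key!r}")
        if not 0 <= self.left_trunc < self.right_trunc:
            raise ValueError("need 0 <= left_trunc < right_trunc")
        if self.key == "uniform":
            if len(self.cosine_orders) != len(self.adjustment_coefficients):
                raise ValueError("one coefficient per cosine order required")
        else:
            if self.sigma is None or not self.sigma > 0:
                raise ValueError("half-normal key needs sigma > 0")

    @property
    def n_parameters(self) -> int:
        return 1 if self.key == "half-normal" else len(self.adjustment_coefficients)


@dataclass
class DetectionFit:
    """Result of a binned maximum-likelihood detection-function fit."""

    model: DetectionFunctionModel
    log_likelihood: float
    aic: float
    expected_bin_probabilities: np.ndarray
    observed_counts: np.ndarray
    average_detection_probability: float
    chi2_statistic: float
    chi2_dof: int
    chi2_p_value: float
    at_boundary: bool = False
    n_evaluations: int = 0


def bin_distances(ds: DistanceDataset) -> np.ndarray:
    """Truncate and histogram distances into the dataset's bins.

    Bins are left-closed/right-open except the last, which is closed so the
    right truncation distance itself is retained.
    """
    r = ds.distances_m
    r = r[np.isfinite(r)]
    kept = r[(r >= ds.left_trunc) & (r <= ds.right_trunc)]
    if kept.size == 0:
        raise ValueError(
            "no distances remain inside "
            f"[{ds.left_trunc}, {ds.right_trunc}] after truncation"
        )
    # np.histogram implements exactly this boundary rule
    counts, _ = np.histogram(kept, bins=ds.bin_edges)
    return counts.astype(np.int64)


def detection_g(model: DetectionFunctionModel, r) -> np.ndarray | float:
    """Evaluate the detection probability ``g(r)`` inside the truncation range."""
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(r_arr < model.left_trunc - 1e-12) or np.any(
        r_arr > model.right_trunc + 1e-12
    ):
        raise ValueError(
            f"distance outside truncation range "
            f"[{model.left_trunc}, {model.right_trunc}]"
        )
    g = _g_unchecked(model, r_arr)
    return float(g) if np.isscalar(r) else g


def _g_unchecked(model: DetectionFunctionModel, r: np.ndarray) -> np.ndarray:
    if model.key == "half-normal":
        return np.exp(-(r**2) / (2.0 * model.sigma**2))
    r_s = (r - model.left_trunc) / (model.right_trunc - model.left_trunc)
    series = np.ones_like(r_s)
    denom = 1.0
    for j, a in zip(model.cosine_orders, model.adjustment_coefficients):
        series = series + a * np.cos(j * math.pi * r_s)
        denom += a
    if denom == 0:
        raise ZeroDivisionError("degenerate adjustment series (1 + sum a_j = 0)")
    return series / denom


def _simpson_adaptive(f, a: float, b: float, rel_tol: float = _SIMPSON_TOL) -> float:
    """Composite Simpson on a uniform grid, doubled until relative convergence."""
    n = 64
    prev = None
    for _ in range(20):
        x = np.linspace(a, b, n + 1)
        y = f(x)
        h = (b - a) / n
        s = (h / 3.0) * (y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-1:2].sum())
        if prev is not None and abs(s - prev) <= rel_tol * max(abs(s), 1e-300):
            return s
        prev = s
        n *= 2
    return prev


def expected_bin_probabilities(
    model: DetectionFunctionModel, bin_edges: np.ndarray
) -> np.ndarray:
    """Multinomial bin probabilities ``p_k`` under point-transect geometry.

    ``p_k`` is the integral of ``r * g(r)`` over bin ``k`` divided by the
    integral over the full truncation range.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)

    def rg(x):
        return x * _g_unchecked(model, x)

    parts = np.array(
        [_simpson_adaptive(rg, edges[k], edges[k + 1]) for k in range(len(edges) - 1)]
    )
    total = parts.sum()
    if not total > 0:
        raise ZeroDivisionError("degenerate detection function: integral of r*g is 0")
    return parts / total


def average_detection_probability(model: DetectionFunctionModel) -> float:
    """Area-weighted mean of g over the truncated annulus:
    ``P = int 2 r g(r) dr / (w_r^2 - w_l^2)``."""
    w_l, w_r = model.left_trunc, model.right_trunc

    def rg2(x):
        return 2.0 * x * _g_unchecked(model, x)

    return _simpson_adaptive(rg2, w_l, w_r) / (w_r**2 - w_l**2)


def _constraint_ok(model: DetectionFunctionModel) -> bool:
    grid = np.linspace(model.left_trunc, model.right_trunc, _CONSTRAINT_GRID_N)
    g = _g_unchecked(model, grid)
    return bool(np.all(g >= -1e-12) and np.all(g <= 1.0 + 1e-12))


def _make_model(
    spec: DetectionFunctionModel, theta: np.ndarray
) -> DetectionFunctionModel:
    if spec.key == "half-normal":
        return DetectionFunctionModel(
            key="half-normal",
            left_trunc=spec.left_trunc,
            right_trunc=spec.right_trunc,
            sigma=float(np.exp(theta[0])),
        )
    return DetectionFunctionModel(
        key="uniform",
        left_trunc=spec.left_trunc,
        right_trunc=spec.right_trunc,
        cosine_orders=spec.cosine_orders,
        adjustment_coefficients=tuple(float(t) for t in theta),
    )


def fit_detection_function(
    counts: np.ndarray,
    bin_edges: np.ndarray,
    *,
    key: str = "uniform",
    cosine_orders: tuple[int, ...] = (1,),
) -> DetectionFit:
    """Fit by binned multinomial maximum likelihood.

    Maximizes ``l(theta) = sum_k n_k log p_k(theta)`` subject to
    ``0 <= g <= 1`` on the constraint grid.  Single-coefficient cosine
    specs use a bounded scalar search; multi-parameter specs use a
    5-start Nelder-Mead with a feasibility penalty.  Solutions pinned at
    the feasible-region boundary are flagged, not rejected.
    """
    counts = np.asarray(counts, dtype=np.float64)
    edges = np.asarray(bin_edges, dtype=np.float64)
    if counts.sum() < 1:
        raise ValueError("need at least one observation")
    if len(edges) != len(counts) + 1:
        raise ValueError("bin_edges must have len(counts)+1 entries")
    w_l, w_r = float(edges[0]), float(edges[-1])

    spec = (
        DetectionFunctionModel(
            key="uniform",
            left_trunc=w_l,
            right_trunc=w_r,
            cosine_orders=tuple(cosine_orders),
            adjustment_coefficients=tuple(0.0 for _ in cosine_orders),
        )
        if key == "uniform"
        else DetectionFunctionModel(
            key="half-normal", left_trunc=w_l, right_trunc=w_r, sigma=w_r
        )
    )

    n_eval = 0

    def neg_ll(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        model = _make_model(spec, np.atleast_1d(theta))
        if not _constraint_ok(model):
            return 1e12
        try:
            p = expected_bin_probabilities(model, edges)
        except ZeroDivisionError:
            return 1e12
        if np.any(p <= 0):
            # zero-probability bin with observations => -inf likelihood
            if np.any((p <= 0) & (counts > 0)):
                return 1e12
            p = np.clip(p, 1e-300, None)
        return -float(np.sum(counts * np.log(p)))

    at_boundary = False
    if key == "half-normal":
        res = optimize.minimize_scalar(
            lambda t: neg_ll(np.array([t])),
            bounds=(math.log(w_r / 50.0), math.log(w_r * 50.0)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta_hat = np.array([res.x])
    elif len(cosine_orders) == 1:
        # for the single-term series the g<=1 constraint forces a_1 >= 0 and
        # g>=0 forces a_1 <= 1; search the closed feasible interval
        lo, hi = 0.0, 1.0
        res = optimize.minimize_scalar(
            lambda t: neg_ll(np.array([t])),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta_hat = np.array([res.x])
        # bounded search never lands exactly on a bound; probe both ends
        for endpoint in (lo, hi):
            if neg_ll(np.array([endpoint])) < neg_ll(theta_hat):
                theta_hat = np.array([endpoint])
        at_boundary = min(theta_hat[0] - lo, hi - theta_hat[0]) < 1e-6
    else:
        rng = np.random.default_rng(0)
        best = None
        for start in range(5):
            x0 = np.zeros(len(cosine_orders))
            if start > 0:
                x0 = rng.uniform(-0.3, 0.3, size=len(cosine_orders))
            res = optimize.minimize(
                neg_ll,
                x0,
                method="Nelder-Mead",
                options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 5000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise RuntimeError(f"detection-function fit failed to converge: {best}")
        theta_hat = np.asarray(best.x)
        at_boundary = not _constraint_ok(
            _make_model(spec, theta_hat + np.sign(theta_hat) * 1e-4)
        )

    nll = neg_ll(theta_hat)
    if not np.isfinite(nll) or nll >= 1e12:
        raise RuntimeError("detection-function fit ended infeasible")

    model_hat = _make_model(spec, theta_hat)
    p_hat = expected_bin_probabilities(model_hat, edges)
    ll = -nll
    dim = model_hat.n_parameters
    n_total = counts.sum()
    expected = n_total * p_hat
    chi2 = float(np.sum((counts - expected) ** 2 / np.where(expected > 0, expected, 1.0)))
    dof = max(1, len(counts) - 1 - dim)
    p_value = float(stats.chi2.sf(chi2, dof))

    return DetectionFit(
        model=model_hat,
        log_likelihood=ll,
        aic=2.0 * dim - 2.0 * ll,
        expected_bin_probabilities=p_hat,
        observed_counts=counts.astype(np.int64),
        average_detection_probability=average_detection_probability(model_hat),
        chi2_statistic=chi2,
        chi2_dof=dof,
        chi2_p_value=p_value,
        at_boundary=bool(at_boundary),
        n_evaluations=n_eval,
    )


def simulate_distances(
    model: DetectionFunctionModel, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. distances from the density ``f(r) ~ r * g(r)`` on the
    truncation range, by rejection sampling.  Deterministic under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w_l, w_r = model.left_trunc, model.right_trunc
    grid = np.linspace(w_l, w_r, 4096)
    envelope = float(np.max(grid * _g_unchecked(model, grid))) * 1.0001

    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(1024, 2 * (n - filled))
        r = rng.uniform(w_l, w_r, size=m)
        u = rng.uniform(0.0, envelope, size=m)
        acc = r[u < r * _g_unchecked(model, r)]
        take = min(acc.size, n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    return out
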