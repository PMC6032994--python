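"""Benchmark objective suite for validating continuous optimizers.

Twenty-three classical test functions (``F1`` .. ``F23``) spanning three
families:

* ``F1``-``F7``: unimodal, scalable dimension (default 30),
* ``F8``-``F13``: multimodal, scalable dimension (default 30),
* ``F14``-``F23``: multimodal with a fixed low dimension.

Each entry carries its search box, default dimension and the best objective
value reported in the optimization literature.  All functions accept either a
single point of shape ``(d,)`` or a batch of points of shape ``(n, d)`` and
evaluate in vectorized NumPy.  ``F7`` adds uniform noise on ``[0, 1)``; the
noise source is injectable and defaults to *off* (no random source, no noise)
so that the suite is deterministic unless a generator is supplied.

A deterministic dense-grid + simplex-polish search
(:func:`reference_minimum`) serves as an independent oracle for the printed
minima of the fixed-dimension functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .exceptions import BudgetError, ContractError

__all__ = [
    "BenchmarkFunction",
    "FUNCTION_IDS",
    "get_function",
    "get_metadata",
    "evaluate",
    "reference_minimum",
    "metadata_table",
]

_ZERO_DIAG_EPS = 1e-12


@dataclass(frozen=True)
class BenchmarkFunction:
    """A benchmark objective with its search box and known minimum."""

    id: str
    dimension: int
    bounds: np.ndarray  # (d, 2) closed intervals
    known_min: float
    _fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    stochastic: bool = False
    scalable: bool = False

    @property
    def lower(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def upper(self) -> np.ndarray:
        return self.bounds[:, 1]

    def evaluate(self, point, rng: np.random.Generator | None = None):
        """Evaluate at ``point`` (``(d,)`` or ``(n, d)``).

        Parameters
        ----------
        point : array-like
            Query point(s).  Must lie inside the search box.
        rng : numpy.random.Generator, optional
            Noise source for the stochastic quartic function (``F7``).  When
            omitted the noise term is zero and evaluation is deterministic.

        Returns
        -------
        float or ndarray
            Objective value(s); scalar for a single point.
        """
        x = np.asarray(point, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.ndim != 2 or X.shape[1] != self.dimension:
            raise ContractError(
                f"{self.id}: expected points of dimension {self.dimension}, "
                f"got shape {x.shape}"
            )
        if not np.isfinite(X).all():
            raise ContractError(f"{self.id}: non-finite coordinates in input")
        tol = 1e-9 * np.maximum(1.0, np.abs(self.bounds).max())
        if (X < self.lower - tol).any() or (X > self.upper + tol).any():
            raise ContractError(f"{self.id}: point outside search bounds")
        vals = self._fn(X)
        if self.stochastic and rng is not None:
            vals = vals + rng.random(X.shape[0])
        return float(vals[0]) if single else np.asarray(vals, dtype=float)

    __call__ = evaluate


def _box(lo: float, hi: float, d: int) -> np.ndarray:
    return np.tile(np.array([lo, hi], dtype=float), (d, 1))


# --- unimodal -------------------------------------------------------------

def _f1(X):  # sphere
    return (X ** 2).sum(axis=1)


def _f2(X):  # sum of |x| plus product of |x|
    A = np.abs(X)
    return A.sum(axis=1) + A.prod(axis=1)


def _f3(X):  # Schwefel 1.2, sum of squared partial sums
    return (np.cumsum(X, axis=1) ** 2).sum(axis=1)


def _f4(X):  # Schwefel 2.21, max |x_i|
    return np.abs(X).max(axis=1)


def _f5(X):  # Rosenbrock
    return (100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2 + (X[:, :-1] - 1) ** 2).sum(axis=1)


def _f6(X):  # step function
    return (np.floor(X + 0.5) ** 2).sum(axis=1)


def _f7(X):  # weighted quartic (noise added separately)
    d = X.shape[1]
    i = np.arange(1, d + 1)
    return (i * X ** 4).sum(axis=1)


# --- multimodal, scalable -------------------------------------------------

def _f8(X):  # Schwefel 2.26
    return (-X * np.sin(np.sqrt(np.abs(X)))).sum(axis=1)


def _f9(X):  # Rastrigin
    return (X ** 2 - 10.0 * np.cos(2 * np.pi * X) + 10.0).sum(axis=1)


def _f10(X):  # Ackley
    d = X.shape[1]
    s1 = (X ** 2).sum(axis=1) / d
    s2 = np.cos(2 * np.pi * X).sum(axis=1) / d
    return -20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e


def _f11(X):  # Griewank
    d = X.shape[1]
    i = np.sqrt(np.arange(1, d + 1))
    return (X ** 2).sum(axis=1) / 4000.0 - np.cos(X / i).prod(axis=1) + 1.0


def _u(X, a, k, m):
    out = np.zeros_like(X)
    hi = X > a
    lo = X < -a
    out[hi] = k * (X[hi] - a) ** m
    out[lo] = k * (-X[lo] - a) ** m
    return out


def _f12(X):  # penalized function 1
    d = X.shape[1]
    Y = 1.0 + (X + 1.0) / 4.0
    term = 10.0 * np.sin(np.pi * Y[:, 0]) ** 2
    term = term + (
        (Y[:, :-1] - 1) ** 2 * (1 + 10.0 * np.sin(np.pi * Y[:, 1:]) ** 2)
    ).sum(axis=1)
    term = term + (Y[:, -1] - 1) ** 2
    return np.pi / d * term + _u(X, 10.0, 100.0, 4).sum(axis=1)


def _f13(X):  # penalized function 2
    term = np.sin(3 * np.pi * X[:, 0]) ** 2
    term = term + (
        (X[:, :-1] - 1) ** 2 * (1 + np.sin(3 * np.pi * X[:, 1:]) ** 2)
    ).sum(axis=1)
    term = term + (X[:, -1] - 1) ** 2 * (1 + np.sin(2 * np.pi * X[:, -1]) ** 2)
    return 0.1 * term + _u(X, 5.0, 100.0, 4).sum(axis=1)


# --- fixed-dimension multimodal ------------------------------------------

_FOXHOLE_A = np.array(
    [
        np.tile([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
        np.repeat([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
    ]
)  # (2, 25)


def _f14(X):  # Shekel's foxholes
    # (n, 2, 25)
    diff = X[:, :, None] - _FOXHOLE_A[None, :, :]
    inner = (diff ** 6).sum(axis=1) + np.arange(1, 26)[None, :]
    return 1.0 / (1.0 / 500.0 + (1.0 / inner).sum(axis=1))


_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.16, 0.0844, 0.0627,
     0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16])


def _f15(X):  # Kowalik
    b = _KOWALIK_B[None, :]
    num = X[:, 0:1] * (b ** 2 + b * X[:, 1:2])
    den = b ** 2 + b * X[:, 2:3] + X[:, 3:4]
    return ((_KOWALIK_A[None, :] - num / den) ** 2).sum(axis=1)


def _f16(X):  # six-hump camel-back
    x, y = X[:, 0], X[:, 1]
    return (4 - 2.1 * x ** 2 + x ** 4 / 3.0) * x ** 2 + x * y + (-4 + 4 * y ** 2) * y ** 2


def _f17(X):  # Branin
    x, y = X[:, 0], X[:, 1]
    a, b, c = 1.0, 5.1 / (4 * np.pi ** 2), 5.0 / np.pi
    r, s, t = 6.0, 10.0, 1.0 / (8 * np.pi)
    return a * (y - b * x ** 2 + c * x - r) ** 2 + s * (1 - t) * np.cos(x) + s


def _f18(X):  # Goldstein-Price
    x, y = X[:, 0], X[:, 1]
    p = 1 + (x + y + 1) ** 2 * (19 - 14 * x + 3 * x ** 2 - 14 * y + 6 * x * y + 3 * y ** 2)
    q = 30 + (2 * x - 3 * y) ** 2 * (18 - 32 * x + 12 * x ** 2 + 48 * y - 36 * x * y + 27 * y ** 2)
    return p * q


_HART3_A = np.array([[3.0, 10, 30], [0.1, 10, 35], [3.0, 10, 30], [0.1, 10, 35]])
_HART3_P = np.array(
    [
        [0.3689, 0.1170, 0.2673],
        [0.4699, 0.4387, 0.7470],
        [0.1091, 0.8732, 0.5547],
        [0.03815, 0.5743, 0.8828],
    ]
)
_HART_C = np.array([1.0, 1.2, 3.0, 3.2])

_HART6_A = np.array(
    [
        [10, 3, 17, 3.5, 1.7, 8],
        [0.05, 10, 17, 0.1, 8, 14],
        [3, 3.5, 1.7, 10, 17, 8],
        [17, 8, 0.05, 10, 0.1, 14],
    ],
    dtype=float,
)
_HART6_P = 1e-4 * np.array(
    [
        [1312, 1696, 5569, 124, 8283, 5886],
        [2329, 4135, 8307, 3736, 1004, 9991],
        [2348, 1451, 3522, 2883, 3047, 6650],
        [4047, 8828, 8732, 5743, 1091, 381],
    ],
    dtype=float,
)


def _hartmann(A, P):
    def fn(X):
        # (n, 4, d) squared deviations
        diff = (X[:, None, :] - P[None, :, :]) ** 2
        expo = (A[None, :, :] * diff).sum(axis=2)
        return -(_HART_C[None, :] * np.exp(-expo)).sum(axis=1)

    return fn


_SHEKEL_A = np.array(
    [
        [4, 4, 4, 4],
        [1, 1, 1, 1],
        [8, 8, 8, 8],
        [6, 6, 6, 6],
        [3, 7, 3, 7],
        [2, 9, 2, 9],
        [5, 5, 3, 3],
        [8, 1, 8, 1],
        [6, 2, 6, 2],
        [7, 3.6, 7, 3.6],
    ],
    dtype=float,
)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(m):
    A = _SHEKEL_A[:m]
    c = _SHEKEL_C[:m]

    def fn(X):
        diff = ((X[:, None, :] - A[None, :, :]) ** 2).sum(axis=2)
        return -(1.0 / (diff + c[None, :])).sum(axis=1)

    return fn


# id -> (fn, default_dim, (lo, hi), known_min, stochastic, scalable)
_SPECS: dict[str, tuple] = {
    "F1": (_f1, 30, (-100, 100), 0.0, False, True),
    "F2": (_f2, 30, (-10, 10), 0.0, False, True),
    "F3": (_f3, 30, (-100, 100), 0.0, False, True),
    "F4": (_f4, 30, (-100, 100), 0.0, False, True),
    "F5": (_f5, 30, (-30, 30), 0.0, False, True),
    "F6": (_f6, 30, (-100, 100), 0.0, False, True),
    "F7": (_f7, 30, (-1.28, 1.28), 0.0, True, True),
    "F8": (_f8, 30, (-500, 500), -418.9829 * 30, False, True),
    "F9": (_f9, 30, (-5.12, 5.12), 0.0, False, True),
    "F10": (_f10, 30, (-32, 32), 0.0, False, True),
    "F11": (_f11, 30, (-600, 600), 0.0, False, True),
    "F12": (_f12, 30, (-50, 50), 0.0, False, True),
    "F13": (_f13, 30, (-50, 50), 0.0, False, True),
    "F14": (_f14, 2, (-65.536, 65.536), 0.998, False, False),
    "F15": (_f15, 4, (-5, 5), 0.00030, False, False),
    "F16": (_f16, 2, (-5, 5), -1.0316, False, False),
    "F17": (_f17, 2, (-5, 5), 0.398, False, False),
    "F18": (_f18, 2, (-2, 2), 3.0, False, False),
    "F19": (_hartmann(_HART3_A, _HART3_P), 3, (0, 1), -3.86, False, False),
    "F20": (_hartmann(_HART6_A, _HART6_P), 6, (0, 1), -3.32, False, False),
    "F21": (_shekel(5), 4, (0, 10), -10.1532, False, False),
    "F22": (_shekel(7), 4, (0, 10), -10.4028, False, False),
    "F23": (_shekel(10), 4, (0, 10), -10.5363, False, False),
}

FUNCTION_IDS = tuple(_SPECS)


def get_function(function_id: str, dimension: int | None = None) -> BenchmarkFunction:
    """Look up a benchmark by id, optionally at a reduced/alternate dimension.

    Only the scalable families (``F1``-``F13``) accept a ``dimension``
    override; the fixed-dimension functions reject one.  ``F8``'s known
    minimum scales with the dimension (Schwefel's function attains
    ``-418.9829 * d``).
    """
    try:
        fn, d0, (lo, hi), fmin, stoch, scalable = _SPECS[function_id]
    except KeyError:
        raise KeyError(f"unknown benchmark id {function_id!r}") from None
    d = d0
    if dimension is not None and dimension != d0:
        if not scalable:
            raise ContractError(f"{function_id} has fixed dimension {d0}")
        if dimension < 1 or (function_id in ("F5", "F12", "F13") and dimension < 2):
            raise ContractError(f"{function_id}: invalid dimension {dimension}")
        d = int(dimension)
        if function_id == "F8":
            fmin = -418.9829 * d
    return BenchmarkFunction(
        id=function_id,
        dimension=d,
        bounds=_box(lo, hi, d),
        known_min=float(fmin),
        _fn=fn,
        stochastic=stoch,
        scalable=scalable,
    )


def get_metadata(function_id: str) -> tuple[int, np.ndarray, float]:
    """Return ``(dimension, bounds, known_min)`` for a benchmark id."""
    f = get_function(function_id)
    return f.dimension, f.bounds, f.known_min


def evaluate(function_id: str, point, rng: np.random.Generator | None = None):
    """Convenience wrapper: evaluate benchmark ``function_id`` at ``point``."""
    return get_function(function_id).evaluate(point, rng=rng)


def metadata_table() -> "object":
    """Metadata for all functions as a pandas DataFrame (id-indexed)."""
    import pandas as pd

    rows = []
    for fid in FUNCTION_IDS:
        d, b, fmin = get_metadata(fid)
        rows.append(
            {
                "id": fid,
                "dimension": d,
                "lower": b[0, 0],
                "upper": b[0, 1],
                "known_min": fmin,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def _grid_points(bounds: np.ndarray, density: int) -> np.ndarray:
    axes = [np.linspace(lo, hi, density) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def reference_minimum(
    function_id: str,
    grid_density: int | None = None,
    refine_iterations: int = 400,
    dimension: int | None = None,
    max_grid_points: int = 4_000_000,
    n_starts: int = 5,
) -> tuple[np.ndarray, float]:
    """Deterministic oracle: dense-grid scan plus Nelder--Mead polish.

    Scans a regular ``grid_density``-per-axis lattice over the search box,
    keeps the ``n_starts`` best lattice points, polishes each with a
    bounded Nelder--Mead simplex (fixed iteration budget, no randomness) and
    returns the best ``(argmin, min)`` found.  Bit-for-bit reproducible for
    fixed settings.

    Raises
    ------
    BudgetError
        If the requested lattice exceeds ``max_grid_points``.
    """
    fn = get_function(function_id, dimension=dimension)
    d = fn.dimension
    if grid_density is None:
        grid_density = min(400, max(3, int(max_grid_points ** (1.0 / d))))
    if grid_density < 2:
        raise BudgetError(f"grid density {grid_density} too small")
    if grid_density ** d > max_grid_points:
        raise BudgetError(
            f"{function_id}: {grid_density}^{d} grid exceeds the "
            f"{max_grid_points}-point budget"
        )
    pts = _grid_points(fn.bounds, grid_density)
    vals = np.empty(len(pts))
    chunk = 200_000
    for s in range(0, len(pts), chunk):
        vals[s : s + chunk] = fn.evaluate(pts[s : s + chunk])
    order = np.argsort(vals, kind="stable")[:n_starts]

    best_x = pts[order[0]].copy()
    best_v = float(vals[order[0]])
    scipy_bounds = [(lo, hi) for lo, hi in fn.bounds]
    for i in order:
        res = minimize(
            lambda z: fn.evaluate(z),
            pts[i],
            method="Nelder-Mead",
            bounds=scipy_bounds,
            options={
                "maxiter": refine_iterations * d,
                "xatol": 1e-12,
                "fatol": 1e-12,
            },
        )
        x = np.clip(res.x, fn.lower, fn.upper)
        v = float(fn.evaluate(x))
        if v < best_v:
            best_x, best_v = x, v
    return best_x, best_v
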