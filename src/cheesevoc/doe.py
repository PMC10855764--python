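"""Central composite design and desirability optimization of HS-SPME.

The extraction optimization uses a two-factor face-centered central
composite design (axial distance alpha = 1, so axial points sit at the
factorial levels): 2^k factorial corners + 2k axial points + replicated
center points. Second-order response surfaces are fitted by ordinary
least squares to the total chromatographic area (Y1) and the number of
detected VOCs (Y2); each predicted response is mapped to a Derringer
desirability d_i in [0, 1] and the global desirability D — the geometric
mean of the d_i — is maximized over the factor domain on a regular grid.
Fiber coatings are compared by a dominance rule on Y2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, SingularFitError


@dataclass(frozen=True)
class Factor:
    """One experimental factor with its three coded levels in natural units."""

    name: str
    low: float
    mid: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ConfigurationError(
                f"factor {self.name!r} needs low < mid < high"
            )
        if not np.isclose(self.mid, 0.5 * (self.low + self.high)):
            raise ConfigurationError(
                f"factor {self.name!r}: face-centered coding requires "
                "mid = (low + high) / 2"
            )

    def decode(self, coded: np.ndarray) -> np.ndarray:
        """Coded level in [-1, +1] -> natural units."""
        return self.mid + np.asarray(coded, dtype=float) * (self.high - self.mid)

    def encode(self, natural: np.ndarray) -> np.ndarray:
        return (np.asarray(natural, dtype=float) - self.mid) / (
            self.high - self.mid
        )


#: The extraction factors of the study: temperature 30/40/50 degC and
#: time 20/40/60 min.
STUDY_FACTORS = (
    Factor("temperature_c", 30.0, 40.0, 50.0),
    Factor("time_min", 20.0, 40.0, 60.0),
)


@dataclass(frozen=True)
class CCDesign:
    """A face-centered central composite design in coded units."""

    coded_runs: np.ndarray  # runs x k, levels in {-1, 0, +1}
    n_center: int
    run_order: tuple[int, ...]

    @property
    def n_runs(self) -> int:
        return self.coded_runs.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coded_runs.shape[1]


def generate_ccd(
    factors: Sequence[Factor], n_center: int = 3
) -> CCDesign:
    """Build a face-centered CCD: 2^k corners + 2k axial + n_center centers."""
    k = len(factors)
    if k < 2:
        raise ConfigurationError("CCD needs at least two factors")
    if n_center < 1:
        raise ConfigurationError("need at least one center point")
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -1.0
        axial[2 * j + 1, j] = 1.0
    centers = np.zeros((n_center, k))
    coded = np.vstack([corners, axial, centers])
    return CCDesign(
        coded_runs=coded,
        n_center=n_center,
        run_order=tuple(range(1, len(coded) + 1)),
    )


def decode(design: CCDesign, factors: Sequence[Factor]) -> pd.DataFrame:
    """Decode a design to natural units (-1 -> low, 0 -> mid, +1 -> high)."""
    if design.n_factors != len(factors):
        raise DataError("design and factor list disagree on k")
    coded = design.coded_runs
    if not np.isin(coded, (-1.0, 0.0, 1.0)).all():
        raise DataError("coded levels must be -1, 0 or +1")
    cols = {
        f.name: f.decode(coded[:, j]) for j, f in enumerate(factors)
    }
    return pd.DataFrame(cols, index=pd.Index(design.run_order, name="run"))


def _model_matrix(coded: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Full second-order model matrix: 1, linear, interactions, quadratics."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    k = coded.shape[1]
    cols = [np.ones(len(coded))]
    names = ["intercept"]
    for j in range(k):
        cols.append(coded[:, j])
        names.append(f"x{j + 1}")
    for a, b in itertools.combinations(range(k), 2):
        cols.append(coded[:, a] * coded[:, b])
        names.append(f"x{a + 1}:x{b + 1}")
    for j in range(k):
        cols.append(coded[:, j] ** 2)
        names.append(f"x{j + 1}^2")
    return np.column_stack(cols), names


@dataclass(frozen=True)
class QuadraticSurface:
    """A fitted (or known-truth) full second-order response surface.

    Coefficients are in coded units, ordered intercept, linear terms,
    pairwise interactions, quadratic terms (1 + 2k + k(k-1)/2 in total).
    """

    coefficients: np.ndarray
    n_factors: int
    term_names: tuple[str, ...] = ()
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        k = self.n_factors
        expected = 1 + 2 * k + k * (k - 1) // 2
        if len(self.coefficients) != expected:
            raise ConfigurationError(
                f"quadratic in {k} factors needs {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def predict(self, coded: np.ndarray) -> np.ndarray:
        X, _ = _model_matrix(np.atleast_2d(coded))
        return X @ self.coefficients


def fit_response_surface(
    design: CCDesign, response: Sequence[float]
) -> QuadraticSurface:
    """OLS fit of the full quadratic in coded units, with R^2."""
    y = np.asarray(response, dtype=float)
    if len(y) != design.n_runs:
        raise DataError(
            f"{len(y)} responses for {design.n_runs} runs"
        )
    X, names = _model_matrix(design.coded_runs)
    if len(y) < X.shape[1]:
        raise SingularFitError("fewer runs than model coefficients")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("rank-deficient model matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
    return QuadraticSurface(
        coefficients=beta,
        n_factors=design.n_factors,
        term_names=tuple(names),
        fit_r2=r2,
    )


@dataclass(frozen=True)
class DesirabilitySpec:
    """Derringer larger-is-better desirability of one response.

    d = 0 below ``lower``, 1 above ``upper`` and
    ``((value - lower)/(upper - lower))**s`` in between.
    """

    lower: float
    upper: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError("desirability needs lower < upper")
        if self.s <= 0:
            raise ConfigurationError("desirability exponent must be positive")


def desirability(value, spec: DesirabilitySpec) -> np.ndarray | float:
    """Map response value(s) to [0, 1] per the spec. Total on the reals."""
    v = np.asarray(value, dtype=float)
    ramp = np.clip((v - spec.lower) / (spec.upper - spec.lower), 0.0, 1.0)
    d = ramp**spec.s
    return float(d) if np.isscalar(value) else d


def global_desirability(d_values: Sequence[float]) -> float:
    """Geometric mean of the individual desirabilities; 0 vetoes."""
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise DataError("no desirabilities to combine")
    if ((d < 0) | (d > 1)).any():
        raise DataError("desirabilities must lie in [0, 1]")
    if (d == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(d))))


def default_spec_for_surface(
    surface: QuadraticSurface,
    factors: Sequence[Factor],
    resolution: int = 201,
    s: float = 1.0,
) -> DesirabilitySpec:
    """Bounds spanning the surface's own range over the design domain.

    Makes d_i sweep the full [0, 1] on the explored region — the natural
    choice when no target values are externally imposed.
    """
    grid = _natural_grid(factors, resolution)
    coded = np.column_stack(
        [f.encode(grid[:, j]) for j, f in enumerate(factors)]
    )
    pred = surface.predict(coded)
    lo, hi = float(pred.min()), float(pred.max())
    if np.isclose(lo, hi):
        hi = lo + 1.0  # flat surface: any spec gives d = const
    return DesirabilitySpec(lower=lo, upper=hi, s=s)


def _natural_grid(factors: Sequence[Factor], resolution: int) -> np.ndarray:
    if resolution < 2:
        raise ConfigurationError("grid resolution must be at least 2")
    axes = [np.linspace(f.low, f.high, resolution) for f in factors]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


@dataclass(frozen=True)
class DOMResult:
    """Outcome of desirability optimization."""

    optimum: dict[str, float]  # natural units per factor
    d_max: float
    d_individual: tuple[float, ...]
    tie: bool = False


def optimize_dom(
    surfaces: Sequence[QuadraticSurface],
    specs: Sequence[DesirabilitySpec],
    factors: Sequence[Factor],
    resolution: int = 201,
) -> DOMResult:
    """Exhaustive grid maximization of global desirability D.

    Evaluates D on a ``resolution``-per-axis regular grid over the natural
    factor domain and returns the argmax; exact ties are broken by the
    first point in row-major scan order and flagged.
    """
    if len(surfaces) != len(specs):
        raise ConfigurationError("one desirability spec per surface required")
    for s in surfaces:
        if s.n_factors != len(factors):
            raise ConfigurationError("surface/factor dimension mismatch")
    grid = _natural_grid(factors, resolution)
    coded = np.column_stack(
        [f.encode(grid[:, j]) for j, f in enumerate(factors)]
    )
    d_cols = np.column_stack(
        [desirability(s.predict(coded), spec) for s, spec in zip(surfaces, specs)]
    )
    with np.errstate(divide="ignore"):
        D = np.where(
            (d_cols == 0).any(axis=1),
            0.0,
            np.exp(np.mean(np.log(np.maximum(d_cols, 1e-300)), axis=1)),
        )
    best = int(np.argmax(D))
    tie = bool((D == D[best]).sum() > 1)
    if tie:
        warnings.warn(
            "global desirability has multiple maxima; returning the first "
            "grid point in row-major order",
            stacklevel=2,
        )
    return DOMResult(
        optimum={f.name: float(grid[best, j]) for j, f in enumerate(factors)},
        d_max=float(D[best]),
        d_individual=tuple(float(v) for v in d_cols[best]),
        tie=tie,
    )


@dataclass(frozen=True)
class FiberComparison:
    selected: str
    dominant: bool
    tie: bool
    mean_y2: dict[str, float]


def compare_fibers(y2_by_fiber: Mapping[str, Sequence[float]]) -> FiberComparison:
    """Select the fiber with the higher VOC count (Y2) across runs.

    Returns the fiber whose Y2 is >= the other's on every run when one
    exists (dominance, the rule used to pick Carboxen/PDMS); otherwise the
    fiber with the higher mean Y2, flagged as non-dominant.
    """
    labels = list(y2_by_fiber)
    if len(labels) != 2:
        raise DataError("fiber comparison expects exactly two fibers")
    a, b = (np.asarray(y2_by_fiber[lab], dtype=float) for lab in labels)
    if a.shape != b.shape:
        raise DataError("fibers measured on different run sets")
    means = {labels[0]: float(a.mean()), labels[1]: float(b.mean())}
    if (a == b).all():
        return FiberComparison(labels[0], dominant=True, tie=True, mean_y2=means)
    if (a >= b).all():
        return FiberComparison(labels[0], dominant=True, tie=False, mean_y2=means)
    if (b >= a).all():
        return FiberComparison(labels[1], dominant=True, tie=False, mean_y2=means)
    winner = labels[0] if means[labels[0]] >= means[labels[1]] else labels[1]
    return FiberComparison(winner, dominant=False, tie=False, mean_y2=means)
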