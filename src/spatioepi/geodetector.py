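"""GeoDetector: stratified-heterogeneity factor, interaction, and sensitivity analysis.

The q-statistic measures how much of an outcome's variance a categorical
stratification explains:

    q = 1 - SSW / SST,   SSW = sum_h N_h * sigma_h^2,  SST = N * sigma^2

(population variances; the ratio is invariant to the sample/population
convention).  q = 0 means the strata carry no information about y; q = 1
means y is constant within every stratum.  Significance follows the
noncentral-F test of the canonical GeoDetector framework.

Continuous covariates are discretized first (equal interval, geometric
interval, natural breaks, quantile); the optimal method/class-count pair is
the one maximizing q.  Pairwise interactions are classified by comparing
q(X1, X2) on the overlay (cross-classification) of two stratifications with
q(X1), q(X2) and their sum.  A perturbation-based sensitivity analysis
quantifies how fragile the detected q values are to small data fluctuations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CrossSection, PanelDataset, bin_years

__all__ = [
    "Stratification",
    "QResult",
    "InteractionResult",
    "SensitivityResult",
    "discretize",
    "jenks_breaks",
    "q_statistic",
    "optimal_discretization",
    "interaction_detect",
    "overlay",
    "factor_screen",
    "sensitivity_analysis",
    "DISCRETIZE_METHODS",
]

#: Search order; also the deterministic tie-break order.
DISCRETIZE_METHODS = ("equal_interval", "geometric", "natural_breaks", "quantile")

#: |q12 - (q1 + q2)| below this is classified "independent".
INDEPENDENCE_TOL = 0.01


@dataclass
class Stratification:
    factor_name: str
    labels: np.ndarray
    n_strata: int
    method: str = "given"
    n_classes_requested: int = 0
    edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        uniq = np.unique(self.labels)
        self.n_strata = len(uniq)
        if self.n_classes_requested and self.n_strata > self.n_classes_requested:
            raise ValueError("more strata than requested classes")


@dataclass
class QResult:
    q: float
    ssw: float
    sst: float
    F_stat: float
    lambda_nc: float
    p: float
    N: int
    L: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.q <= 1 + 1e-12:
            raise ValueError(f"q = {self.q} outside [0, 1]")


@dataclass
class InteractionResult:
    factor1: str
    factor2: str
    q1: float
    q2: float
    q12: float
    category: str


@dataclass
class SensitivityResult:
    per_factor: dict[str, float]
    mean_rel_change: float
    perturb_fraction: float
    n_replicates: int
    seed: int
    skipped: list[str] = field(default_factory=list)

    @property
    def stable(self) -> bool:
        """True when the mean relative q change stays under the 10% threshold."""
        return self.mean_rel_change < 0.10


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def jenks_breaks(x: np.ndarray, n_classes: int) -> np.ndarray:
    """Natural-breaks (Fisher-Jenks) class edges minimizing within-class SSD.

    Dynamic program over the sorted values; exact, deterministic.  Returns
    ``n_classes + 1`` edges with internal edges at midpoints between adjacent
    class-boundary values.
    """
    v = np.sort(np.asarray(x, dtype=float))
    n = len(v)
    k = min(n_classes, len(np.unique(v)))
    if k < 2:
        raise ValueError("not enough distinct values for natural breaks")
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v**2)])

    def ssd(a: np.ndarray, b: int) -> np.ndarray:
        # within-class sum of squared deviations of v[a:b] (vector over a)
        cnt = b - a
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s**2 / cnt

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    idx = np.arange(n + 1)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            a = idx[c - 1 : j]
            tot = cost[c - 1, c - 1 : j] + ssd(a, j)
            m = int(np.argmin(tot))
            cost[c, j] = tot[m]
            back[c, j] = a[m]
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b_0 < b_1 < ... < b_k = n
    edges = [v[0]]
    for b in bounds[1:-1]:
        edges.append(0.5 * (v[b - 1] + v[b]))
    edges.append(v[-1])
    return np.asarray(edges)


def _method_edges(x: np.ndarray, method: str, n_classes: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if method == "equal_interval":
        return np.linspace(lo, hi, n_classes + 1)
    if method == "quantile":
        return np.quantile(x, np.linspace(0, 1, n_classes + 1))
    if method == "natural_breaks":
        return jenks_breaks(x, n_classes)
    if method == "geometric":
        shift = 0.0 if lo > 0 else 1.0 - lo
        a, b = lo + shift, hi + shift
        if a <= 0:
            raise ValueError("geometric intervals need a positive (shifted) range")
        r = (b / a) ** (1.0 / n_classes)
        return a * r ** np.arange(n_classes + 1) - shift
    raise ValueError(f"unknown discretization method {method!r}")


def discretize(x, method: str, n_classes: int, factor_name: str = "") -> Stratification:
    """Bin a continuous covariate into ordered classes.

    Empty classes (possible with skewed data under equal or geometric
    intervals) are dropped and the realized stratum count adjusted, so the
    result always has consecutively labeled non-empty strata.
    """
    if isinstance(x, CrossSection):
        factor_name = factor_name or x.label
        x = x.values
    x = np.asarray(x, dtype=float)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate cannot be discretized")
    edges = _method_edges(x, method, n_classes)
    labels = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    # relabel to consecutive ints, dropping empty classes
    uniq = np.unique(labels)
    remap = {int(u): i for i, u in enumerate(uniq)}
    labels = np.array([remap[int(l)] for l in labels])
    return Stratification(
        factor_name=factor_name,
        labels=labels,
        n_strata=len(uniq),
        method=method,
        n_classes_requested=n_classes,
        edges=edges,
    )


# ---------------------------------------------------------------------------
# q-statistic
# ---------------------------------------------------------------------------

def _as_labels(strata) -> np.ndarray:
    return strata.labels if isinstance(strata, Stratification) else np.asarray(strata)


def q_statistic(y, strata) -> QResult:
    """Factor-detector q with noncentral-F significance.

    ``y`` may be an array or a :class:`CrossSection`; ``strata`` a
    :class:`Stratification` or a raw label vector.  The F statistic is

        F = (N - L) / (L - 1) * q / (1 - q)

    referred to a noncentral F(L-1, N-L; lambda) with

        lambda = [sum_h ybar_h^2 - (sum_h sqrt(N_h) ybar_h)^2 / N] / sigma^2.
    """
    if isinstance(y, CrossSection):
        y = y.values
    y = np.asarray(y, dtype=float)
    labels = _as_labels(strata)
    if len(y) != len(labels):
        raise ValueError("y and strata must be aligned")
    N = len(y)
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    L = len(uniq)
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0:
        raise ValueError("y has zero variance")
    if L < 2:
        warnings.warn("single stratum: q = 0 by convention")
        return QResult(0.0, sst, sst, 0.0, 0.0, 1.0, N, 1)
    means = np.bincount(inv, weights=y) / counts
    ssw = float(np.sum((y - means[inv]) ** 2))
    q = 1.0 - ssw / sst
    sigma2 = sst / N
    lam = float(
        (np.sum(means**2) - (np.sum(np.sqrt(counts) * means)) ** 2 / N) / sigma2
    )
    lam = max(lam, 0.0)
    if q >= 1.0 - 1e-15:
        F = np.inf
        p = 0.0
    else:
        F = (N - L) / (L - 1) * q / (1.0 - q)
        p = float(stats.ncf.sf(F, L - 1, N - L, lam))
    return QResult(float(q), ssw, sst, float(F), lam, p, N, L)


def optimal_discretization(
    x,
    y,
    methods=DISCRETIZE_METHODS,
    class_range: tuple[int, int] = (3, 8),
) -> tuple[Stratification, QResult, pd.DataFrame]:
    """Search (method, n_classes) for the stratification maximizing q.

    Ties break deterministically: higher q, then fewer classes, then method
    order as in :data:`DISCRETIZE_METHODS`.  Returns the winning
    stratification, its QResult, and the full comparison table.
    """
    lo, hi = class_range
    if not (2 <= lo <= hi <= 12):
        raise ValueError("class_range must lie within [2, 12]")
    rows = []
    candidates = {}
    for n_classes in range(lo, hi + 1):
        for method in methods:
            try:
                s = discretize(x, method, n_classes)
                if s.n_strata < 2:
                    continue
                qr = q_statistic(y, s)
            except ValueError:
                continue
            rows.append((method, n_classes, s.n_strata, qr.q, qr.p))
            candidates[(method, n_classes)] = (s, qr)
    if not candidates:
        raise ValueError("no valid discretization candidate (constant covariate?)")
    table = pd.DataFrame(rows, columns=["method", "n_classes", "n_strata", "q", "p"])
    method_rank = {m: i for i, m in enumerate(DISCRETIZE_METHODS)}
    best_key = min(
        candidates,
        key=lambda k: (-candidates[k][1].q, k[1], method_rank.get(k[0], 99)),
    )
    s, qr = candidates[best_key]
    return s, qr, table


# ---------------------------------------------------------------------------
# Interaction detector
# ---------------------------------------------------------------------------

def overlay(s1: Stratification, s2: Stratification) -> Stratification:
    """Cross-classification of two stratifications; empty cells never appear
    because cells are defined by the observed label pairs."""
    l1, l2 = _as_labels(s1), _as_labels(s2)
    if len(l1) != len(l2):
        raise ValueError("stratifications cover different records")
    pairs = np.stack([l1, l2], axis=1)
    _, joint = np.unique(pairs, axis=0, return_inverse=True)
    name = f"{getattr(s1, 'factor_name', 'A')}*{getattr(s2, 'factor_name', 'B')}"
    return Stratification(name, joint, int(joint.max()) + 1)


def classify_interaction(q1: float, q2: float, q12: float, tol: float = INDEPENDENCE_TOL) -> str:
    """Interaction category from the three q values.

    The independence check (|q12 - (q1+q2)| <= tol) runs first because exact
    equality never holds in floating point; the inequality rules follow:
    q12 > q1 + q2 nonlinear enhancement, q12 > max bilinear enhancement,
    q12 < min nonlinear weakening, otherwise unilateral weakening.
    """
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "enhance_nonlinear"
    if q12 > max(q1, q2):
        return "enhance_bilinear"
    if q12 < min(q1, q2):
        return "weaken_nonlinear"
    return "weaken_unilateral"


def interaction_detect(y, s1: Stratification, s2: Stratification, tol: float = INDEPENDENCE_TOL) -> InteractionResult:
    """q of the overlay of two factors, classified per the enhancement/weakening rules."""
    ov = overlay(s1, s2)
    if ov.n_strata < 2:
        raise ValueError("overlay leaves fewer than 2 non-empty cells")
    q1 = q_statistic(y, s1).q
    q2 = q_statistic(y, s2).q
    q12 = q_statistic(y, ov).q
    return InteractionResult(
        factor1=s1.factor_name,
        factor2=s2.factor_name,
        q1=q1,
        q2=q2,
        q12=q12,
        category=classify_interaction(q1, q2, q12, tol),
    )


# ---------------------------------------------------------------------------
# Panel-level screening and sensitivity
# ---------------------------------------------------------------------------

def _window_data(panel: PanelDataset, factors, bin_width, pooled):
    """Yield (label, y values, {factor: x values}) per analysis window."""
    outs = bin_years(panel, bin_width)
    year_windows = []
    years = panel.years
    for start in range(int(years[0]), int(years[-1]) + 1, bin_width):
        year_windows.append(list(range(start, start + bin_width)))
    for sec, win in zip(outs, year_windows):
        xs = {
            f: panel.covariate_section(f, win).reindex(sec.unit_ids).values
            for f in factors
        }
        yield sec.label, sec.values, xs
    if pooled:
        from .panel import cumulative

        sec = cumulative(panel, op="mean")
        xs = {
            f: panel.covariate_section(f).reindex(sec.unit_ids).values
            for f in factors
        }
        yield "overall", sec.values, xs


def factor_screen(
    panel: PanelDataset,
    factors: list[str] | None = None,
    alpha: float = 0.05,
    *,
    bin_width: int = 5,
    methods=DISCRETIZE_METHODS,
    class_range: tuple[int, int] = (3, 8),
    pooled: bool = True,
) -> pd.DataFrame:
    """Per-window factor detection: optimal discretization, q, p, and ranking.

    Each window analyzes the window-mean outcome against window-mean
    covariates across units; ``pooled`` adds a whole-period row set using
    full-span means.  Rank 1 is the strongest factor in its window.
    """
    factors = list(factors or panel.covariate_names)
    rows = []
    for label, yv, xs in _window_data(panel, factors, bin_width, pooled):
        for f in factors:
            s, qr, _ = optimal_discretization(xs[f], yv, methods, class_range)
            rows.append(
                {
                    "window": label,
                    "factor": f,
                    "q": qr.q,
                    "p": qr.p,
                    "method": s.method,
                    "n_classes": s.n_strata,
                    "significant": qr.p < alpha,
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = out.groupby("window")["q"].rank(ascending=False, method="min").astype(int)
    return out.sort_values(["window", "rank"]).reset_index(drop=True)


def interaction_matrix(
    panel: PanelDataset,
    factors: list[str] | None = None,
    *,
    years: list[int] | None = None,
    methods=DISCRETIZE_METHODS,
    class_range: tuple[int, int] = (3, 8),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise interactions on per-unit mean values over ``years``.

    Returns (q matrix with single-factor q on the diagonal and joint q off
    the diagonal, long-format category table).
    """
    factors = list(factors or panel.covariate_names)
    from .panel import cumulative

    if years is None:
        sec = cumulative(panel, op="mean")
        yearset = None
    else:
        sub = PanelDataset(
            panel.df[panel.df["year"].isin(years)].copy(), panel.covariate_names
        )
        sec = cumulative(sub, op="mean")
        yearset = years
    yv = sec.values
    stratifications = {}
    for f in factors:
        xv = panel.covariate_section(f, yearset).reindex(sec.unit_ids).values
        s, _, _ = optimal_discretization(xv, yv, methods, class_range)
        s.factor_name = f
        stratifications[f] = s
    qmat = pd.DataFrame(np.nan, index=factors, columns=factors)
    rows = []
    for f in factors:
        qmat.loc[f, f] = q_statistic(yv, stratifications[f]).q
    for f1, f2 in itertools.combinations(factors, 2):
        res = interaction_detect(yv, stratifications[f1], stratifications[f2])
        qmat.loc[f1, f2] = qmat.loc[f2, f1] = res.q12
        rows.append(
            {
                "factor1": f1,
                "factor2": f2,
                "q1": res.q1,
                "q2": res.q2,
                "q12": res.q12,
                "category": res.category,
            }
        )
    return qmat, pd.DataFrame(rows)


def sensitivity_analysis(
    panel: PanelDataset,
    factors: list[str] | None = None,
    perturb_fraction: float = 0.10,
    n_replicates: int = 20,
    seed: int = 0,
    *,
    methods=DISCRETIZE_METHODS,
    class_range: tuple[int, int] = (3, 8),
    refit_edges: bool = True,
) -> SensitivityResult:
    """Perturbation robustness of the factor-detector q values.

    Each covariate is multiplied elementwise by (1 + u) with
    u ~ Uniform(-perturb_fraction, +perturb_fraction); q is recomputed on the
    perturbed covariate (the winning method/class-count is frozen from the
    baseline; with ``refit_edges`` the bin edges are re-fitted on perturbed
    data so classification sensitivity propagates).  The per-factor relative
    change |q' - q| / q is averaged over replicates, and the overall mean is
    compared against the 10% stability threshold by ``result.stable``.
    """
    if perturb_fraction < 0:
        raise ValueError("perturb_fraction must be >= 0")
    factors = list(factors or panel.covariate_names)
    from .panel import cumulative

    sec = cumulative(panel, op="mean")
    yv = sec.values
    rng = np.random.default_rng(seed)
    per_factor: dict[str, float] = {}
    skipped: list[str] = []
    for f in factors:
        xv = panel.covariate_section(f).reindex(sec.unit_ids).values
        s0, qr0, _ = optimal_discretization(xv, yv, methods, class_range)
        if qr0.q == 0:
            warnings.warn(f"factor {f!r}: baseline q = 0; relative change undefined, skipped")
            skipped.append(f)
            continue
        rel = []
        for _ in range(n_replicates):
            u = rng.uniform(-perturb_fraction, perturb_fraction, size=len(xv))
            xp = xv * (1.0 + u)
            if refit_edges:
                try:
                    sp = discretize(xp, s0.method, s0.n_classes_requested, f)
                except ValueError:
                    rel.append(0.0)
                    continue
            else:
                labels = np.clip(
                    np.searchsorted(s0.edges, xp, side="right") - 1,
                    0,
                    len(s0.edges) - 2,
                )
                sp = Stratification(f, labels, len(np.unique(labels)))
            qp = q_statistic(yv, sp).q
            rel.append(abs(qp - qr0.q) / qr0.q)
        per_factor[f] = float(np.mean(rel))
    if not per_factor:
        raise ValueError("no factor with nonzero baseline q")
    return SensitivityResult(
        per_factor=per_factor,
        mean_rel_change=float(np.mean(list(per_factor.values()))),
        perturb_fraction=perturb_fraction,
        n_replicates=n_replicates,
        seed=seed,
        skipped=skipped,
    )
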