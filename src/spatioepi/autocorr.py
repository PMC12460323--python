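"""Global Moran's I and Getis-Ord Gi* hot/cold-spot statistics.

Moran's I summarizes the overall spatial autocorrelation of a surface:

    I = (N / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the total weight.  Inference defaults to the randomization
assumption (values permuted over units); a conditional permutation test is
available as a distribution-free alternative.  A z-score above 2.58 flags
clustering significant at the 99% confidence level.

Gi* is the local, self-inclusive counterpart: each unit's z-score compares
the sum over its neighborhood (itself included) with the global mean, flagging
clusters of high values (hot spots) or low values (cold spots), binned at the
90/95/99% two-sided thresholds 1.645 / 1.960 / 2.576.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CrossSection
from .weights import SpatialWeights, row_standardize

__all__ = [
    "MoranResult",
    "GiStarResult",
    "global_morans_i",
    "morans_permutation",
    "getis_ord_gistar",
    "hotspot_persistence",
    "BIN_THRESHOLDS",
]

#: Two-sided z thresholds for the 90 / 95 / 99% confidence classes.
BIN_THRESHOLDS = {"90": 1.645, "95": 1.960, "99": 2.576}


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z: float
    p_analytic: float
    significant: bool
    n: int
    label: str = ""
    p_perm: float | None = None
    n_perm: int | None = None


@dataclass
class GiStarResult:
    unit_ids: list
    z: np.ndarray
    p: np.ndarray
    bin: list[str]
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_ids, "z": self.z, "p": self.p, "bin": self.bin}
        )


def _aligned_values(x: CrossSection, W: SpatialWeights) -> np.ndarray:
    return x.reindex(W.unit_ids).values


def _moran_numerator_terms(W: SpatialWeights):
    Wd = W.to_dense()
    S0 = Wd.sum()
    if S0 == 0:
        raise ValueError("weights have no edges (all islands)")
    S1 = 0.5 * np.sum((Wd + Wd.T) ** 2)
    S2 = np.sum((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2)
    return Wd, float(S0), float(S1), float(S2)


def global_morans_i(
    x: CrossSection,
    W: SpatialWeights,
    significance_z: float = 2.58,
    *,
    standardize: bool = True,
    variance: str = "randomization",
) -> MoranResult:
    """Global Moran's I with analytic (randomization-assumption) inference.

    ``standardize`` row-standardizes the weights first (the default
    convention; it makes the checkerboard identity I = -1 exact on a regular
    lattice).  ``variance`` selects the randomization or normality null
    variance.  The ``significant`` flag applies the one-sided clustering rule
    z > ``significance_z`` (default 2.58, the 99% confidence level).
    """
    if standardize and W.standardization != "row":
        W = row_standardize(W)
    vals = _aligned_values(x, W)
    N = len(vals)
    if N < 3:
        raise ValueError("need at least 3 units")
    z = vals - vals.mean()
    m2 = np.sum(z**2)
    if m2 == 0:
        raise ValueError("degenerate field: zero variance")
    Wd, S0, S1, S2 = _moran_numerator_terms(W)
    I = float(N / S0 * (z @ Wd @ z) / m2)
    EI = -1.0 / (N - 1)
    if variance == "randomization":
        b2 = N * np.sum(z**4) / m2**2
        num = N * ((N**2 - 3 * N + 3) * S1 - N * S2 + 3 * S0**2) - b2 * (
            (N**2 - N) * S1 - 2 * N * S2 + 6 * S0**2
        )
        VI = num / ((N - 1) * (N - 2) * (N - 3) * S0**2) - EI**2
    elif variance == "normality":
        VI = (N**2 * S1 - N * S2 + 3 * S0**2) / ((N**2 - 1) * S0**2) - EI**2
    else:
        raise ValueError(f"unknown variance assumption {variance!r}")
    if VI <= 0:
        raise ValueError("non-positive Moran variance (degenerate weights)")
    zscore = (I - EI) / np.sqrt(VI)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(
        I=I,
        expected_I=EI,
        variance_I=float(VI),
        z=float(zscore),
        p_analytic=float(p),
        significant=bool(zscore > significance_z),
        n=N,
        label=x.label,
    )


def morans_i_many(fields: np.ndarray, W: SpatialWeights, *, standardize: bool = True) -> np.ndarray:
    """Moran's I for each column of an (N, n_fields) matrix (shared weights)."""
    if standardize and W.standardization != "row":
        W = row_standardize(W)
    Wd = W.to_dense()
    S0 = Wd.sum()
    Z = fields - fields.mean(axis=0, keepdims=True)
    num = np.einsum("if,if->f", Z, Wd @ Z)
    den = np.sum(Z**2, axis=0)
    return fields.shape[0] / S0 * num / den


def morans_permutation(
    x: CrossSection,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    *,
    standardize: bool = True,
    alternative: str = "greater",
) -> float:
    """Permutation pseudo p-value for Moran's I.

    Values are shuffled over units ``n_perm`` times; the high-tail pseudo-p is
    (1 + #{I_perm >= I_obs}) / (1 + n_perm).  ``alternative="two-sided"``
    doubles the smaller tail.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if standardize and W.standardization != "row":
        W = row_standardize(W)
    vals = _aligned_values(x, W)
    if np.ptp(vals) == 0:
        raise ValueError("degenerate field: zero variance")
    rng = np.random.default_rng(seed)
    obs = global_morans_i(x, W, standardize=False).I
    perms = np.empty((len(vals), n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(vals)
    Is = morans_i_many(perms, W, standardize=False)
    p_hi = (1.0 + np.sum(Is >= obs)) / (1.0 + n_perm)
    if alternative == "greater":
        return float(p_hi)
    if alternative == "two-sided":
        p_lo = (1.0 + np.sum(Is <= obs)) / (1.0 + n_perm)
        return float(min(1.0, 2.0 * min(p_hi, p_lo)))
    raise ValueError(f"unknown alternative {alternative!r}")


def _bin_z(z: np.ndarray) -> list[str]:
    bins = []
    for zi in z:
        a = abs(zi)
        if a >= BIN_THRESHOLDS["99"]:
            cls = "99"
        elif a >= BIN_THRESHOLDS["95"]:
            cls = "95"
        elif a >= BIN_THRESHOLDS["90"]:
            cls = "90"
        else:
            bins.append("ns")
            continue
        bins.append(("hot" if zi > 0 else "cold") + cls)
    return bins


def getis_ord_gistar(
    x: CrossSection, W: SpatialWeights, *, row_standardized: bool = False
) -> GiStarResult:
    """Getis-Ord Gi* z-scores and confidence bins for every unit.

    Weights are binary contiguity with self-inclusion applied internally
    (the * variant); pass ``row_standardized=True`` for the row-scaled form.
    Per unit,

        z_i = (sum_j w_ij x_j - xbar * W_i) /
              (S * sqrt[(N * sum_j w_ij^2 - W_i^2) / (N - 1)])

    where sums include j = i with w_ii = 1, W_i = sum_j w_ij, and
    S = sqrt(sum_j x_j^2 / N - xbar^2).
    """
    Wstar = W.with_self()
    if row_standardized:
        Wstar = row_standardize(Wstar)
    vals = _aligned_values(x, Wstar)
    N = len(vals)
    if np.ptp(vals) == 0:
        raise ValueError("degenerate field: zero variance")
    for u in W.islands:
        warnings.warn(f"unit {u!r} has no neighbors; Gi* computed from self only")
    Wd = Wstar.to_dense()
    Wi = Wd.sum(axis=1)
    Wi2 = (Wd**2).sum(axis=1)
    xbar = vals.mean()
    S = np.sqrt(np.sum(vals**2) / N - xbar**2)
    lag = Wd @ vals
    denom_inner = (N * Wi2 - Wi**2) / (N - 1)
    z = np.where(
        denom_inner > 0,
        (lag - xbar * Wi) / (S * np.sqrt(np.maximum(denom_inner, 1e-300))),
        0.0,
    )
    p = 2.0 * stats.norm.sf(np.abs(z))
    return GiStarResult(list(Wstar.unit_ids), z, p, _bin_z(z), label=x.label)


def hotspot_persistence(sections: list[GiStarResult]) -> pd.DataFrame:
    """Tabulate per-unit hot/cold classes across time windows.

    Returns one row per unit with the bin in every window plus counts of
    windows classified hot or cold at each confidence class (a 99% count of 6
    over six windows is the signature of a structurally persistent hot spot).
    """
    if len(sections) < 2:
        raise ValueError("need at least 2 sections")
    base = list(sections[0].unit_ids)
    for s in sections[1:]:
        if set(s.unit_ids) != set(base):
            raise ValueError("sections cover different unit sets")
    table = pd.DataFrame(index=pd.Index(base, name="unit_id"))
    for k, s in enumerate(sections):
        col = s.label or f"window_{k}"
        table[col] = pd.Series(dict(zip(s.unit_ids, s.bin)))
    win_cols = list(table.columns)
    for side in ("hot", "cold"):
        for cls in ("90", "95", "99"):
            # count windows at *at least* this confidence, e.g. hot99 counts in hot90
            eligible = [side + c for c in ("90", "95", "99") if c >= cls]
            table[f"n_{side}{cls}"] = table[win_cols].isin(eligible).sum(axis=1)
    table["n_ns"] = (table[win_cols] == "ns").sum(axis=1)
    return table
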