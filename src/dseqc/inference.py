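"""Null-model estimation and the chi-squared test for squared DVARS.

Under temporal homogeneity the squared DVARS series has some mean mu0 and
variance sigma0_sq; matching moments to a scaled chi-squared gives the test
statistic X_t = (2 mu0 / sigma0_sq) DVARS_t^2 with nu = 2 mu0^2 / sigma0_sq
degrees of freedom.  Both moments are estimated robustly from the data with
quantile-based spread estimators, so that the very spikes being tested do
not corrupt the null.

All sample quantiles use linear interpolation (numpy's default); the
quantile rule matters for IQR-based estimates and is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DSETimeSeries

__all__ = [
    "IQR0",
    "HIQR0",
    "NullModel",
    "InferenceResult",
    "estimate_mu0",
    "estimate_sigma0_sq",
    "fit_null",
    "dvars_test",
    "z_scores",
    "standardized_variants",
    "flag_scans",
    "infer_dvars",
]

#: Interquartile range of the standard normal; divides a sample IQR to give
#: a robust standard-deviation estimate.
IQR0: float = float(stats.norm.ppf(0.75) - stats.norm.ppf(0.25))

#: Median minus first quartile of the standard normal (half IQR).
HIQR0: float = IQR0 / 2.0

_MU0_METHODS = ("mean_dvars2", "median_dvars2", "mean_voxel_sigmaD", "median_voxel_sigmaD")
_VAR_METHODS = ("sample", "iqr", "hiqr")
_D_EXPONENTS = (1.0, 0.5, 1.0 / 3.0, 0.25)


@dataclass
class NullModel:
    """Estimated null moments of squared DVARS and the implied chi-squared.

    ``nu = 2 mu0^2 / sigma0_sq`` acts as an effective number of independent
    spatial elements: it equals the voxel count under complete spatial
    independence and shrinks with spatial structure.  It is highly sensitive
    to the moment estimators used and is not meant for any purpose beyond
    this test (e.g. it is not a spatial Bonferroni factor).
    """

    mu0: float
    sigma0_sq: float
    mu0_method: str = "median_dvars2"
    var_method: str = "hiqr"
    d: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu0) and self.mu0 > 0):
            raise ValueError("mu0 must be positive and finite")
        if not (np.isfinite(self.sigma0_sq) and self.sigma0_sq > 0):
            raise ValueError("sigma0_sq must be positive and finite")

    @property
    def sigma0(self) -> float:
        return float(np.sqrt(self.sigma0_sq))

    @property
    def nu(self) -> float:
        return 2.0 * self.mu0**2 / self.sigma0_sq

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0,
            "sigma0_sq": self.sigma0_sq,
            "nu": self.nu,
            "mu0_method": self.mu0_method,
            "var_method": self.var_method,
            "d": self.d,
        }


def _robust_sd(x: np.ndarray, var_method: str) -> float:
    if var_method == "iqr":
        q1, q3 = np.quantile(x, [0.25, 0.75])
        return float((q3 - q1) / IQR0)
    if var_method == "hiqr":
        q1, q2 = np.quantile(x, [0.25, 0.5])
        return float((q2 - q1) / HIQR0)
    if var_method == "sample":
        return float(np.std(x, ddof=1))
    raise ValueError(f"unknown var_method {var_method!r}; choose from {_VAR_METHODS}")


def estimate_mu0(
    dvars_sq: np.ndarray,
    diffdata: np.ndarray | None = None,
    method: str = "median_dvars2",
) -> float:
    """Estimate the null mean of squared DVARS.

    ``median_dvars2`` (default) and ``mean_dvars2`` act directly on the
    squared-DVARS series.  The voxelwise methods estimate each voxel's
    differenced-data variance as ``(IQR(diff series)/IQR0)^2`` and average
    (mean or median) over voxels; they need ``diffdata``, the I x (T-1)
    matrix of temporal differences.

    Raises
    ------
    ValueError
        "degenerate null" when the relevant IQR (or the series itself)
        collapses to zero.
    """
    x = np.asarray(dvars_sq, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 scan pairs")
    if method == "mean_dvars2":
        mu0 = float(x.mean())
    elif method == "median_dvars2":
        mu0 = float(np.median(x))
    elif method in ("mean_voxel_sigmaD", "median_voxel_sigmaD"):
        if diffdata is None:
            raise ValueError(f"method {method!r} requires diffdata")
        diffdata = np.asarray(diffdata, dtype=float)
        q1, q3 = np.quantile(diffdata, [0.25, 0.75], axis=1)
        sigma_d_sq = ((q3 - q1) / IQR0) ** 2
        if np.all(sigma_d_sq == 0):
            raise ValueError("degenerate null: zero IQR in every differenced series")
        mu0 = float(sigma_d_sq.mean() if method == "mean_voxel_sigmaD"
                    else np.median(sigma_d_sq))
    else:
        raise ValueError(f"unknown mu0 method {method!r}; choose from {_MU0_METHODS}")
    if mu0 <= 0:
        raise ValueError("degenerate null: non-positive mu0 estimate")
    return mu0


def estimate_sigma0_sq(
    dvars_sq: np.ndarray,
    var_method: str = "hiqr",
    d: float = 1.0 / 3.0,
) -> float:
    """Estimate the null variance of squared DVARS.

    The series is power-transformed, X = (DVARS^2)^d, to bring it closer to
    normality before the quantile-based spread is taken; d = 1/3 is the
    cube-root normalizing transform for chi-squared-like variables.  The
    spread on the transformed scale is mapped back by the delta method:
    sigma0 = spread / (d * m^(d-1)) with m the series median on the original
    scale.

    With ``var_method="sample"`` the plain (non-robust) sample variance of
    the untransformed series is returned.

    Raises
    ------
    ValueError
        "degenerate null" when the spread estimate is zero.
    """
    x = np.asarray(dvars_sq, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 scan pairs for a spread estimate")
    if not any(np.isclose(d, ref) for ref in _D_EXPONENTS):
        raise ValueError(f"d must be one of {_D_EXPONENTS}")
    if var_method == "sample":
        s2 = float(np.var(x, ddof=1))
        if s2 <= 0:
            raise ValueError("degenerate null: zero sample variance")
        return s2

    xd = x**d
    spread = _robust_sd(xd, var_method)
    if spread <= 0:
        raise ValueError("degenerate null: zero spread in transformed series")
    if d == 1.0:
        sigma0 = spread
    else:
        m = float(np.median(x))
        if m <= 0:
            raise ValueError("degenerate null: non-positive median")
        sigma0 = spread / (d * m ** (d - 1.0))
    return float(sigma0**2)


def fit_null(
    dvars_sq: np.ndarray,
    diffdata: np.ndarray | None = None,
    mu0_method: str = "median_dvars2",
    var_method: str = "hiqr",
    d: float = 1.0 / 3.0,
) -> NullModel:
    """Estimate both null moments and bundle them into a :class:`NullModel`."""
    mu0 = estimate_mu0(dvars_sq, diffdata=diffdata, method=mu0_method)
    sigma0_sq = estimate_sigma0_sq(dvars_sq, var_method=var_method, d=d)
    return NullModel(mu0=mu0, sigma0_sq=sigma0_sq,
                     mu0_method=mu0_method, var_method=var_method, d=d)


def dvars_test(
    dvars_sq: np.ndarray,
    null: NullModel,
    two_sided: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Chi-squared test statistics and p-values for each scan pair.

    One-sided upper-tail by default (spikes); the two-sided variant doubles
    the smaller tail and can also pick up down-spikes.
    """
    x = np.asarray(dvars_sq, dtype=float)
    stat = (2.0 * null.mu0 / null.sigma0_sq) * x
    upper = stats.chi2.sf(stat, null.nu)
    if two_sided:
        lower = stats.chi2.cdf(stat, null.nu)
        p = np.minimum(2.0 * np.minimum(upper, lower), 1.0)
    else:
        p = upper
    return stat, p


def z_scores(
    p_values: np.ndarray,
    dvars_sq: np.ndarray,
    null: NullModel,
) -> np.ndarray:
    """Equivalent Z scores, Z = Phi^-1(1 - p).

    Where the chi-squared tail probability underflows to exactly zero the
    moment-based approximation (DVARS^2 - mu0)/sigma0 is substituted.
    """
    p = np.asarray(p_values, dtype=float)
    x = np.asarray(dvars_sq, dtype=float)
    fallback = (x - null.mu0) / null.sigma0
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p)
    return np.where(p > 0.0, z, fallback)


def standardized_variants(dse: DSETimeSeries, null: NullModel) -> pd.DataFrame:
    """Per-pair standardized DVARS variants.

    Columns: ``dvars`` (RMS of the differenced image), ``dvar`` (fast mean
    square D_t), ``sqrt_dvar``, ``pct_dvar`` (100 D_t / A), ``delta_pct_dvar``
    (excess fast variability over the null mean as % of average sum of
    squares) and ``rel_dvars`` (DVARS / sqrt(mu0)).
    """
    A = dse.averages("whole")["A"]
    if A <= 0:
        raise ValueError("total variability is zero; variants undefined")
    D = dse.D
    dvars_sq = 4.0 * D
    return pd.DataFrame({
        "dvars": np.sqrt(dvars_sq),
        "dvar": D,
        "sqrt_dvar": np.sqrt(D),
        "pct_dvar": 100.0 * D / A,
        "delta_pct_dvar": 100.0 * (dvars_sq - null.mu0) / (4.0 * A),
        "rel_dvars": np.sqrt(dvars_sq) / np.sqrt(null.mu0),
    })


def flag_scans(
    result: "InferenceResult",
    alpha: float = 0.05,
    correction: str = "bonferroni",
    delta_threshold: float = 5.0,
) -> pd.DataFrame:
    """Statistical and practical significance flags per scan pair.

    A pair is statistically significant when its p-value passes the
    Bonferroni-corrected level alpha/(T-1); practically significant when, in
    addition, the excess fast variability exceeds ``delta_threshold`` percent
    of average variability.  Practical flags are therefore a subset of
    statistical ones.  Returns a frame with 1-based pair indices ``t`` and
    ``t_next`` (the two scans involved).
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    tab = result.table
    n = len(tab)
    threshold = alpha / n
    stat = tab["p_value"].to_numpy() <= threshold
    prac = stat & (tab["delta_pct_dvar"].to_numpy() > delta_threshold)
    return pd.DataFrame({
        "t": np.arange(1, n + 1),
        "t_next": np.arange(2, n + 2),
        "flag_statistical": stat,
        "flag_practical": prac,
    })


def write_flag_list(result: "InferenceResult", path) -> None:
    """Write the statistically significant pairs as a small TSV.

    Each row names both scans of the pair (1-based), mirroring how flagged
    pairs are reported, plus the practical-significance flag and the key
    statistics.
    """
    tab = result.table
    sel = tab[tab["flag_statistical"]] if "flag_statistical" in tab else tab.iloc[:0]
    out = pd.DataFrame({
        "scan": sel["t"].astype(int),
        "scan_next": sel["t"].astype(int) + 1,
        "dvars": sel["dvars"],
        "delta_pct_dvar": sel["delta_pct_dvar"],
        "p_value": sel["p_value"],
        "z_score": sel["z_score"],
        "flag_practical": sel["flag_practical"] if "flag_practical" in sel else False,
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class InferenceResult:
    """Full per-pair inference table plus the null model that produced it.

    ``table`` has one row per scan pair t (1-based, pair = scans t, t+1)
    with the standardized variants, test statistic, p, Z and both flags.
    """

    table: pd.DataFrame
    null: NullModel
    alpha: float = 0.05
    delta_threshold: float = 5.0
    two_sided: bool = False

    @property
    def flagged_pairs(self) -> list[tuple[int, int]]:
        """(t, t+1) scan index pairs that are statistically significant."""
        sel = self.table[self.table.flag_statistical]
        return [(int(t), int(t) + 1) for t in sel["t"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def infer_dvars(
    dse: DSETimeSeries,
    diffdata: np.ndarray | None = None,
    mu0_method: str = "median_dvars2",
    var_method: str = "hiqr",
    d: float = 1.0 / 3.0,
    alpha: float = 0.05,
    delta_threshold: float = 5.0,
    two_sided: bool = False,
) -> InferenceResult:
    """End-to-end DVARS inference from a DSE decomposition."""
    dvars_sq = 4.0 * dse.D
    null = fit_null(dvars_sq, diffdata=diffdata, mu0_method=mu0_method,
                    var_method=var_method, d=d)
    stat, p = dvars_test(dvars_sq, null, two_sided=two_sided)
    z = z_scores(p, dvars_sq, null)
    tab = standardized_variants(dse, null)
    tab.insert(0, "t", np.arange(1, len(tab) + 1))
    tab["x_stat"] = stat
    tab["p_value"] = p
    tab["z_score"] = z
    result = InferenceResult(table=tab, null=null, alpha=alpha,
                             delta_threshold=delta_threshold, two_sided=two_sided)
    flags = flag_scans(result, alpha=alpha, delta_threshold=delta_threshold)
    tab["flag_statistical"] = flags["flag_statistical"].to_numpy()
    tab["flag_practical"] = flags["flag_practical"].to_numpy()
    return result
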