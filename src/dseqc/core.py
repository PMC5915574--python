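"""Scaling and DSE (D-var / S-var / E-var) sum-of-squares decomposition.

The decomposition splits the total sum of squares of an I x T data matrix
into a fast component built from half-differences of adjacent scans, a slow
component built from half-sums, and an edge component carrying the first and
last scans.  Each component further splits into the part explained by the
spatial (global) mean signal and the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "RawData",
    "ScaledData",
    "DSETimeSeries",
    "DSEImages",
    "IdentityReport",
    "scale_center",
    "compute_dse_timeseries",
    "compute_dse_images",
    "dvars_series",
    "verify_identities",
]

ScaleMode = Literal["median-of-means", "mean-of-means", "user-supplied", "none"]

_SCALE_MODES = ("median-of-means", "mean-of-means", "user-supplied", "none")


@dataclass
class RawData:
    """Raw I x T data matrix in arbitrary scanner units.

    Parameters
    ----------
    values : ndarray, shape (I, T)
        One row per retained voxel, one column per timepoint.
    voxel_ids : ndarray or None
        Flat spatial index of each row into the source volume; ``None`` for
        plain matrix input.
    geometry : dict or None
        Volume shape / affine / header needed to write images back out.
    """

    values: np.ndarray
    voxel_ids: np.ndarray | None = None
    geometry: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (voxels x time) matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.voxel_ids is not None:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if len(self.voxel_ids) != self.values.shape[0]:
                raise ValueError("voxel_ids length does not match row count")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ScaledData:
    """Centered (and optionally globally rescaled) data matrix.

    ``values`` has zero temporal mean in every row.  ``voxel_means`` and
    ``overall_mean`` record the centering/scaling constants so the transform
    is invertible.
    """

    values: np.ndarray
    voxel_means: np.ndarray
    overall_mean: float
    scale_mode: str
    excluded_voxels: list[tuple[int, str]] = field(default_factory=list)
    voxel_ids: np.ndarray | None = None
    geometry: dict | None = None

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def scale_center(
    raw: RawData,
    scale_mode: ScaleMode = "median-of-means",
    target: float = 100.0,
    overall_mean: float | None = None,
) -> ScaledData:
    """Center each voxel time series and rescale to a common grand mean.

    Every voxel is centered by its temporal mean; unless ``scale_mode`` is
    ``"none"`` the whole matrix is then divided by an overall mean intensity
    and multiplied by ``target`` so that typical pre-centering brain values
    sit near ``target`` regardless of scanner units.

    Voxels with any non-finite value or zero temporal variance are dropped
    (and recorded) before the overall mean is computed.

    Parameters
    ----------
    raw : RawData
    scale_mode : {"median-of-means", "mean-of-means", "user-supplied", "none"}
        How the overall mean intensity is obtained from the retained voxel
        means.  ``"user-supplied"`` requires ``overall_mean``.
    target : float
        Nominal grand-mean intensity after scaling (default 100).
    overall_mean : float, optional
        Externally supplied overall mean, used when
        ``scale_mode="user-supplied"``.

    Raises
    ------
    ValueError
        "empty mask" if every voxel is excluded; "bad scale" if the overall
        mean is non-positive or non-finite.
    """
    if scale_mode not in _SCALE_MODES:
        raise ValueError(f"unknown scale_mode {scale_mode!r}; choose from {_SCALE_MODES}")

    Y = raw.values
    excluded: list[tuple[int, str]] = []
    finite = np.isfinite(Y).all(axis=1)
    for i in np.flatnonzero(~finite):
        excluded.append((int(i), "non-finite value"))
    variance = np.zeros(Y.shape[0])
    variance[finite] = Y[finite].var(axis=1)
    constant = finite & (variance == 0.0)
    for i in np.flatnonzero(constant):
        excluded.append((int(i), "zero temporal variance"))

    keep = finite & ~constant
    if not keep.any():
        raise ValueError("empty mask: no voxels left after exclusion")

    Yk = Y[keep]
    means = Yk.mean(axis=1)

    if scale_mode == "none":
        m = 1.0
        values = Yk - means[:, None]
    else:
        if scale_mode == "median-of-means":
            m = float(np.median(means))
        elif scale_mode == "mean-of-means":
            m = float(means.mean())
        else:  # user-supplied
            if overall_mean is None:
                raise ValueError("scale_mode='user-supplied' requires overall_mean")
            m = float(overall_mean)
        if not np.isfinite(m) or m <= 0:
            raise ValueError(f"bad scale: overall mean {m!r} is not a positive finite number")
        values = (Yk - means[:, None]) / m * target

    voxel_ids = raw.voxel_ids[keep] if raw.voxel_ids is not None else None
    return ScaledData(
        values=values,
        voxel_means=means,
        overall_mean=m,
        scale_mode=scale_mode,
        excluded_voxels=excluded,
        voxel_ids=voxel_ids,
        geometry=raw.geometry,
    )


@dataclass
class DSETimeSeries:
    """The twelve DSE diagnostic series plus the global mean signal.

    Whole-scope series:

    ==========  ============================================  ===========
    name        value                                         index range
    ==========  ============================================  ===========
    ``A``       mean_i Y_it^2                                 1..T
    ``D``       mean_i ((Y_{i,t+1} - Y_it)/2)^2               1..T-1
    ``S``       mean_i ((Y_it + Y_{i,t+1})/2)^2               1..T-1
    ``E``       mean_i Y_it^2 / 2 at t in {1, T}, else 0      1..T
    ==========  ============================================  ===========

    Global series (``AG`` .. ``EG``) replace the spatial mean square by the
    square of the spatial mean; non-global series (``AN`` .. ``EN``) use the
    spatially demeaned data.  ``A`` and ``E`` plot at integer t, ``D`` and
    ``S`` midway between scans at t + 1/2.
    """

    A: np.ndarray
    D: np.ndarray
    S: np.ndarray
    E: np.ndarray
    AG: np.ndarray
    DG: np.ndarray
    SG: np.ndarray
    EG: np.ndarray
    AN: np.ndarray
    DN: np.ndarray
    SN: np.ndarray
    EN: np.ndarray
    global_mean_series: np.ndarray
    n_voxels: int

    _SCOPES = ("whole", "global", "nonglobal")

    @property
    def n_timepoints(self) -> int:
        return len(self.A)

    def series(self, component: str, scope: str = "whole") -> np.ndarray:
        """Return one of the 12 series by component letter and scope."""
        suffix = {"whole": "", "global": "G", "nonglobal": "N"}[scope]
        return getattr(self, component + suffix)

    def abscissa(self, component: str) -> np.ndarray:
        """Plotting positions (1-based): t for A/E, t + 1/2 for D/S."""
        T = self.n_timepoints
        if component in ("A", "E"):
            return np.arange(1, T + 1, dtype=float)
        return np.arange(1, T, dtype=float) + 0.5

    def averages(self, scope: str = "whole") -> dict[str, float]:
        """Scan-level averages: each series' sum divided by T.

        Dividing every sum by T (rather than by the series length) is what
        makes A = D + S + E hold exactly.
        """
        T = self.n_timepoints
        return {c: float(self.series(c, scope).sum() / T) for c in "ADSE"}


def compute_dse_timeseries(data: ScaledData) -> DSETimeSeries:
    """Compute all twelve DSE series from centered data.

    Raises
    ------
    ValueError
        If fewer than 2 timepoints are available.
    """
    Y = data.values
    I, T = Y.shape
    if T < 2:
        raise ValueError("DSE decomposition needs at least 2 timepoints")

    gm = Y.mean(axis=0)  # Ybar_t
    Yc = Y - gm[None, :]  # spatially demeaned

    def _series(M: np.ndarray) -> tuple[np.ndarray, ...]:
        A = (M**2).mean(axis=0)
        half_diff = (M[:, 1:] - M[:, :-1]) / 2.0
        half_sum = (M[:, 1:] + M[:, :-1]) / 2.0
        D = (half_diff**2).mean(axis=0)
        S = (half_sum**2).mean(axis=0)
        E = np.zeros(T)
        E[0] = A[0] / 2.0
        E[-1] = A[-1] / 2.0
        return A, D, S, E

    A, D, S, E = _series(Y)
    AG, DG, SG, EG = _series(gm[None, :])
    AN, DN, SN, EN = _series(Yc)

    return DSETimeSeries(
        A=A, D=D, S=S, E=E,
        AG=AG, DG=DG, SG=SG, EG=EG,
        AN=AN, DN=DN, SN=SN, EN=EN,
        global_mean_series=gm,
        n_voxels=I,
    )


@dataclass
class DSEImages:
    """Per-voxel variance decomposition maps.

    ``A_img[i] = sum_t Y_it^2 / T``; ``D_img`` and ``S_img`` analogously use
    squared half-differences and half-sums divided by 4T.  Spatial means of
    the three maps equal the scan-average A, D and S.
    """

    A_img: np.ndarray
    D_img: np.ndarray
    S_img: np.ndarray
    voxel_ids: np.ndarray | None = None
    geometry: dict | None = None


def compute_dse_images(data: ScaledData) -> DSEImages:
    """Voxelwise total / fast / slow variability maps."""
    Y = data.values
    T = Y.shape[1]
    A_img = (Y**2).sum(axis=1) / T
    D_img = ((Y[:, 1:] - Y[:, :-1]) ** 2).sum(axis=1) / (4.0 * T)
    S_img = ((Y[:, 1:] + Y[:, :-1]) ** 2).sum(axis=1) / (4.0 * T)
    return DSEImages(A_img=A_img, D_img=D_img, S_img=S_img,
                     voxel_ids=data.voxel_ids, geometry=data.geometry)


def dvars_series(dse: DSETimeSeries) -> np.ndarray:
    """DVARS_t = 2 sqrt(D_t), for t = 1..T-1.

    The round trip ``dvars**2 / 4`` recovers the fast component exactly.
    """
    return 2.0 * np.sqrt(dse.D)


@dataclass
class IdentityReport:
    """Residuals of the algebraic identities linking the DSE series."""

    pairwise_residual: float   # max |D_t + S_t - (A_t + A_{t+1})/2|, relative
    total_residual: float      # max over scopes |A - (D + S + E)|, relative
    scope_residual: float      # max |whole - global - nonglobal|, relative
    tol: float
    ok: bool


def verify_identities(dse: DSETimeSeries, tol: float = 1e-8) -> IdentityReport:
    """Check the exact decomposition identities, relative to average A.

    Residuals are scaled by the scan-average total variability so the
    tolerance is unit free.  A report is always returned; ``ok`` is False
    when any residual exceeds ``tol``.
    """
    scale = max(dse.averages("whole")["A"], np.finfo(float).tiny)

    mid = (dse.A[:-1] + dse.A[1:]) / 2.0
    pairwise = float(np.abs(dse.D + dse.S - mid).max() / scale)

    total = 0.0
    for scope in dse._SCOPES:
        av = dse.averages(scope)
        total = max(total, abs(av["A"] - (av["D"] + av["S"] + av["E"])) / scale)

    scope_res = 0.0
    for comp in "ADSE":
        whole = dse.series(comp, "whole")
        resid = np.abs(whole - dse.series(comp, "global") - dse.series(comp, "nonglobal"))
        scope_res = max(scope_res, float(resid.max() / scale))

    ok = max(pairwise, total, scope_res) <= tol
    return IdentityReport(pairwise_residual=pairwise, total_residual=total,
                          scope_residual=scope_res, tol=tol, ok=ok)
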