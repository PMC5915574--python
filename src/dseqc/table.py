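"""DSE summary table with nominal reference values.

Summarizes each variability component in three forms: RMS (data units),
percent of total variability, and the percent normalized by its expectation
under spatially and temporally independent noise ("relative IID").  Also
provides expectations under a time-space-separable noise model and the
S - D lag-1 autocorrelation heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core import DSETimeSeries

__all__ = [
    "DSETable",
    "ReferenceModel",
    "iid_fractions",
    "summarize",
    "expected_table",
    "lag1_estimate",
]

_WHOLE_ROWS = ["A", "D", "S", "E"]
_GLOBAL_ROWS = ["AG", "DG", "SG", "EG"]
_NONGLOBAL_ROWS = ["AN", "DN", "SN", "EN"]

_ROW_LABELS = {
    "A": "A - All", "D": "D - Fast", "S": "S - Slow", "E": "E - Edge",
    "AG": "AG - All Global", "DG": "DG - Fast Global",
    "SG": "SG - Slow Global", "EG": "EG - Edge Global",
    "AN": "AN - All Non-Global", "DN": "DN - Fast Non-Global",
    "SN": "SN - Slow Non-Global", "EN": "EN - Edge Non-Global",
}


def iid_fractions(I: int, T: int) -> dict[str, float]:
    """Expected fraction of total variability per component under IID noise.

    Whole rows: A -> 1, D and S -> (T-1)/(2T), E -> 1/T.  Global rows are
    the whole fractions divided by the voxel count I.  Non-global rows carry
    the complement (1 - 1/I) of the whole fractions.
    """
    half = 0.5 * (T - 1) / T
    whole = {"A": 1.0, "D": half, "S": half, "E": 1.0 / T}
    out = dict(whole)
    for k, v in whole.items():
        out[k + "G"] = v / I
        out[k + "N"] = v * (1.0 - 1.0 / I)
    return out


@dataclass
class DSETable:
    """Component-by-statistic summary of a DSE decomposition.

    ``data`` is indexed by component ({A, D, S, E} x {whole, global, and
    optionally non-global}) with columns ``ms`` (mean square, data units
    squared), ``rms``, ``pct_avar`` (percent of total) and ``rel_iid``.
    """

    data: pd.DataFrame
    n_voxels: int
    n_timepoints: int

    def row(self, name: str) -> pd.Series:
        return self.data.loc[name]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "source", [_ROW_LABELS[r] for r in out.index])
        out.to_csv(path, sep="\t", index_label="component", float_format="%.6g")

    def to_json(self, path=None):
        payload = {
            "I": self.n_voxels,
            "T": self.n_timepoints,
            "rows": {r: {c: float(v) for c, v in rec.items()}
                     for r, rec in self.data.iterrows()},
        }
        if path is None:
            return payload
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    def render(self, hide_nonglobal: bool = True) -> str:
        """Plain-text table: Source / RMS / % of A-var / Relative to IID."""
        rows = [r for r in self.data.index
                if not (hide_nonglobal and r in _NONGLOBAL_ROWS)]
        lines = [f"{'Source':<22}{'RMS':>10}{'% of A-var':>14}{'Relative to IID':>18}"]
        for r in rows:
            rec = self.data.loc[r]
            lines.append(
                f"{_ROW_LABELS[r]:<22}{rec.rms:>10.3f}{rec.pct_avar:>14.3f}"
                f"{rec.rel_iid:>18.3f}"
            )
        return "\n".join(lines)


def _build_table(ms: dict[str, float], avar: float, I: int, T: int) -> DSETable:
    frac = iid_fractions(I, T)
    recs = {}
    for name, value in ms.items():
        pct = 100.0 * value / avar
        recs[name] = {
            "ms": value,
            "rms": float(np.sqrt(max(value, 0.0))),
            "pct_avar": pct,
            "rel_iid": (pct / 100.0) / frac[name],
        }
    df = pd.DataFrame.from_dict(recs, orient="index",
                                columns=["ms", "rms", "pct_avar", "rel_iid"])
    return DSETable(data=df, n_voxels=I, n_timepoints=T)


def summarize(dse: DSETimeSeries, I: int | None = None, T: int | None = None,
              include_nonglobal: bool = True) -> DSETable:
    """Build the DSE table from a computed decomposition.

    All percent and relative-IID values — including the global and
    non-global rows — are normalized to the *whole* scan-average A, not to
    the scope's own total.

    Parameters
    ----------
    dse : DSETimeSeries
    I, T : int, optional
        Expected dimensions; a mismatch with ``dse`` is an error.
    include_nonglobal : bool
        Compute the non-global rows too (hidden by default when rendering).
    """
    if I is not None and I != dse.n_voxels:
        raise ValueError(f"I={I} does not match data ({dse.n_voxels} voxels)")
    if T is not None and T != dse.n_timepoints:
        raise ValueError(f"T={T} does not match data ({dse.n_timepoints} timepoints)")
    I, T = dse.n_voxels, dse.n_timepoints

    ms: dict[str, float] = {}
    scopes = [("", "whole"), ("G", "global")]
    if include_nonglobal:
        scopes.append(("N", "nonglobal"))
    for suffix, scope in scopes:
        av = dse.averages(scope)
        for comp in "ADSE":
            ms[comp + suffix] = av[comp]
    return _build_table(ms, avar=ms["A"], I=I, T=T)


@dataclass
class ReferenceModel:
    """Nominal noise model for DSE expectations.

    ``separable``: arbitrary spatial covariance summarized by the average
    voxel variance ``sigma_bar_sq`` and the average element of the spatial
    covariance matrix ``sigma_dbar_sq``, with a single lag-1 temporal
    autocorrelation ``rho`` shared by all voxels.  ``iid`` fixes rho = 0 and
    sigma_dbar_sq = sigma_bar_sq / I.
    """

    kind: Literal["iid", "separable"]
    I: int
    T: int
    sigma_bar_sq: float = 1.0
    rho: float = 0.0
    sigma_dbar_sq: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "iid":
            self.rho = 0.0
            self.sigma_dbar_sq = self.sigma_bar_sq / self.I
        if self.sigma_dbar_sq is None:
            raise ValueError("separable model needs sigma_dbar_sq")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma_bar_sq <= 0:
            raise ValueError("sigma_bar_sq must be positive")
        if self.sigma_dbar_sq > self.sigma_bar_sq:
            raise ValueError("average spatial covariance cannot exceed average variance")


def expected_table(model: ReferenceModel) -> DSETable:
    """Expected DSE table under a nominal model.

    Whole-scope mean squares scale with the average voxel variance; the fast
    component shrinks by (1 - rho) and the slow grows by (1 + rho).  Global
    rows scale with the average spatial covariance instead.  The edge
    component is 1/T of the scale and carries no rho term.
    """
    T, I = model.T, model.I
    half = 0.5 * (T - 1) / T

    def _rows(scale: float, suffix: str) -> dict[str, float]:
        return {
            "A" + suffix: scale,
            "D" + suffix: scale * half * (1.0 - model.rho),
            "S" + suffix: scale * half * (1.0 + model.rho),
            "E" + suffix: scale / T,
        }

    ms = _rows(model.sigma_bar_sq, "")
    ms.update(_rows(model.sigma_dbar_sq, "G"))
    return _build_table(ms, avar=model.sigma_bar_sq, I=I, T=T)


def lag1_estimate(dse: DSETimeSeries) -> tuple[float, np.ndarray]:
    """Average lag-1 autocorrelation from the S - D gap.

    Returns the scalar ``rho_hat = (S - D)/A * T/(T-1)`` and the per-pair
    series built the same way from S_t - D_t.  Values are not clamped; for
    genuine data they fall in [-1, 1] up to sampling noise.
    """
    T = dse.n_timepoints
    if T < 2:
        raise ValueError("lag-1 estimate needs at least 2 timepoints")
    av = dse.averages("whole")
    if av["A"] <= 0:
        raise ValueError("total variability is zero")
    factor = T / (T - 1.0)
    rho_hat = (av["S"] - av["D"]) / av["A"] * factor
    rho_t = (dse.S - dse.D) / av["A"] * factor
    return float(rho_hat), rho_t
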