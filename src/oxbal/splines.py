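"""Restricted (natural) cubic spline basis for dose-response modelling.

A restricted cubic spline with k knots t_1 < ... < t_k is a cubic spline
constrained to be linear beyond the boundary knots.  The truncated-power
construction yields k-1 regression columns: the linear term x itself and
k-2 nonlinear columns

    C_j(x) = [ (x - t_j)+^3
               - (x - t_{k-1})+^3 (t_k - t_j) / (t_k - t_{k-1})
               + (x - t_k)+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ]
             / (t_k - t_1)^2,          j = 1, ..., k-2,

which have continuous value, first and second derivative everywhere and
zero second derivative outside [t_1, t_k].  The division by the squared
knot range keeps the nonlinear columns on roughly the scale of x.

Default knot policy: 4 knots at the 5th/35th/65th/95th percentiles of
the observed exposure, a standard epidemiological choice; both count and
locations are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations (exposure units) for a restricted cubic spline."""

    knots: tuple[float, ...]
    basis: str = "truncated-power-natural"

    def __post_init__(self) -> None:
        ks = np.asarray(self.knots, dtype=float)
        if ks.size < 3:
            raise ValueError("a restricted cubic spline needs at least 3 knots")
        if not np.all(np.diff(ks) > 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")

    @classmethod
    def from_data(
        cls, x: np.ndarray, quantiles: tuple[float, ...] = DEFAULT_KNOT_QUANTILES
    ) -> "SplineSpec":
        """Place knots at empirical quantiles of the observed exposure."""
        ks = np.quantile(np.asarray(x, dtype=float), quantiles)
        if not np.all(np.diff(ks) > 0):
            # discrete exposures can collapse quantiles; fall back to
            # evenly spaced distinct observed values
            uniq = np.unique(x)
            if uniq.size < len(quantiles):
                raise ValueError(
                    f"exposure has only {uniq.size} distinct values; "
                    f"cannot place {len(quantiles)} distinct knots"
                )
            idx = np.linspace(0, uniq.size - 1, len(quantiles)).round().astype(int)
            ks = uniq[idx]
        return cls(knots=tuple(float(k) for k in ks))


def rcs_basis(x: np.ndarray, spec: SplineSpec, prefix: str = "rcs") -> pd.DataFrame:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns a DataFrame with columns ``{prefix}_lin`` (x itself) and
    ``{prefix}_nl{j}`` for the k-2 nonlinear columns.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots, dtype=float)
    k = t.size
    norm = (t[-1] - t[0]) ** 2
    cols = {f"{prefix}_lin": x}
    for j in range(k - 2):
        cub = np.clip(x - t[j], 0, None) ** 3
        cub -= np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
        cub += np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        cols[f"{prefix}_nl{j + 1}"] = cub / norm
    return pd.DataFrame(cols, index=pd.RangeIndex(len(x)))
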