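"""Preferential-interaction coefficients and their decomposition.

For a ternary water(1)-solute(2)-cosolvent(3) system the difference

    gamma = G23 - G12        [nm^3]

quantifies preferential interaction (gamma > 0, the cosolvent accumulates
at the solute) or exclusion (gamma < 0).  Two decompositions isolate where
the interaction happens on a peptide:

- side chains: gamma_i^sc = gamma_i - gamma_gly, subtracting the glycine
  value measured under the same (capped) conditions;
- backbone: the constant-increment method fits gamma of a glycine-repeat
  series against the number x of internal glycine units,
  gamma(x) = gamma_eg + gamma_bb * x, by ordinary least squares; the slope
  is the per-residue backbone contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GammaRecord",
    "SideChainGamma",
    "BackboneFit",
    "gamma_from_kbis",
    "side_chain_gamma",
    "backbone_fit",
]


@dataclass
class GammaRecord:
    solute_id: str
    G23: float
    G12: float
    gamma: float
    stderr: float | None = None
    interpretation: str = ""


@dataclass
class SideChainGamma:
    residue: str
    gamma_sc: float
    interpretation: str = ""


@dataclass
class BackboneFit:
    """OLS fit gamma = gamma_eg + gamma_bb * x with the conventional
    coefficient of determination R^2 = 1 - SS_res/SS_tot."""

    gamma_eg: float
    gamma_bb: float
    r_squared: float
    n_points: int
    stderr_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a line fit needs at least two points")
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError("R^2 must lie in [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))


def _sign_label(value: float) -> str:
    if value > 0:
        return "preferential interaction"
    if value < 0:
        return "preferential exclusion"
    return "indifferent"


def gamma_from_kbis(
    G23: float,
    G12: float,
    solute_id: str = "",
    stderr_G23: float | None = None,
    stderr_G12: float | None = None,
) -> GammaRecord:
    """gamma = G23 - G12 (nm^3) with the sign convention attached: negative
    means the cosolvent is preferentially excluded from the solute.  KBI
    standard errors, when given, propagate in quadrature."""
    if not (np.isfinite(G23) and np.isfinite(G12)):
        raise ValueError("KBIs must be finite")
    gamma = G23 - G12
    stderr = None
    if stderr_G23 is not None or stderr_G12 is not None:
        stderr = float(np.hypot(stderr_G23 or 0.0, stderr_G12 or 0.0))
    return GammaRecord(
        solute_id=solute_id,
        G23=float(G23),
        G12=float(G12),
        gamma=float(gamma),
        stderr=stderr,
        interpretation=_sign_label(gamma),
    )


def side_chain_gamma(
    gamma_i: float,
    gamma_gly: float,
    residue: str = "",
    conditions_i: str | None = None,
    conditions_gly: str | None = None,
) -> SideChainGamma:
    """Side-chain contribution gamma_i - gamma_gly.  Both inputs must come
    from the same capping conditions; a metadata mismatch draws a warning
    (the additivity assumption does not hold across conditions)."""
    if conditions_i is not None and conditions_gly is not None and conditions_i != conditions_gly:
        warnings.warn(
            f"condition metadata differ ({conditions_i!r} vs {conditions_gly!r}); "
            "side-chain subtraction assumes matched conditions",
            stacklevel=2,
        )
    sc = float(gamma_i) - float(gamma_gly)
    return SideChainGamma(residue=residue, gamma_sc=sc, interpretation=_sign_label(sc))


def backbone_fit(series: Sequence[tuple]) -> BackboneFit:
    """Constant-increment fit of gamma against internal glycine count.

    Ordinary least squares; returns slope (gamma_bb, nm^3 per glycine),
    intercept (gamma_eg, nm^3) and R^2.  Two points give a perfect fit by
    construction and draw a low-n warning.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("series must be >= 2 (x, gamma) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all x values identical; slope undefined")
    if arr.shape[0] == 2:
        warnings.warn("two-point series: R^2 = 1 by construction", stacklevel=2)
    res = stats.linregress(x, y)
    return BackboneFit(
        gamma_eg=float(res.intercept),
        gamma_bb=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=arr.shape[0],
        stderr_slope=float(res.stderr),
    )
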