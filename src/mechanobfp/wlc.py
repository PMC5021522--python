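"""Worm-like-chain (WLC) polymer elasticity and contour-length fitting.

The WLC model describes the entropic elasticity of an unfolded polypeptide
tether: the force needed to hold the chain at end-to-end extension ``x`` is,
in the Marko–Siggia interpolation,

    F(x) = (kBT / p) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

with contour length ``Lc`` (nm), persistence length ``p`` (nm) and thermal
energy ``kBT`` (pN nm).  Fitting mean unfolding force versus unfolding length
data to this curve yields the contour length of the unfolded domain, the
quantity used to identify which receptor domain unfolded.

Defaults follow polypeptide conventions: p = 0.5 nm for an unstructured
chain, kBT = 4.28 pN nm (310 K, physiological temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "WLCParams",
    "wlc_force",
    "wlc_extension",
    "WLCModel",
    "WLCResults",
    "fit_contour_length",
    "sort_unfolding_mechanics",
    "DEFAULT_PERSISTENCE_NM",
    "DEFAULT_KBT_PN_NM",
]

DEFAULT_PERSISTENCE_NM = 0.5
DEFAULT_KBT_PN_NM = 4.28


@dataclass(frozen=True)
class WLCParams:
    """WLC parameter triple.

    Attributes
    ----------
    contour_length : float
        Full chain length Lc, nm.
    persistence_length : float
        Bending stiffness length scale p, nm. Must satisfy 0 < p < Lc.
    kbt : float
        Thermal energy, pN nm.
    """

    contour_length: float
    persistence_length: float = DEFAULT_PERSISTENCE_NM
    kbt: float = DEFAULT_KBT_PN_NM

    def __post_init__(self) -> None:
        if not (0 < self.persistence_length < self.contour_length):
            raise ValueError(
                "require 0 < persistence_length < contour_length, got "
                f"p={self.persistence_length}, Lc={self.contour_length}"
            )
        if self.kbt <= 0:
            raise ValueError("kbt must be positive")


def wlc_force(extension, params: WLCParams):
    """Marko–Siggia force (pN) at the given extension(s) (nm).

    Strictly increasing in extension, diverging as x -> Lc.  Raises
    ``ValueError`` if any extension lies outside [0, Lc).
    """
    x = np.asarray(extension, dtype=float)
    lc = params.contour_length
    if np.any(x < 0) or np.any(x >= lc):
        raise ValueError(f"extension must lie in [0, Lc={lc}) nm")
    z = x / lc
    f = (params.kbt / params.persistence_length) * (
        0.25 / (1.0 - z) ** 2 - 0.25 + z
    )
    return f if f.ndim else float(f)


def wlc_extension(force, params: WLCParams):
    """Inverse of :func:`wlc_force` by bracketed root finding (nm)."""
    f = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    lc = params.contour_length
    out = np.empty_like(f)
    for i, fi in enumerate(f):
        if fi == 0.0:
            out[i] = 0.0
            continue
        out[i] = optimize.brentq(
            lambda x: wlc_force(x, params) - fi,
            0.0,
            lc * (1.0 - 1e-12),
            xtol=1e-12 * lc,
            rtol=8.9e-16,
        )
    return out if np.asarray(force).ndim else float(out[0])


class WLCResults:
    """Estimates and uncertainties from a WLC contour-length fit.

    ``params`` is an array ``[Lc]`` or ``[Lc, p]`` depending on whether the
    persistence length was held fixed; ``bse`` are the corresponding standard
    errors from the least-squares covariance.
    """

    def __init__(self, model, params, cov, fitted):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov, dtype=float)
        self.bse = np.sqrt(np.diag(self.cov_params))
        self.fittedvalues = fitted
        self.resid = model.force - fitted

    @property
    def contour_length(self) -> float:
        return float(self.params[0])

    @property
    def contour_length_se(self) -> float:
        return float(self.bse[0])

    @property
    def persistence_length(self) -> float:
        if self.model.fix_persistence is not None:
            return float(self.model.fix_persistence)
        return float(self.params[1])

    @property
    def wlc_params(self) -> WLCParams:
        return WLCParams(self.contour_length, self.persistence_length, self.model.kbt)

    def conf_int(self, alpha: float = 0.05):
        from scipy import stats

        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        names = ["Lc (nm)"]
        if self.model.fix_persistence is None:
            names.append("p (nm)")
        lines = ["WLC contour-length fit (Marko-Siggia)"]
        lines.append(f"  n points: {self.model.force.size}")
        lines.append(f"  kBT:      {self.model.kbt:.3f} pN nm")
        if self.model.fix_persistence is not None:
            lines.append(f"  p fixed:  {self.model.fix_persistence:.3f} nm")
        for name, est, se in zip(names, self.params, self.bse):
            lines.append(f"  {name:8s} = {est:10.4f} +/- {se:.4f}")
        rss = float(np.sum(self.resid**2))
        lines.append(f"  residual SS = {rss:.4g} pN^2")
        return "\n".join(lines)


class WLCModel:
    """Least-squares WLC model for (unfolding length, unfolding force) data.

    Parameters
    ----------
    force : array-like
        Observed forces, pN (endogenous variable).
    extension : array-like
        Observed lengths/extensions, nm.
    fix_persistence : float or None
        If a float, p is held fixed at that value and only Lc is estimated;
        if None, p is estimated jointly with Lc.
    kbt : float
        Thermal energy, pN nm.
    """

    def __init__(self, force, extension, fix_persistence: float | None = DEFAULT_PERSISTENCE_NM,
                 kbt: float = DEFAULT_KBT_PN_NM):
        self.force = np.asarray(force, dtype=float)
        self.extension = np.asarray(extension, dtype=float)
        if self.force.shape != self.extension.shape or self.force.ndim != 1:
            raise ValueError("force and extension must be 1-D arrays of equal length")
        if self.force.size < 4:
            raise ValueError("need at least 4 (extension, force) points")
        if np.any(self.force <= 0):
            raise ValueError("forces must be positive")
        if np.any(self.extension <= 0):
            raise ValueError("extensions must be positive")
        self.fix_persistence = fix_persistence
        self.kbt = kbt

    def _predict(self, theta):
        if self.fix_persistence is not None:
            lc, p = theta[0], self.fix_persistence
        else:
            lc, p = theta
        # soft guard: curve_fit may probe infeasible Lc during line search
        if lc <= self.extension.max() or p <= 0:
            return np.full_like(self.force, 1e6)
        return wlc_force(self.extension, WLCParams(lc, p, self.kbt))

    def fit(self) -> WLCResults:
        xmax = float(self.extension.max())
        lc0 = xmax * 1.3
        theta0 = [lc0] if self.fix_persistence is not None else [lc0, DEFAULT_PERSISTENCE_NM]
        try:
            popt, pcov = optimize.curve_fit(
                lambda _x, *theta: self._predict(np.asarray(theta)),
                self.extension,
                self.force,
                p0=theta0,
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"WLC fit failed to converge (n={self.force.size}, "
                f"x in [{self.extension.min():.2f}, {xmax:.2f}] nm): {exc}"
            ) from exc
        if not np.all(np.isfinite(pcov)):
            raise RuntimeError("WLC fit covariance is singular; data may be degenerate")
        fitted = self._predict(popt)
        return WLCResults(self, popt, pcov, fitted)


def fit_contour_length(lengths, forces, fix_persistence: float | None = DEFAULT_PERSISTENCE_NM,
                       kbt: float = DEFAULT_KBT_PN_NM) -> WLCResults:
    """Fit the WLC contour length to (length, force) points.

    Thin functional wrapper over :class:`WLCModel`.
    """
    return WLCModel(forces, lengths, fix_persistence=fix_persistence, kbt=kbt).fit()


def sort_unfolding_mechanics(lengths, forces, bins=8, min_count: int = 2):
    """Bin unfolding events by length and average force per bin.

    Reproduces the averaging used to build mean unfolding force vs. length
    point sets: events are sorted into length bins and each retained bin is
    summarised by the mean length, mean force and the s.e.m. of the force.
    Bins with fewer than ``min_count`` events are dropped (an s.e.m. is
    undefined for a single event).

    Returns a dict of arrays ``{"length", "force", "force_sem", "n"}``.
    """
    lengths = np.asarray(lengths, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if lengths.size == 0:
        raise ValueError("no events to sort")
    if np.isscalar(bins):
        edges = np.linspace(lengths.min(), lengths.max() + 1e-9, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.digitize(lengths, edges) - 1
    out = {"length": [], "force": [], "force_sem": [], "n": []}
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n < min_count:
            continue
        out["length"].append(float(lengths[sel].mean()))
        out["force"].append(float(forces[sel].mean()))
        out["force_sem"].append(float(forces[sel].std(ddof=1) / np.sqrt(n)))
        out["n"].append(n)
    return {k: np.asarray(v) for k, v in out.items()}
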