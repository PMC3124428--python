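"""Phylogenetic informativeness: the per-site signal function and its integrals.

The informativeness of a single site with substitution rate ``lam`` at
historical time ``t`` (measured from the present, at the tips, toward the
root) is

    rho(t; lam) = 16 * lam**2 * t * exp(-4 * lam * t)

It is zero at the present, rises to a maximum at ``t = 1/(4*lam)`` of height
``4*lam/e``, and decays as deeper divergences are obscured by subsequent
substitutions.  Integrated over all time each site contributes exactly one
unit of informativeness, so the epoch integral apportions that unit across
history.  A locus profile is the sum of ``rho`` over its rated sites (net)
or that sum divided by the number of rated sites (per-site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Epoch",
    "rho",
    "integrate_epoch",
    "net_profile",
    "per_site_profile",
]


@dataclass(frozen=True)
class Epoch:
    """A historical time interval [t_start, t_end), present at t=0.

    Times are in the units of the tree's branch lengths.  ``t_end`` may
    equal the tree depth; validation against depth happens where a tree
    is in scope (the profiler).
    """

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not (self.t_start >= 0):
            raise ValueError(f"epoch t_start must be >= 0, got {self.t_start}")
        if not (self.t_end > self.t_start):
            raise ValueError(
                f"epoch must satisfy t_start < t_end, got [{self.t_start}, {self.t_end}]"
            )

    @property
    def span(self) -> float:
        return self.t_end - self.t_start


def rho(t, lam):
    """Per-site phylogenetic informativeness density 16*lam^2*t*exp(-4*lam*t).

    Parameters
    ----------
    t : float or array-like
        Historical time(s), >= 0, measured from the tips toward the root.
    lam : float or array-like
        Site substitution rate(s), >= 0, in substitutions/site/unit time.
        Broadcast against ``t``.

    Returns
    -------
    float or ndarray
    """
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(t < 0):
        raise ValueError("time t must be non-negative")
    if np.any(lam < 0):
        raise ValueError("rate lambda must be non-negative")
    out = 16.0 * lam**2 * t * np.exp(-4.0 * lam * t)
    if out.ndim == 0:
        return float(out)
    return out


def integrate_epoch(lam, epoch: Epoch):
    """Exact integral of rho(t; lam) over an epoch.

    Uses the closed form

        (1 + 4*lam*t1) * exp(-4*lam*t1) - (1 + 4*lam*t2) * exp(-4*lam*t2)

    which for lam=0 is identically 0 and tends to 1 as t2 -> infinity with
    t1 = 0 (one unit of informativeness per site over all of history).

    ``lam`` may be an array; the result broadcasts.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("rate lambda must be non-negative")
    t1, t2 = epoch.t_start, epoch.t_end
    a1 = 4.0 * lam * t1
    a2 = 4.0 * lam * t2
    out = (1.0 + a1) * np.exp(-a1) - (1.0 + a2) * np.exp(-a2)
    if out.ndim == 0:
        return float(out)
    return out


def _rates_and_mask(rates) -> tuple[np.ndarray, int]:
    """Extract the usable (non-faulty) rates from a SiteRateVector or array."""
    faulty = getattr(rates, "faulty", None)
    values = np.asarray(getattr(rates, "rates", rates), dtype=float)
    if faulty is not None:
        values = values[~np.asarray(faulty, dtype=bool)]
    else:
        values = values[np.isfinite(values)]
    return values, values.size


def net_profile(rates, grid) -> np.ndarray:
    """Net informativeness: sum of rho over the rated sites, per grid time.

    ``rates`` is a SiteRateVector (faulty sites excluded) or a plain array
    of site rates.  ``grid`` is a non-empty array of times >= 0.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    lam, n = _rates_and_mask(rates)
    if n == 0:
        warnings.warn("all sites faulty: net profile is identically zero")
        return np.zeros_like(grid)
    # outer evaluation (n_times, n_sites) summed over sites
    return rho(grid[:, None], lam[None, :]).sum(axis=1)


def per_site_profile(rates, grid, denominator: int | None = None) -> np.ndarray:
    """Per-site informativeness: net profile divided by the site count.

    The default denominator is the number of rated (non-faulty) sites;
    pass ``denominator`` (e.g. the raw locus length) to override.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    lam, n = _rates_and_mask(rates)
    denom = n if denominator is None else int(denominator)
    if n == 0 or denom == 0:
        warnings.warn("all sites faulty: per-site profile is identically zero")
        return np.zeros_like(grid)
    return rho(grid[:, None], lam[None, :]).sum(axis=1) / denom
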