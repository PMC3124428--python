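"""Multi-locus orchestration: profiles, epoch integrals, and locus rankings.

Loci arrive either as alignments (rates are estimated on the tree) or as
precomputed SiteRateVectors.  NEXUS partitions are profiled as pseudo-loci
named ``<locus>:<partition>``.  Epoch integrals use the closed form per
site — the time grid exists only for display and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .informativeness import Epoch, integrate_epoch, net_profile, per_site_profile
from .io_phylo import (
    Alignment,
    SiteRateVector,
    UltrametricTree,
    ValidationError,
    reconcile,
)
from . import site_rates as _sr

__all__ = [
    "PIProfile",
    "RankEntry",
    "EpochRanking",
    "profile_loci",
    "rank_loci",
    "multi_epoch_report",
    "combined_ranking_frame",
]


@dataclass
class PIProfile:
    """Evaluated informativeness curves on a shared time grid.

    ``curves`` maps each locus label to a ``(net, per_site)`` pair of
    arrays aligned with ``grid``.
    """

    grid: np.ndarray
    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    depth: float
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not self.loci:
            self.loci = list(self.curves)
        if self.grid.size == 0:
            raise ValidationError("profile grid is empty")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("profile grid must be strictly increasing")
        if self.grid[0] < 0 or self.grid[-1] > self.depth * (1 + 1e-9):
            raise ValidationError("profile grid must lie within [0, depth]")


@dataclass(frozen=True)
class RankEntry:
    locus: str
    integral_net: float
    integral_per_site: float
    rank: int
    tied: bool = False


@dataclass
class EpochRanking:
    """Loci ordered by their informativeness integral over one epoch."""

    epoch: Epoch
    entries: list[RankEntry]
    basis: str  # "net" | "per_site"


def _coerce_vectors(loci, tree: UltrametricTree | None,
                    model=None, lambda_max=None,
                    include_partitions: bool = True) -> list[SiteRateVector]:
    """Normalize the locus inputs to SiteRateVectors (estimating if needed)."""
    if not loci:
        raise ValidationError("no loci supplied")
    vectors: list[SiteRateVector] = []
    for item in loci:
        if isinstance(item, SiteRateVector):
            vectors.append(item)
            continue
        if not isinstance(item, Alignment):
            raise TypeError(f"expected Alignment or SiteRateVector, got {type(item)}")
        if tree is None:
            raise ValidationError(
                f"locus {item.locus_name!r} is an alignment but no tree was given"
            )
        if not set(item.taxa) & set(tree.taxa):
            raise ValidationError(
                f"locus {item.locus_name!r}: taxa are disjoint from the tree"
            )
        work_tree = reconcile(item, tree)
        vec = _sr.estimate_locus_rates(item, work_tree, model=model,
                                       lambda_max=lambda_max)
        vectors.append(vec)
        if include_partitions and item.partitions:
            for pname, cols in item.partitions.items():
                idx = np.array(cols) - 1
                vectors.append(SiteRateVector(
                    locus_name=f"{item.locus_name}:{pname}",
                    rates=vec.rates[idx],
                    faulty=vec.faulty[idx],
                    model_tag=vec.model_tag,
                ))
    names = [v.locus_name for v in vectors]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate locus names: {names}")
    return vectors


def _resolve_depth(tree: UltrametricTree | None, depth: float | None) -> float:
    if tree is not None:
        return tree.depth
    if depth is None:
        raise ValidationError("a tree or an explicit depth is required")
    if depth <= 0:
        raise ValidationError("depth must be positive")
    return float(depth)


def profile_loci(loci, tree: UltrametricTree | None = None, *,
                 model=None, lambda_max=None, depth: float | None = None,
                 grid=None, n_points: int = 1000,
                 include_partitions: bool = True,
                 per_site_denominator: str = "estimated") -> PIProfile:
    """Net and per-site informativeness curves for every locus.

    ``grid`` defaults to ``n_points`` evenly spaced times on [0, depth].
    ``per_site_denominator`` is "estimated" (rated sites; default) or
    "length" (raw locus length).
    """
    depth = _resolve_depth(tree, depth)
    vectors = _coerce_vectors(loci, tree, model, lambda_max, include_partitions)
    if grid is None:
        grid = np.linspace(0.0, depth, n_points)
    grid = np.asarray(grid, dtype=float)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for v in vectors:
        net = net_profile(v, grid)
        denom = v.length if per_site_denominator == "length" else None
        per = per_site_profile(v, grid, denominator=denom)
        curves[v.locus_name] = (net, per)
    return PIProfile(grid=grid, curves=curves, depth=depth,
                     loci=[v.locus_name for v in vectors])


def _epoch_integrals(vector: SiteRateVector, epoch: Epoch,
                     per_site_denominator: str = "estimated"
                     ) -> tuple[float, float]:
    lam = vector.rates[~vector.faulty]
    net = float(np.sum(integrate_epoch(lam, epoch))) if lam.size else 0.0
    denom = vector.length if per_site_denominator == "length" else vector.n_estimated
    per = net / denom if denom else 0.0
    return net, per


def rank_loci(loci, epoch: Epoch, tree: UltrametricTree | None = None, *,
              basis: str = "per_site", model=None, lambda_max=None,
              depth: float | None = None, include_partitions: bool = True,
              per_site_denominator: str = "estimated") -> EpochRanking:
    """Rank loci by exact epoch integrals (descending on ``basis``).

    Ties share the smaller rank (competition ranking) and are flagged;
    exactly tied loci keep stable alphabetical order.
    """
    if basis not in ("net", "per_site"):
        raise ValidationError(f"basis must be 'net' or 'per_site', got {basis!r}")
    depth = _resolve_depth(tree, depth)
    if epoch.t_end > depth * (1 + 1e-9):
        raise ValidationError(
            f"epoch [{epoch.t_start}, {epoch.t_end}] exceeds tree depth: "
            f"allowed range is [0, {depth:g}]"
        )
    vectors = _coerce_vectors(loci, tree, model, lambda_max, include_partitions)
    rows = []
    for v in vectors:
        net, per = _epoch_integrals(v, epoch, per_site_denominator)
        rows.append((v.locus_name, net, per))
    key = (lambda r: r[1]) if basis == "net" else (lambda r: r[2])
    rows.sort(key=lambda r: (-key(r), r[0]))
    values = [key(r) for r in rows]
    entries = []
    for i, (locus, net, per) in enumerate(rows):
        rank = 1 + sum(1 for w in values if w > values[i])  # competition ranking
        tied = values.count(values[i]) > 1
        entries.append(RankEntry(locus, net, per, rank, tied))
    return EpochRanking(epoch=epoch, entries=entries, basis=basis)


def multi_epoch_report(loci, epochs: list[Epoch],
                       tree: UltrametricTree | None = None, *,
                       basis: str = "per_site", model=None, lambda_max=None,
                       depth: float | None = None,
                       include_partitions: bool = True) -> list[EpochRanking]:
    """Independent rankings for several (possibly overlapping) epochs.

    Rates are estimated once and shared across epochs.
    """
    if not epochs:
        raise ValidationError("at least one epoch is required")
    depth = _resolve_depth(tree, depth)
    vectors = _coerce_vectors(loci, tree, model, lambda_max, include_partitions)
    return [
        rank_loci(vectors, epoch, basis=basis, depth=depth,
                  include_partitions=False)
        for epoch in epochs
    ]


def combined_ranking_frame(rankings: list[EpochRanking]) -> pd.DataFrame:
    """Wide table: one row per locus, integral + rank columns per epoch."""
    frames = []
    for rk in rankings:
        tag = f"{rk.epoch.t_start:g}-{rk.epoch.t_end:g}"
        df = pd.DataFrame(
            {
                "locus": [e.locus for e in rk.entries],
                f"net[{tag}]": [e.integral_net for e in rk.entries],
                f"persite[{tag}]": [e.integral_per_site for e in rk.entries],
                f"rank[{tag}]": [e.rank for e in rk.entries],
            }
        ).set_index("locus")
        frames.append(df)
    return pd.concat(frames, axis=1).sort_index()
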