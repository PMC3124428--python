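"""SVG rendering: the ultrametric tree aligned above the informativeness profiles.

Both panels share one linear time transform, so a divergence on the tree
sits directly above the profile values that predict signal for it.  Time
runs with the present (t = 0, the tips) at the left and the root at the
right by default; ``flip_time`` mirrors the axis.  Output is plain SVG 1.1
with generic font families, byte-stable for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re

import numpy as np

from .informativeness import Epoch
from .io_phylo import UltrametricTree, ValidationError
from .profiler import PIProfile

__all__ = ["PlotSpec", "render_tree", "render_profiles", "render_figure", "PALETTE"]

# Wong colorblind-safe palette
PALETTE = [
    "#0072B2", "#D55E00", "#009E73", "#CC79A7",
    "#E69F00", "#56B4E9", "#F0E442", "#999999",
]

_HEX = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass
class PlotSpec:
    """Layout and styling for the figure."""

    width: float = 800.0
    height: float = 320.0  # per panel
    colors: dict[str, str] = field(default_factory=dict)  # locus -> hex
    time_window: tuple[float, float] | None = None  # subinterval of [0, depth]
    show: str = "per_site"  # "per_site" | "net"
    epoch_shading: list[Epoch] = field(default_factory=list)
    flip_time: bool = False
    margin_left: float = 60.0
    margin_right: float = 30.0
    margin_top: float = 20.0
    margin_bottom: float = 45.0
    tip_label_space: float = 110.0

    def __post_init__(self) -> None:
        for locus, c in self.colors.items():
            if not _HEX.match(c):
                raise ValidationError(f"invalid hex color {c!r} for locus {locus!r}")
        if self.show not in ("per_site", "net"):
            raise ValidationError("show must be 'per_site' or 'net'")
        if self.time_window is not None:
            t0, t1 = self.time_window
            if not (0 <= t0 < t1):
                raise ValidationError(f"empty or invalid time window {self.time_window}")


def _fmt(v: float) -> str:
    return f"{v:.6f}"


class _TimeScale:
    """Shared linear map from time to the horizontal SVG coordinate."""

    def __init__(self, spec: PlotSpec, t0: float, t1: float):
        self.t0, self.t1 = t0, t1
        self.x0 = spec.margin_left
        self.x1 = spec.width - spec.margin_right - spec.tip_label_space
        self.flip = spec.flip_time

    def x(self, t: float) -> float:
        u = (t - self.t0) / (self.t1 - self.t0)
        if self.flip:
            u = 1.0 - u
        return self.x0 + u * (self.x1 - self.x0)


def _axis_ticks(lo: float, hi: float, n: int = 6) -> list[float]:
    raw = np.linspace(lo, hi, n)
    return [float(v) for v in raw]


def _time_axis_svg(scale: _TimeScale, y: float) -> list[str]:
    parts = [
        f'<line x1="{_fmt(scale.x(scale.t0))}" y1="{_fmt(y)}" '
        f'x2="{_fmt(scale.x(scale.t1))}" y2="{_fmt(y)}" stroke="#000000" stroke-width="1"/>'
    ]
    for t in _axis_ticks(scale.t0, scale.t1):
        x = scale.x(t)
        parts.append(
            f'<line x1="{_fmt(x)}" y1="{_fmt(y)}" x2="{_fmt(x)}" '
            f'y2="{_fmt(y + 5)}" stroke="#000000" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{_fmt(x)}" y="{_fmt(y + 18)}" font-family="sans-serif" '
            f'font-size="11" text-anchor="middle">{t:.3g}</text>'
        )
    return parts


def _svg_doc(width: float, height: float, body: list[str]) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    return head + "\n" + "\n".join(body) + "\n</svg>\n"


# ---------------------------------------------------------------------------
# tree panel


def _ladderized_layout(utree: UltrametricTree):
    """Stable (x=time, y=row) coordinates: ladderized by clade size, ties by label."""
    tree = utree.tree
    sizes: dict[int, int] = {}
    labels: dict[int, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sizes[id(node)] = 1
            labels[id(node)] = node.taxon.label
        else:
            kids = node.child_nodes()
            sizes[id(node)] = sum(sizes[id(c)] for c in kids)
            labels[id(node)] = min(labels[id(c)] for c in kids)
    times: dict[int, float] = {}  # historical time: depth at root, ~0 at tips
    dist = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            dist[id(node)] = dist[id(node.parent_node)] + (node.edge.length or 0.0)
        times[id(node)] = max(utree.depth - dist[id(node)], 0.0)
    rows: dict[int, float] = {}
    counter = [0]

    def assign(node):
        if node.is_leaf():
            rows[id(node)] = float(counter[0])
            counter[0] += 1
            return rows[id(node)]
        kids = sorted(node.child_nodes(),
                      key=lambda c: (sizes[id(c)], labels[id(c)]))
        ys = [assign(c) for c in kids]
        rows[id(node)] = sum(ys) / len(ys)
        return rows[id(node)]

    assign(tree.seed_node)
    return times, rows, max(counter[0] - 1, 1)


def _tree_body(utree: UltrametricTree, spec: PlotSpec, scale: _TimeScale,
               y_offset: float, panel_h: float) -> list[str]:
    times, rows, max_row = _ladderized_layout(utree)
    y_top = y_offset + spec.margin_top
    y_span = panel_h - spec.margin_top - 10.0

    def y(row: float) -> float:
        return y_top + (row / max_row) * y_span

    parts = ['<g class="tree" fill="none" stroke="#333333" stroke-width="1.5">']
    tree = utree.tree
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            # horizontal branch from the parent's time to this node's time
            x_a = scale.x(times[id(node.parent_node)])
            x_b = scale.x(times[id(node)])
            yy = y(rows[id(node)])
            parts.append(
                f'<line x1="{_fmt(x_a)}" y1="{_fmt(yy)}" x2="{_fmt(x_b)}" '
                f'y2="{_fmt(yy)}"/>'
            )
        if not node.is_leaf():
            kids = node.child_nodes()
            ys = [y(rows[id(c)]) for c in kids]
            x_n = scale.x(times[id(node)])
            parts.append(
                f'<line x1="{_fmt(x_n)}" y1="{_fmt(min(ys))}" '
                f'x2="{_fmt(x_n)}" y2="{_fmt(max(ys))}"/>'
            )
    parts.append("</g>")
    parts.append('<g class="tip-labels" font-family="sans-serif" font-size="12">')
    for leaf in sorted(tree.leaf_node_iter(), key=lambda n: rows[id(n)]):
        x_tip = scale.x(times[id(leaf)])
        parts.append(
            f'<text x="{_fmt(x_tip + 6)}" y="{_fmt(y(rows[id(leaf)]) + 4)}">'
            f"{leaf.taxon.label}</text>"
        )
    parts.append("</g>")
    return parts


def render_tree(tree: UltrametricTree, spec: PlotSpec | None = None) -> str:
    """Standalone SVG of the ultrametric tree on the time axis."""
    spec = spec or PlotSpec()
    t0, t1 = spec.time_window or (0.0, tree.depth)
    scale = _TimeScale(spec, t0, t1)
    body = _tree_body(tree, spec, scale, 0.0, spec.height - spec.margin_bottom)
    body += _time_axis_svg(scale, spec.height - spec.margin_bottom)
    return _svg_doc(spec.width, spec.height, body)


# ---------------------------------------------------------------------------
# profile panel


def _assign_colors(loci: list[str], spec: PlotSpec) -> dict[str, str]:
    out = {}
    for i, name in enumerate(loci):
        out[name] = spec.colors.get(name, PALETTE[i % len(PALETTE)])
    return out


def _profile_body(profile: PIProfile, spec: PlotSpec, scale: _TimeScale,
                  y_offset: float, panel_h: float,
                  loci: list[str]) -> list[str]:
    which = 1 if spec.show == "per_site" else 0
    mask = (profile.grid >= scale.t0 - 1e-12) & (profile.grid <= scale.t1 + 1e-12)
    if not np.any(mask):
        raise ValidationError("profile grid does not cover the time window")
    ymax = max(
        float(np.max(profile.curves[name][which][mask])) for name in loci
    )
    ymax = ymax if ymax > 0 else 1.0
    y_top = y_offset + spec.margin_top
    y_base = y_offset + panel_h - spec.margin_bottom

    def y(v: float) -> float:
        return y_base - (v / ymax) * (y_base - y_top)

    parts = []
    for ep in spec.epoch_shading:
        xa, xb = sorted((scale.x(ep.t_start), scale.x(ep.t_end)))
        parts.append(
            f'<rect x="{_fmt(xa)}" y="{_fmt(y_top)}" width="{_fmt(xb - xa)}" '
            f'height="{_fmt(y_base - y_top)}" fill="#DDDDDD" fill-opacity="0.5"/>'
        )
    colors = _assign_colors(loci, spec)
    for name in loci:
        values = profile.curves[name][which]
        pts = " ".join(
            f"{_fmt(scale.x(t))},{_fmt(y(float(v)))}"
            for t, v in zip(profile.grid[mask], values[mask])
        )
        parts.append(
            f'<polyline fill="none" stroke="{colors[name]}" stroke-width="1.5" '
            f'points="{pts}"><title>{name}</title></polyline>'
        )
    # y axis
    parts.append(
        f'<line x1="{_fmt(scale.x0)}" y1="{_fmt(y_top)}" x2="{_fmt(scale.x0)}" '
        f'y2="{_fmt(y_base)}" stroke="#000000" stroke-width="1"/>'
    )
    for v in _axis_ticks(0.0, ymax, 5):
        parts.append(
            f'<text x="{_fmt(scale.x0 - 8)}" y="{_fmt(y(v) + 4)}" '
            f'font-family="sans-serif" font-size="11" text-anchor="end">{v:.3g}</text>'
        )
    # legend in the tip-label gutter
    lx = scale.x1 + 10
    for i, name in enumerate(loci):
        ly = y_top + 16 * i
        parts.append(
            f'<line x1="{_fmt(lx)}" y1="{_fmt(ly)}" x2="{_fmt(lx + 18)}" '
            f'y2="{_fmt(ly)}" stroke="{colors[name]}" stroke-width="2"/>'
        )
        parts.append(
            f'<text x="{_fmt(lx + 24)}" y="{_fmt(ly + 4)}" '
            f'font-family="sans-serif" font-size="11">{name}</text>'
        )
    parts += _time_axis_svg(scale, y_base)
    return parts


def _select_loci(profile: PIProfile, loci: list[str] | None) -> list[str]:
    if loci is None:
        return list(profile.loci)
    missing = [n for n in loci if n not in profile.curves]
    if missing:
        raise ValidationError(
            f"loci {missing} not in profile; available: {list(profile.loci)}"
        )
    return list(loci)


def render_profiles(profile: PIProfile, spec: PlotSpec | None = None,
                    loci: list[str] | None = None) -> str:
    """Standalone SVG of the informativeness curves."""
    spec = spec or PlotSpec()
    loci = _select_loci(profile, loci)
    t0, t1 = spec.time_window or (0.0, profile.depth)
    scale = _TimeScale(spec, t0, t1)
    body = _profile_body(profile, spec, scale, 0.0, spec.height, loci)
    return _svg_doc(spec.width, spec.height, body)


def render_figure(tree: UltrametricTree, profile: PIProfile,
                  spec: PlotSpec | None = None,
                  loci: list[str] | None = None) -> str:
    """The combined figure: tree panel above profiles, one shared x-scale."""
    spec = spec or PlotSpec()
    loci = _select_loci(profile, loci)
    t0, t1 = spec.time_window or (0.0, profile.depth)
    scale = _TimeScale(spec, t0, t1)
    tree_h = spec.height
    body = _tree_body(tree, spec, scale, 0.0, tree_h - 40.0)
    body += _time_axis_svg(scale, tree_h - 30.0)
    body += _profile_body(profile, spec, scale, tree_h, spec.height, loci)
    return _svg_doc(spec.width, tree_h + spec.height, body)
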