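"""SVG rendering of per-neuron property maps on the hexagonal lattice.

Each neuron is drawn as a hexagon colored by its value; missing-value
neurons are hatched; cluster membership is shown by the hexagon outline
color; optional population circles have area proportional to the count.
The dashed frame marks the toroidal seam (the display is one unit cell
of the periodic map).
"""
from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, to_hex

from .property_mapping import NeuronPropertyMap
from .som_core import GridSpec, SQRT3_2, neuron_positions, shifted_labels

HEX_R = 1.0 / np.sqrt(3.0)  # circumradius for unit center spacing

CLUSTER_COLORS = ["#444444", "#888888", "#bbbbbb", "#666699", "#996666",
                  "#669966", "#999933", "#993399", "#339999", "#cc6600"]


def _hex_points(cx: float, cy: float, scale: float) -> str:
    pts = []
    for k in range(6):
        ang = np.pi / 6 + k * np.pi / 3  # pointy-top
        pts.append(f"{cx + scale * HEX_R * np.cos(ang):.3f},"
                   f"{cy + scale * HEX_R * np.sin(ang):.3f}")
    return " ".join(pts)


def render_hexmap(property_map: NeuronPropertyMap, grid: GridSpec,
                  cluster_labels: np.ndarray | None = None,
                  shift: tuple[int, int] = (0, 0),
                  population: np.ndarray | None = None,
                  cmap: str = "viridis",
                  vmin: float | None = None, vmax: float | None = None,
                  scale: float = 40.0) -> str:
    """Return an SVG string for a per-neuron property map.

    `shift` is a display-only toroidal re-centering offset (from
    recenter_map); `population` adds circles with area proportional to
    the per-neuron counts.
    """
    if property_map.n_neurons != grid.n_neurons:
        raise ValueError("property map does not match grid dimensions")
    values = shifted_labels(grid, property_map.values, shift)
    clusters = None
    if cluster_labels is not None:
        if len(cluster_labels) != grid.n_neurons:
            raise ValueError("cluster labels do not match grid dimensions")
        clusters = shifted_labels(grid, np.asarray(cluster_labels), shift)
    pop = None
    if population is not None:
        if len(population) != grid.n_neurons:
            raise ValueError("population does not match grid dimensions")
        pop = shifted_labels(grid, np.asarray(population, dtype=float), shift)

    pos = neuron_positions(grid) * scale
    pad = scale
    width = grid.nx * scale + 2 * pad
    height = (grid.ny - 1) * SQRT3_2 * scale + 2 * pad

    finite = values[np.isfinite(values)]
    lo = vmin if vmin is not None else (finite.min() if finite.size else 0.0)
    hi = vmax if vmax is not None else (finite.max() if finite.size else 1.0)
    norm = Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
    cm = colormaps[cmap]

    out = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
           f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
           '<defs><pattern id="hatch" width="6" height="6" '
           'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
           '<line x1="0" y1="0" x2="0" y2="6" stroke="#999" stroke-width="2"/>'
           '</pattern></defs>']
    for v in range(grid.n_neurons):
        cx, cy = pos[v, 0] + pad, pos[v, 1] + pad
        if np.isfinite(values[v]):
            fill = to_hex(cm(norm(values[v])))
        else:
            fill = "url(#hatch)"
        stroke = "#222222"
        if clusters is not None:
            uniq = sorted(set(np.asarray(clusters).tolist()))
            stroke = CLUSTER_COLORS[uniq.index(clusters[v]) % len(CLUSTER_COLORS)]
        out.append(f'<polygon points="{_hex_points(cx, cy, scale)}" '
                   f'fill="{fill}" stroke="{stroke}" stroke-width="2.5"/>')
    if pop is not None:
        pmax = np.nanmax(pop) if np.isfinite(pop).any() else 0.0
        rmax = 0.42 * scale
        for v in range(grid.n_neurons):
            if not np.isfinite(pop[v]) or pop[v] <= 0 or pmax <= 0:
                continue
            r = rmax * np.sqrt(pop[v] / pmax)  # area proportional to count
            cx, cy = pos[v, 0] + pad, pos[v, 1] + pad
            out.append(f'<circle cx="{cx:.3f}" cy="{cy:.3f}" r="{r:.5f}" '
                       'fill="magenta" fill-opacity="0.6"/>')
    # toroidal seam
    out.append(f'<rect x="{pad/2:.0f}" y="{pad/2:.0f}" '
               f'width="{width-pad:.0f}" height="{height-pad:.0f}" '
               'fill="none" stroke="#333" stroke-dasharray="6 4"/>')
    out.append("</svg>")
    return "\n".join(out)
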