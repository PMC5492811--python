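"""Plot-boundary recovery from vegetation-index maps and spectra extraction.

Residual across-track geometric distortion in pushbroom imagery means
plot sides across the flight strip cannot be trusted from the nominal
field layout alone.  The approach here: run a Canny detector over a
vegetation-index map (the soil buffers between plots provide the
contrast), then snap the across-track sides of each nominal plot
rectangle to the nearest strong edge, keeping the along-track sides at
their nominal position.  Where no edge is found within the search
window the nominal side is kept and a warning is emitted, which makes
runs reproducible where a visual choice would not be.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import ndimage as ndi

from .core import HyperCube, PlotSpectra
from .simulate import PlotRect

__all__ = ["detect_edges", "edges_to_plots", "extract_polygon_spectra"]


def _gradient_magnitude(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient magnitude on the same scale the Canny detector uses.

    Gaussian smoothing followed by Sobel derivatives, so that a mean of
    this magnitude is directly usable as an absolute hysteresis
    threshold.
    """
    smoothed = ndi.gaussian_filter(image, sigma, mode="constant")
    jsobel = ndi.sobel(smoothed, axis=1)
    isobel = ndi.sobel(smoothed, axis=0)
    return np.hypot(isobel, jsobel)


def detect_edges(
    vi_map: np.ndarray, sigma: float = 0.5, n_segments: int = 4
) -> np.ndarray:
    """Canny edge mask with image-statistic thresholds, per segment.

    The image is split into ``n_segments`` equal bands along the strip
    axis (rows); within each segment the high hysteresis threshold is
    the mean of the directional gradient magnitudes of that segment and
    the low threshold is 40% of it.  The Gaussian pre-smoothing width
    is ``sigma`` (default 0.5).
    """
    from skimage.feature import canny

    vi_map = np.asarray(vi_map, float)
    if vi_map.ndim != 2:
        raise ValueError("vegetation-index map must be 2-D")
    edges = np.zeros(vi_map.shape, bool)
    bounds = np.linspace(0, vi_map.shape[0], n_segments + 1).astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        segment = vi_map[lo:hi]
        grad = _gradient_magnitude(segment, sigma)
        high = float(grad.mean())
        if high <= 0:
            continue  # constant segment: no edges
        low = 0.4 * high
        edges[lo:hi] = canny(
            segment, sigma=sigma, low_threshold=low, high_threshold=high
        )
    return edges


def edge_thresholds(vi_map: np.ndarray, sigma: float = 0.5) -> tuple[float, float]:
    """(high, low) hysteresis thresholds for one image segment."""
    grad = _gradient_magnitude(np.asarray(vi_map, float), sigma)
    high = float(grad.mean())
    return high, 0.4 * high


def edges_to_plots(
    edge_mask: np.ndarray,
    layout_prior: list[PlotRect],
    pixel_size: float = 0.2,
    origin: tuple[float, float] = (0.0, 0.0),
    search_window_m: float = 1.0,
    min_edge_support: float = 0.6,
) -> list[PlotRect]:
    """Snap the across-track sides of nominal plot rectangles to edges.

    The strip runs along x (image columns); the across-track plot sides
    are the left and right rectangle edges (constant-x lines).  A step
    boundary lies between two pixel columns and the detector thins it
    onto one of the two per row, so candidate boundaries are scored by
    the combined edge support of each adjacent column pair within the
    plot's row span.  Each side moves to the best-supported boundary
    inside ``search_window_m``, provided that support covers at least
    ``min_edge_support`` of the rows; otherwise the nominal side is
    kept and a warning emitted.  Along-track (y) sides are never moved.
    """
    edge_mask = np.asarray(edge_mask, bool)
    x0_map, y0_map = origin
    out = []
    window_px = max(1, int(round(search_window_m / pixel_size)))
    for rect in layout_prior:
        row_lo = int(np.floor((rect.y0 - y0_map) / pixel_size))
        row_hi = int(np.ceil((rect.y0 + rect.height - y0_map) / pixel_size))
        row_lo = max(row_lo, 0)
        row_hi = min(row_hi, edge_mask.shape[0])
        n_rows = max(1, row_hi - row_lo)
        band = edge_mask[row_lo:row_hi]
        support = band.sum(axis=0)
        # pair_support[i]: edge pixels backing a boundary between
        # columns i and i + 1
        pair_support = support[:-1] + support[1:]

        def snap(x_nominal: float) -> float:
            # boundary between columns i and i+1 sits at col coordinate
            # i + 0.5 relative to pixel centers
            b_nom = (x_nominal - x0_map) / pixel_size - 0.5
            lo = max(0, int(np.floor(b_nom)) - window_px)
            hi = min(pair_support.size, int(np.ceil(b_nom)) + window_px + 1)
            if hi <= lo:
                return x_nominal
            local = pair_support[lo:hi]
            if local.max() < min_edge_support * n_rows:
                warnings.warn(
                    f"no strong edge within {search_window_m} m of x={x_nominal} "
                    f"for plot {rect.plot_id}; keeping nominal side",
                    stacklevel=3,
                )
                return x_nominal
            # of equally supported boundaries take the one nearest nominal
            best = lo + np.flatnonzero(local == local.max())
            b = best[np.argmin(np.abs(best - b_nom))]
            return x0_map + (b + 0.5) * pixel_size

        x_left = snap(rect.x0)
        x_right = snap(rect.x0 + rect.width)
        if x_right <= x_left:
            warnings.warn(
                f"snapped sides of plot {rect.plot_id} collapsed; keeping nominal",
                stacklevel=2,
            )
            out.append(rect)
        else:
            out.append(replace(rect, x0=x_left, width=x_right - x_left))
    return out


def extract_polygon_spectra(
    cube: HyperCube, polygon: PlotRect, dap: int = 1
) -> PlotSpectra:
    """All cube pixels whose centers fall inside the rectangle.

    Containment is half-open: a center on the minimum edge is inside,
    on the maximum edge outside, so pixel counts are deterministic and
    adjacent rectangles partition the raster.
    """
    rows, cols, _ = cube.shape
    x0, y0 = cube.origin
    xc = x0 + np.arange(cols) * cube.pixel_size
    yc = y0 + np.arange(rows) * cube.pixel_size
    in_x = (xc >= polygon.x0) & (xc < polygon.x0 + polygon.width)
    in_y = (yc >= polygon.y0) & (yc < polygon.y0 + polygon.height)
    if not in_x.any() or not in_y.any():
        raise ValueError(
            f"polygon {polygon.plot_id} contains no pixel centers of the raster"
        )
    block = cube.data[np.ix_(in_y, in_x)]
    return PlotSpectra(
        plot_id=polygon.plot_id,
        treatment=polygon.treatment or "",
        dap=dap,
        band_set=cube.band_set,
        reflectance=block.reshape(-1, cube.shape[2]),
    )
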