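"""Histogram of curvature over scale (HOCS) from the area integral invariant.

The boundary shape of the segmented plant carries stress information: leaf
rolling and loss of turgor ruffle the silhouette. Curvature at a boundary
point is measured by the *normalized area integral invariant* (AII): the
fraction of a disc of radius r, centered at the point, that lies inside the
region. On a straight edge the fraction is 0.5; convex points fall below
0.5, concave points above. Computing the AII at every boundary point for a
ladder of radii (default 5, 10, ..., 125 px) and histogramming the values
into a few uniform bins per radius (default 5) yields a rotation- and
translation-invariant multi-scale descriptor of boundary curvature.

Implementation: the per-pixel count of foreground within a disc is a 2-D
convolution of the mask with a binary disc kernel, evaluated here with an
FFT (zero padding makes out-of-frame pixels count as background) and rounded
back to exact integer counts; boundary points are foreground pixels with at
least one background 8-neighbor, image border included, and each interior
hole contributes its boundary too.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

#: Default radius ladder in pixels: 5 to 125 inclusive, step 5 (25 scales).
DEFAULT_RADII: Tuple[int, ...] = tuple(range(5, 126, 5))
DEFAULT_N_BINS = 5

_STRUCT8 = np.ones((3, 3), bool)


@dataclasses.dataclass
class HOCSDescriptor:
    """Per-scale curvature histograms: matrix of shape (n_scales, n_bins)."""

    matrix: np.ndarray
    radii: Tuple[int, ...]
    bin_edges: np.ndarray

    def flatten(self) -> np.ndarray:
        return self.matrix.ravel()

    def feature_names(self) -> List[str]:
        return [
            f"hocs_r{r}_b{b}" for r in self.radii for b in range(self.matrix.shape[1])
        ]


def disc_offsets(radius: int) -> np.ndarray:
    """Integer (dy, dx) offsets of the discrete disc: dy^2 + dx^2 <= r^2."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    span = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    keep = dy**2 + dx**2 <= radius**2
    return np.column_stack([dy[keep], dx[keep]])


def disc_kernel(radius: int) -> np.ndarray:
    span = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    return (dy**2 + dx**2 <= radius**2)


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 8-adjacent to background (frame edge counts)."""
    mask = np.asarray(mask, bool)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return mask & ~eroded


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary points of all foreground components, as (y, x) rows.

    Each boundary pixel appears exactly once. Within a component, points are
    chained by greedy nearest-neighbor walking from the topmost-leftmost
    boundary pixel — adjacent boundary pixels end up adjacent in the list,
    which is what boundary-order consumers (plotting, arc traversal) need;
    the histogram descriptor itself is order-free. Components are emitted in
    label order and their boundaries concatenated.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot trace the boundary of an empty mask")
    bnd = boundary_mask(mask)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    chains = []
    for lab in range(1, n + 1):
        pts = np.column_stack(np.nonzero(bnd & (labels == lab)))
        chains.append(_chain_points(pts))
    return np.vstack(chains)


def _chain_points(pts: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbor ordering starting at the topmost-leftmost point."""
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    remaining = pts.astype(float)
    order = [0]
    used = np.zeros(len(pts), bool)
    used[0] = True
    cur = remaining[0]
    for _ in range(len(pts) - 1):
        d2 = np.where(used, np.inf, ((remaining - cur) ** 2).sum(axis=1))
        nxt = int(np.argmin(d2))
        order.append(nxt)
        used[nxt] = True
        cur = remaining[nxt]
    return pts[order]


def area_integral_invariant(mask: np.ndarray, point: Tuple[int, int], radius: int) -> float:
    """AII at one point: fraction of the radius-r disc that is foreground.

    ``point`` is (y, x). Disc membership is squared-distance <= radius^2;
    pixels outside the image frame count as background, so the fraction
    drops near the frame edge by construction.
    """
    mask = np.asarray(mask, bool)
    y, x = point
    offs = disc_offsets(radius)
    ys, xs = y + offs[:, 0], x + offs[:, 1]
    inside = (ys >= 0) & (ys < mask.shape[0]) & (xs >= 0) & (xs < mask.shape[1])
    count = int(np.count_nonzero(mask[ys[inside], xs[inside]]))
    return count / len(offs)


def aii_field(mask: np.ndarray, radius: int) -> np.ndarray:
    """AII at every pixel at once, via FFT convolution with the disc kernel.

    The convolution of the 0/1 mask with the 0/1 disc counts foreground
    pixels per disc; results are rounded back to exact integers (counts are
    integral, FFT error is ~1e-9 at these sizes) and divided by the disc
    area.
    """
    mask = np.asarray(mask, float)
    kernel = disc_kernel(radius).astype(float)
    counts = np.rint(fftconvolve(mask, kernel, mode="same"))
    return counts / kernel.sum()


def hocs_descriptor(
    mask: np.ndarray,
    radii: Sequence[int] = DEFAULT_RADII,
    n_bins: int = DEFAULT_N_BINS,
) -> HOCSDescriptor:
    """Multi-scale curvature histogram of the mask boundary.

    For each radius, the AII is evaluated at every boundary point and
    histogrammed into ``n_bins`` uniform bins on [0, 1] (right edge of the
    last bin closed); each row is normalized to sum to 1, so scales are
    directly comparable. Rows are ordered by increasing radius.
    """
    mask = np.asarray(mask, bool)
    bnd = boundary_mask(mask)
    ys, xs = np.nonzero(bnd)
    if ys.size == 0:
        raise ValueError("empty boundary: mask has no foreground")
    radii = tuple(sorted(int(r) for r in radii))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    matrix = np.empty((len(radii), n_bins))
    for i, r in enumerate(radii):
        values = aii_field(mask, r)[ys, xs]
        hist, _ = np.histogram(values, bins=edges)
        matrix[i] = hist / hist.sum()
    return HOCSDescriptor(matrix=matrix, radii=radii, bin_edges=edges)


def parse_radii(spec: str) -> Tuple[int, ...]:
    """Parse a ``start:stop:step`` radius grid, stop inclusive (e.g. 5:125:5)."""
    start, stop, step = (int(p) for p in spec.split(":"))
    return tuple(range(start, stop + 1, step))
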