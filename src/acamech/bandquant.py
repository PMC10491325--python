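"""Empty-band quantification of elastin multiphoton projections.

In multiphoton cross-sections of the arterial wall, degradation of the
elastic-fiber network shows up as a signal-free radial band at the
media-adventitia interface.  The quantification works on a grayscale maximum
intensity projection: the wall is aligned vertically (radial axis running
left-to-right), a rectangular region of interest is binarized, discretized
into a 30 x 30 grid, and the foreground area fraction of each grid column is
profiled along the radial axis.  Columns whose mean area fraction falls two
standard deviations below the media's are flagged; the longest contiguous
flagged run between media and adventitia is the empty band, and its width is
reported in micrometres.  Per-sample widths average the band over several
measurement locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

GRID_SIZE = 30


@dataclass
class ProjectionImage:
    """2D grayscale projection with physical pixel size (um / pixel).

    The arterial wall is assumed pre-rotated so that it runs vertically and
    the radial direction is horizontal; ``intima_side`` declares which image
    edge the intima faces.
    """

    pixels: np.ndarray
    pixel_size: float
    intima_side: str = "left"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um per pixel)")


@dataclass
class GridProfile:
    """Area-fraction profile of a 30 x 30 grid over a region of interest."""

    cell_fractions: np.ndarray          # (30, 30), rows x columns
    column_means: np.ndarray            # (30,)
    column_width: float                 # um per grid column
    region_columns: dict[str, tuple[int, int]] = field(default_factory=dict)

    def region_stats(self, region: str) -> tuple[float, float]:
        """Mean and sample SD of the column means inside a declared region."""
        lo, hi = self.region_columns[region]
        vals = self.column_means[lo : hi + 1]
        return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


@dataclass(frozen=True)
class BandCall:
    """Detected empty band: threshold used, flagged columns, width in um."""

    threshold: float
    flagged_columns: tuple[int, ...]
    width: float
    contiguous: bool

    @property
    def exists(self) -> bool:
        return self.width > 0


def max_projection(zstack: np.ndarray, pixel_size: float = 1.0) -> ProjectionImage:
    """Maximum intensity projection of a z-stack along its first axis."""
    zstack = np.asarray(zstack)
    if zstack.ndim == 2:
        zstack = zstack[None, ...]
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("expected a non-empty z-stack of 2D planes")
    return ProjectionImage(pixels=zstack.max(axis=0), pixel_size=pixel_size)


def binarize(img: ProjectionImage, method: str = "otsu") -> np.ndarray:
    """Threshold a projection into a boolean foreground (elastin signal) mask.

    ``method`` is ``"otsu"`` or ``"fixed:<value>"``.  Foreground means signal
    pixels regardless of how a particular viewer renders the binary image.
    """
    px = np.asarray(img.pixels, dtype=float)
    if method == "otsu":
        if np.ptp(px) == 0:
            raise ValueError(
                "constant image: Otsu threshold undefined, use method='fixed:<value>'"
            )
        thr = threshold_otsu(px)
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return px > thr


def grid_area_fractions(
    binary: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    regions: dict[str, tuple[int, int]] | None = None,
    pixel_size: float = 1.0,
) -> GridProfile:
    """Per-cell foreground fractions on a 30 x 30 grid over a ROI.

    Parameters
    ----------
    binary : boolean image, foreground = signal.
    roi : (row0, col0, height, width) in pixels; whole image when None.
    regions : grid-column index ranges (inclusive) for e.g. "media" and
        "adventitia", supplied by the user after visual annotation.
    pixel_size : um per pixel, used to express the column width physically.

    The ROI is partitioned into near-equal cells; remainder pixels attach to
    the last row/column so total area is conserved.
    """
    binary = np.asarray(binary).astype(bool)
    if roi is None:
        roi = (0, 0, binary.shape[0], binary.shape[1])
    r0, c0, h, w = roi
    if h < GRID_SIZE or w < GRID_SIZE:
        raise ValueError(
            f"ROI of {h}x{w} px is smaller than the {GRID_SIZE}x{GRID_SIZE} grid"
        )
    sub = binary[r0 : r0 + h, c0 : c0 + w]

    # equal cells of floor size; remainder pixels attach to the last row/column
    row_edges = np.arange(GRID_SIZE + 1) * (h // GRID_SIZE)
    col_edges = np.arange(GRID_SIZE + 1) * (w // GRID_SIZE)
    row_edges[-1], col_edges[-1] = h, w

    frac = np.empty((GRID_SIZE, GRID_SIZE))
    for i in range(GRID_SIZE):
        for j in range(GRID_SIZE):
            cell = sub[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            frac[i, j] = cell.mean()
    return GridProfile(
        cell_fractions=frac,
        column_means=frac.mean(axis=0),
        column_width=w * pixel_size / GRID_SIZE,
        region_columns=dict(regions or {}),
    )


def band_threshold(media_mean: float, media_sd: float) -> float:
    """Empty-band cutoff: media mean area fraction minus two SDs, floored at 0."""
    if media_sd < 0:
        raise ValueError("standard deviation must be non-negative")
    return max(media_mean - 2.0 * media_sd, 0.0)


def detect_band(profile: GridProfile, threshold: float) -> BandCall:
    """Locate the empty band between the media and adventitia regions.

    Columns from the start of the media range through the end of the
    adventitia range with mean area fraction strictly below ``threshold`` are
    flagged; the band is the longest contiguous flagged run (first such run on
    ties) and its width is run length x column width.  Width 0 means no band.
    """
    if "media" not in profile.region_columns or "adventitia" not in profile.region_columns:
        raise ValueError("profile must declare 'media' and 'adventitia' column ranges")
    m_lo, m_hi = profile.region_columns["media"]
    a_lo, a_hi = profile.region_columns["adventitia"]
    if m_lo > a_lo:
        raise ValueError("media range must precede adventitia range radially")

    window = range(m_lo, a_hi + 1)
    flagged = [j for j in window if profile.column_means[j] < threshold]
    if not flagged:
        return BandCall(threshold=threshold, flagged_columns=(), width=0.0, contiguous=True)

    # split flagged indices into contiguous runs, keep the longest
    runs: list[list[int]] = [[flagged[0]]]
    for j in flagged[1:]:
        if j == runs[-1][-1] + 1:
            runs[-1].append(j)
        else:
            runs.append([j])
    best = max(runs, key=len)
    return BandCall(
        threshold=threshold,
        flagged_columns=tuple(best),
        width=len(best) * profile.column_width,
        contiguous=len(runs) == 1,
    )


def sample_band_width(calls: list[BandCall]) -> float:
    """Per-sample band width: mean over measurement locations (4 expected)."""
    if not calls:
        raise ValueError("no band calls to average")
    if len(calls) != 4:
        warnings.warn(
            f"expected 4 measurement locations, got {len(calls)}", stacklevel=2
        )
    return float(np.mean([c.width for c in calls]))
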