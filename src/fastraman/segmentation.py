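"""Auto-fluorescence image segmentation.

The AF image guides where Raman sampling is worthwhile: collagen-rich
dermis fluoresces strongly under 405 nm excitation and is screened out,
and the remaining tissue is partitioned into connected candidate segments
by fluorescence intensity.  Segments are the unit of all downstream
sampling and diagnosis.

Pipeline: ``detect_tissue`` (tissue vs bare substrate) ->
``screen_dermis`` (bright collagen mask) -> ``extract_segments``
(intensity bands -> 8-connected components -> merges).  All steps are
deterministic: the same image always yields the same segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian as _gaussian_filter
from skimage.filters import threshold_otsu


class EmptyCassetteError(ValueError):
    """Raised when no pixel rises above the background level."""


@dataclass
class Segment:
    """One connected candidate region of the non-dermis tissue area."""

    id: int
    rows: np.ndarray  # pixel row indices (0-based)
    cols: np.ndarray  # pixel col indices
    mean_af: float

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid in pixel coordinates (may fall outside)."""
        return float(self.rows.mean()), float(self.cols.mean())


@dataclass
class SegmentationResult:
    tissue_mask: np.ndarray  # bool, pixels containing tissue
    dermis_mask: np.ndarray  # bool, screened-out collagen-rich dermis
    segments: list[Segment]
    label_image: np.ndarray = field(default=None)  # 0 = none, else segment id

    def __post_init__(self) -> None:
        if self.label_image is None:
            lab = np.zeros(self.tissue_mask.shape, np.int32)
            for seg in self.segments:
                lab[seg.rows, seg.cols] = seg.id
            self.label_image = lab

    def segment_by_id(self, seg_id: int) -> Segment:
        for seg in self.segments:
            if seg.id == seg_id:
                return seg
        raise KeyError(seg_id)


def detect_tissue(
    af_image: np.ndarray,
    background_fraction: float = 0.04,
    full_scale: float | None = None,
) -> np.ndarray:
    """Mask of pixels containing tissue (vs bare substrate / empty window).

    The threshold is Otsu's on the full image, clamped from above by an
    absolute background ceiling (``background_fraction`` of full scale):
    the clamp keeps a full-footprint image — where Otsu would split within
    the tissue — entirely inside the mask.  If even the upper Otsu class
    sits below the ceiling the cassette is empty and an
    :class:`EmptyCassetteError` is raised.  Only the largest 8-connected
    component is kept.
    """
    af = np.asarray(af_image, float)
    if af.size == 0:
        raise EmptyCassetteError("empty cassette: image has no pixels")
    if full_scale is None:
        full_scale = (
            float(np.iinfo(af_image.dtype).max)
            if np.issubdtype(np.asarray(af_image).dtype, np.integer)
            else 65535.0
        )
    floor = background_fraction * full_scale
    if af.max() == af.min():
        hi_mean = af.max()
    else:
        t = threshold_otsu(af)
        hi = af > t
        hi_mean = af[hi].mean() if hi.any() else af.max()
    if hi_mean < floor:
        raise EmptyCassetteError(
            "empty cassette: no pixel rises above the background level"
        )
    thresh = min(threshold_otsu(af) if af.max() > af.min() else floor, floor)
    mask = af > thresh
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def screen_dermis(
    af_image: np.ndarray,
    tissue_mask: np.ndarray,
    threshold: float | None = None,
    bimodality_min: float = 0.80,
    relative_fallback: float = 0.70,
) -> np.ndarray:
    """Mask of collagen-rich (high-AF) dermis pixels within the tissue.

    With ``threshold`` given, simply ``af > threshold`` within tissue
    (exposed so the threshold-monotonicity property can be exercised).
    Otherwise the threshold is chosen per image: Otsu's on the tissue
    pixels when its normalised between-class variance indicates genuine
    bimodality, else ``relative_fallback`` times the median tissue AF.
    The fallback handles the two regimes where Otsu misbehaves — a
    homogeneous (e.g. all-dermis) layer, and a dermis layer with only a
    tiny dark inclusion — under the assumption that the dominant tissue
    mode is dermis.
    """
    if not np.any(tissue_mask):
        raise ValueError("tissue mask is empty")
    af = np.asarray(af_image, float)
    vals = af[tissue_mask]
    if threshold is None:
        threshold = _dermis_threshold(vals, bimodality_min, relative_fallback)
    return tissue_mask & (af > threshold)


def _dermis_threshold(
    vals: np.ndarray, bimodality_min: float, relative_fallback: float
) -> float:
    if vals.max() == vals.min():
        return relative_fallback * float(np.median(vals))
    t = threshold_otsu(vals)
    lo, hi = vals[vals <= t], vals[vals > t]
    if lo.size == 0 or hi.size == 0:
        return relative_fallback * float(np.median(vals))
    p = hi.size / vals.size
    between = p * (1 - p) * (hi.mean() - lo.mean()) ** 2
    total = vals.var()
    if total > 0 and between / total >= bimodality_min:
        return float(t)
    return relative_fallback * float(np.median(vals))


def extract_segments(
    af_image: np.ndarray,
    tissue_mask: np.ndarray,
    dermis_mask: np.ndarray,
    n_bands: int = 4,
    min_area_px: int = 10,
    merge_delta: float = 1500.0,
    smooth_sigma: float = 1.5,
) -> SegmentationResult:
    """Partition the non-dermis tissue area into candidate segments.

    The AF image is lightly smoothed, the non-dermis intensities are
    quantised into ``n_bands`` equal-frequency bands, and 8-connected
    components within each band become provisional segments.  Two merge
    steps follow: components smaller than ``min_area_px`` are absorbed by
    the adjacent segment with the closest mean AF, and adjacent segments
    whose (raw) mean AF differs by less than ``merge_delta`` counts are
    joined, so a homogeneous region whose noise straddles a band edge
    stays one segment.  Every non-dermis tissue pixel ends up in exactly
    one segment.
    """
    work = tissue_mask & ~dermis_mask
    if not work.any():
        return SegmentationResult(
            tissue_mask=tissue_mask, dermis_mask=dermis_mask, segments=[]
        )
    af = np.asarray(af_image, float)
    smooth = _gaussian_filter(af, sigma=smooth_sigma, preserve_range=True)
    vals = smooth[work]
    n_bands = max(1, min(n_bands, vals.size))
    edges = np.quantile(vals, np.linspace(0, 1, n_bands + 1)[1:-1])
    band = np.digitize(vals, np.unique(edges))
    band_map = np.full(af.shape, 0, np.int32)
    band_map[work] = band + 1
    lab = measure.label(band_map, background=0, connectivity=2)

    roots = _merge_components(lab, af, work, min_area_px, merge_delta)
    return _build_result(tissue_mask, dermis_mask, af, roots)


def _merge_components(
    lab: np.ndarray,
    af: np.ndarray,
    work: np.ndarray,
    min_area_px: int,
    merge_delta: float,
) -> np.ndarray:
    """Union-find merge of labelled components; returns final root labels."""
    n = lab.max()
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    count = np.bincount(lab[work], minlength=n + 1).astype(float)
    total = np.bincount(lab[work], weights=af[work], minlength=n + 1)

    # 8-connected adjacency between different labels
    H, W = lab.shape
    pairs: set[tuple[int, int]] = set()
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        a = lab[r0:r1, c0:c1]
        b = lab[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        sel = (a > 0) & (b > 0) & (a != b)
        if not sel.any():
            continue
        x = a[sel].astype(np.int64)
        y = b[sel].astype(np.int64)
        lo, hi_ = np.minimum(x, y), np.maximum(x, y)
        for code in np.unique(lo * (n + 1) + hi_):
            pairs.add((int(code // (n + 1)), int(code % (n + 1))))
    edges = sorted(pairs)

    def do_merge(ra: int, rb: int) -> None:
        # keep the lower root id for determinism
        ra, rb = (ra, rb) if ra < rb else (rb, ra)
        parent[rb] = ra
        count[ra] += count[rb]
        total[ra] += total[rb]

    changed = True
    while changed:
        changed = False
        # root-level adjacency
        adj: dict[int, set[int]] = {}
        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra != rb:
                adj.setdefault(ra, set()).add(rb)
                adj.setdefault(rb, set()).add(ra)
        # absorb undersized components into closest-mean neighbour
        small = sorted(
            r for r in adj if parent[r] == r and 0 < count[r] < min_area_px
        )
        for r in small:
            r = find(r)
            if count[r] >= min_area_px or r not in adj:
                continue
            neigh = [find(x) for x in adj[r] if find(x) != r]
            if not neigh:
                continue
            mean_r = total[r] / count[r]
            best = min(neigh, key=lambda x: (abs(total[x] / count[x] - mean_r), x))
            do_merge(r, best)
            changed = True
        if changed:
            continue
        # join adjacent segments of near-identical mean AF
        best_pair, best_diff = None, merge_delta
        for a, b in edges:
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            diff = abs(total[ra] / count[ra] - total[rb] / count[rb])
            if diff < best_diff:
                best_pair, best_diff = (ra, rb), diff
        if best_pair is not None:
            do_merge(*best_pair)
            changed = True

    out = np.zeros_like(lab)
    lut = np.array([find(i) for i in range(n + 1)])
    out[work] = lut[lab[work]]
    return out


def _build_result(
    tissue_mask: np.ndarray,
    dermis_mask: np.ndarray,
    af: np.ndarray,
    roots: np.ndarray,
) -> SegmentationResult:
    segments: list[Segment] = []
    label_image = np.zeros(roots.shape, np.int32)
    # deterministic ids: order by first pixel in row-major order
    ids = [int(v) for v in np.unique(roots) if v > 0]
    firsts = []
    flat = roots.ravel()
    for v in ids:
        firsts.append((int(np.argmax(flat == v)), v))
    firsts.sort()
    for new_id, (_, v) in enumerate(firsts, start=1):
        rr, cc = np.nonzero(roots == v)
        segments.append(
            Segment(id=new_id, rows=rr, cols=cc, mean_af=float(af[rr, cc].mean()))
        )
        label_image[rr, cc] = new_id
    return SegmentationResult(
        tissue_mask=tissue_mask,
        dermis_mask=dermis_mask,
        segments=segments,
        label_image=label_image,
    )


def segment_layer(af_image: np.ndarray, **kwargs) -> SegmentationResult:
    """Full segmentation: tissue detection, dermis screen, segment extraction."""
    tissue = detect_tissue(af_image)
    dermis = screen_dermis(af_image, tissue)
    return extract_segments(af_image, tissue, dermis, **kwargs)
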