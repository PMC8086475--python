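"""Synthetic excised-tissue-layer phantoms.

A phantom is a digital stand-in for one excised skin layer pressed flat
against the measurement window of a tissue cassette: a ground-truth tissue
class label map, a matching auto-fluorescence (AF) image in which
collagen-rich dermis is by construction the brightest class, and an
on-demand Raman spectrum generator whose noise scales like shot noise with
acquisition time (sigma ~ 1/sqrt(exposure)).

Everything is reproducible: the same (spec, seed) pair yields a
bit-identical phantom, and spectra are deterministic in their own seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .library import TISSUE_CLASSES, TRAINABLE_CLASSES, WAVENUMBERS, spectral_library

#: Maximum layer edge accepted by the cassette, mm.
MAX_LAYER_MM = 20.0

#: Reference acquisition time (s) at which ``raman_noise_sd`` is specified.
REFERENCE_EXPOSURE_S = 2.0

#: Mean AF intensity per class (16-bit counts).  Dermis is deliberately the
#: brightest class; substrate (empty cassette window) the darkest.
AF_MEANS: dict[str, float] = {
    "dermis": 40000.0,
    "inflamed_dermis": 21000.0,
    "epidermis": 16500.0,
    "muscle": 13500.0,
    "hair_follicle": 11500.0,
    "bcc": 9500.0,
    "fat": 7000.0,
    "blood": 4500.0,
    "out_of_contact": 3500.0,
    "substrate": 600.0,
    "ink": 5500.0,
}

#: Integer code per class used in label maps (0-based, order of TISSUE_CLASSES).
CLASS_CODES: dict[str, int] = {c: i for i, c in enumerate(TISSUE_CLASSES)}
CODE_CLASSES: dict[int, str] = {i: c for c, i in CLASS_CODES.items()}


@dataclass
class Spectrum:
    """One Raman measurement at a stage position.

    Stage coordinates are continuous micrometres with the origin at the
    centre of the image's top-left pixel (x along columns, y along rows),
    independent of the pixel grid.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    position: tuple[float, float]  # (x_um, y_um)
    exposure: float  # seconds
    true_class: str | None = None  # ground truth, phantom mode only

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.wavenumbers.size < 2:
            raise ValueError("spectrum axis needs at least 2 points")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError("axis and intensities differ in length")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")


@dataclass(frozen=True)
class RegionSpec:
    """A planted region: a disc or axis-aligned rectangle of one class."""

    tissue_class: str
    centre_mm: tuple[float, float]  # (x_mm, y_mm) from layer top-left
    shape: str = "disc"  # "disc" | "rect"
    diameter_um: float = 500.0  # disc diameter
    size_um: tuple[float, float] | None = None  # rect (width, height)

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.shape not in ("disc", "rect"):
            raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Plain-text-configurable description of one synthetic layer."""

    width_mm: float = 6.0
    height_mm: float = 6.0
    pixel_pitch_um: float = 25.0
    background: str = "dermis"
    footprint: str = "full"  # "full" | "ellipse"
    margin_mm: float = 0.0  # substrate border inside the image
    regions: list[RegionSpec] = field(default_factory=list)
    raman_noise_sd: float = 0.02  # at REFERENCE_EXPOSURE_S, peak-normalised units
    af_noise_sd: float = 700.0  # counts
    contrast: float = 1.0  # spectral separability knob

    @classmethod
    def from_yaml(cls, text_or_path) -> "PhantomSpec":
        if hasattr(text_or_path, "read"):
            raw = yaml.safe_load(text_or_path)
        else:
            text = str(text_or_path)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text) as fh:
                    raw = yaml.safe_load(fh)
            else:
                raw = yaml.safe_load(text)
        regions = [
            RegionSpec(
                tissue_class=r["tissue_class"],
                centre_mm=tuple(r["centre_mm"]),
                shape=r.get("shape", "disc"),
                diameter_um=r.get("diameter_um", 500.0),
                size_um=tuple(r["size_um"]) if r.get("size_um") else None,
            )
            for r in raw.pop("regions", [])
        ]
        return cls(regions=regions, **raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["regions"] = [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in r.items() if v is not None}
            for r in d["regions"]
        ]
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class TissueLayerPhantom:
    """Ground truth + AF image + spectral source for one simulated layer."""

    spec: PhantomSpec
    seed: int
    label_map: np.ndarray  # int codes, shape (rows, cols)
    af_image: np.ndarray  # float counts, same shape
    spectral_library: dict[str, np.ndarray]
    wavenumbers: np.ndarray

    @property
    def pixel_pitch_um(self) -> float:
        return self.spec.pixel_pitch_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def class_at(self, position: tuple[float, float]) -> str:
        """Tissue class at the pixel nearest a continuous stage position."""
        row, col = self._nearest_pixel(position)
        return CODE_CLASSES[int(self.label_map[row, col])]

    def _nearest_pixel(self, position: tuple[float, float]) -> tuple[int, int]:
        x_um, y_um = position
        pitch = self.pixel_pitch_um
        nrow, ncol = self.label_map.shape
        col = int(round(x_um / pitch))
        row = int(round(y_um / pitch))
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(
                f"stage position ({x_um:.1f}, {y_um:.1f}) um is outside the layer"
            )
        return row, col

    def class_mask(self, tissue_class: str) -> np.ndarray:
        return self.label_map == CLASS_CODES[tissue_class]


def _region_mask(
    region: RegionSpec, shape: tuple[int, int], pitch_um: float
) -> np.ndarray:
    rows = np.arange(shape[0])[:, None] * pitch_um  # y of pixel centres
    cols = np.arange(shape[1])[None, :] * pitch_um  # x of pixel centres
    cx = region.centre_mm[0] * 1000.0
    cy = region.centre_mm[1] * 1000.0
    if region.shape == "disc":
        r = region.diameter_um / 2.0
        return (cols - cx) ** 2 + (rows - cy) ** 2 <= r**2
    w, h = region.size_um  # type: ignore[misc]
    return (np.abs(cols - cx) <= w / 2.0) & (np.abs(rows - cy) <= h / 2.0)


def generate_layer(spec: PhantomSpec, seed: int) -> TissueLayerPhantom:
    """Build a reproducible phantom layer from its spec.

    Raises ``ValueError`` if the layer exceeds the 20 x 20 mm cassette
    limit, if a planted region falls outside the tissue footprint, or if
    two planted regions overlap.
    """
    if spec.width_mm > MAX_LAYER_MM or spec.height_mm > MAX_LAYER_MM:
        raise ValueError(
            f"layer {spec.width_mm} x {spec.height_mm} mm exceeds the "
            f"{MAX_LAYER_MM:.0f} x {MAX_LAYER_MM:.0f} mm cassette limit"
        )
    pitch = spec.pixel_pitch_um
    ncol = max(2, int(round(spec.width_mm * 1000.0 / pitch)))
    nrow = max(2, int(round(spec.height_mm * 1000.0 / pitch)))
    shape = (nrow, ncol)

    # tissue footprint: everything else is bare substrate
    tissue = np.ones(shape, bool)
    if spec.margin_mm > 0:
        m = int(round(spec.margin_mm * 1000.0 / pitch))
        tissue[:] = False
        tissue[m : nrow - m, m : ncol - m] = True
    if spec.footprint == "ellipse":
        rr = (np.arange(nrow)[:, None] - (nrow - 1) / 2.0) / (nrow / 2.0)
        cc = (np.arange(ncol)[None, :] - (ncol - 1) / 2.0) / (ncol / 2.0)
        tissue &= rr**2 + cc**2 <= 1.0
    elif spec.footprint != "full":
        raise ValueError(f"unknown footprint {spec.footprint!r}")
    if not tissue.any():
        raise ValueError("tissue footprint is empty")

    label = np.full(shape, CLASS_CODES["substrate"], dtype=np.int16)
    label[tissue] = CLASS_CODES[spec.background]

    painted = np.zeros(shape, bool)
    for region in spec.regions:
        cx, cy = (v * 1000.0 for v in region.centre_mm)
        if region.shape == "disc":
            rx = ry = region.diameter_um / 2.0
        else:
            rx, ry = (v / 2.0 for v in region.size_um)
        if (
            cx - rx < 0
            or cy - ry < 0
            or cx + rx > spec.width_mm * 1000.0
            or cy + ry > spec.height_mm * 1000.0
        ):
            raise ValueError(
                f"region {region.tissue_class!r} at {region.centre_mm} mm "
                "extends outside the layer"
            )
        mask = _region_mask(region, shape, pitch)
        if not mask.any():
            raise ValueError(
                f"region {region.tissue_class!r} at {region.centre_mm} mm "
                "covers no pixel"
            )
        if np.any(mask & ~tissue):
            raise ValueError(
                f"region {region.tissue_class!r} at {region.centre_mm} mm "
                "extends outside the tissue footprint"
            )
        if np.any(mask & painted):
            raise ValueError(
                f"region {region.tissue_class!r} at {region.centre_mm} mm "
                "overlaps a previously planted region"
            )
        label[mask] = CLASS_CODES[region.tissue_class]
        painted |= mask

    rng = np.random.default_rng(seed)
    af = np.empty(shape, float)
    for cls, code in CLASS_CODES.items():
        sel = label == code
        if sel.any():
            af[sel] = AF_MEANS[cls]
    af += rng.normal(0.0, spec.af_noise_sd, size=shape)
    af = np.clip(af, 0.0, 65535.0)

    return TissueLayerPhantom(
        spec=spec,
        seed=seed,
        label_map=label,
        af_image=af,
        spectral_library=spectral_library(spec.contrast),
        wavenumbers=WAVENUMBERS.copy(),
    )


def spectrum_at(
    phantom: TissueLayerPhantom,
    position: tuple[float, float],
    exposure: float,
    seed: int,
) -> Spectrum:
    """Simulate one Raman acquisition at a continuous stage position.

    The returned intensities are the class template at the nearest pixel
    plus a smooth random quadratic auto-fluorescence baseline plus
    zero-mean Gaussian noise with standard deviation
    ``raman_noise_sd * sqrt(REFERENCE_EXPOSURE_S / exposure)`` — i.e. the
    shot-noise-like 1/sqrt(t) scaling.  Out-of-contact positions carry a
    zero template, so their signal-to-noise ratio is below the contact
    threshold by construction.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    cls = phantom.class_at(position)  # raises if outside the layer
    rng = np.random.default_rng(seed)
    wn = phantom.wavenumbers
    u = np.linspace(-1.0, 1.0, wn.size)
    baseline = (
        rng.uniform(0.05, 0.30)
        + rng.uniform(-0.20, 0.20) * u
        + rng.uniform(-0.15, 0.15) * u**2
    )
    sd = phantom.spec.raman_noise_sd * np.sqrt(REFERENCE_EXPOSURE_S / exposure)
    intens = phantom.spectral_library[cls] + baseline + rng.normal(0.0, sd, wn.size)
    return Spectrum(
        wavenumbers=wn,
        intensities=intens,
        position=tuple(position),
        exposure=float(exposure),
        true_class=cls,
    )


def training_set(
    n_per_class: int,
    seed: int,
    classes: tuple[str, ...] = TRAINABLE_CLASSES,
    contrast: float = 1.0,
    raman_noise_sd: float = 0.02,
    exposure: float = REFERENCE_EXPOSURE_S,
    amplitude_jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a labelled spectral training matrix from the template library.

    ``amplitude_jitter`` multiplies each drawn spectrum's template by a
    lognormal-ish factor exp(N(0, jitter)), emulating specimen-to-specimen
    signal-strength variation.  Returns (X, y) with X of shape
    (n_per_class * len(classes), n_wavenumbers) and y the class names.
    """
    rng = np.random.default_rng(seed)
    lib = spectral_library(contrast)
    wn = WAVENUMBERS
    u = np.linspace(-1.0, 1.0, wn.size)
    sd = raman_noise_sd * np.sqrt(REFERENCE_EXPOSURE_S / exposure)
    rows, labels = [], []
    for cls in classes:
        for _ in range(n_per_class):
            gain = float(np.exp(rng.normal(0.0, amplitude_jitter))) if amplitude_jitter else 1.0
            baseline = (
                rng.uniform(0.05, 0.30)
                + rng.uniform(-0.20, 0.20) * u
                + rng.uniform(-0.15, 0.15) * u**2
            )
            rows.append(gain * lib[cls] + baseline + rng.normal(0.0, sd, wn.size))
            labels.append(cls)
    return np.asarray(rows), np.asarray(labels)


def random_layer_spec(
    rng: np.random.Generator,
    with_bcc: bool,
    width_mm: float = 6.0,
    height_mm: float = 6.0,
    bcc_diameter_um: tuple[float, float] = (300.0, 800.0),
    n_benign_regions: tuple[int, int] = (2, 4),
    **spec_kwargs,
) -> PhantomSpec:
    """Draw a randomised layer spec resembling a Mohs excision layer.

    Dermis background with a few benign structures (fat, epidermis,
    inflamed dermis, muscle, hair follicle) and, if requested, one planted
    BCC disc.  Regions are placed on a jittered grid so they never overlap.
    """
    candidates = ["fat", "epidermis", "inflamed_dermis", "muscle", "hair_follicle"]
    n_benign = int(rng.integers(n_benign_regions[0], n_benign_regions[1] + 1))
    # place regions on a 3x3 cell grid with jitter; cell size >> max diameter
    cells = [(i, j) for i in range(3) for j in range(3)]
    order = rng.permutation(len(cells))
    regions: list[RegionSpec] = []
    n_regions = n_benign + (1 if with_bcc else 0)
    for k in range(n_regions):
        ci, cj = cells[order[k]]
        cx = (cj + 0.5 + float(rng.uniform(-0.15, 0.15))) * width_mm / 3.0
        cy = (ci + 0.5 + float(rng.uniform(-0.15, 0.15))) * height_mm / 3.0
        if with_bcc and k == 0:
            cls = "bcc"
            diam = float(rng.uniform(*bcc_diameter_um))
        else:
            cls = candidates[int(rng.integers(len(candidates)))]
            diam = float(rng.uniform(400.0, 900.0))
        regions.append(RegionSpec(tissue_class=cls, centre_mm=(cx, cy), diameter_um=diam))
    return PhantomSpec(
        width_mm=width_mm, height_mm=height_mm, regions=regions, **spec_kwargs
    )
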