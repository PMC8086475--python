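"""Built-in Raman spectral template library for the tissue phantom.

Each tissue class is modelled as a sum of Gaussian bands on a fixed
fingerprint-region wavenumber grid (800-1800 cm^-1).  Band positions are
loosely inspired by common skin Raman assignments (collagen 855/938,
phenylalanine ~1002, CH2 deformation ~1450, amide I ~1660, lipid ester
carbonyl ~1745, haem bands ~1548/1621, carbon D/G bands for surgical ink),
but no claim of biochemical accuracy is made: the library exists to give
each class a distinct, reproducible spectral signature with realistic band
structure.

The library is versioned by :data:`LIBRARY_VERSION`; band tables are frozen
so that phantoms are bit-reproducible across runs.
"""

from __future__ import annotations

import numpy as np

LIBRARY_VERSION = "1.0"

#: Shared wavenumber axis (cm^-1), strictly increasing, 2 cm^-1 pitch.
WAVENUMBERS: np.ndarray = np.linspace(800.0, 1800.0, 501)

#: Closed enumeration of tissue classes a phantom pixel can carry.
TISSUE_CLASSES: tuple[str, ...] = (
    "dermis",
    "epidermis",
    "inflamed_dermis",
    "fat",
    "muscle",
    "hair_follicle",
    "bcc",
    "blood",
    "ink",
    "substrate",
    "out_of_contact",
)

#: Classes with a genuine Raman signature (everything but out-of-contact,
#: which by definition returns no signal from the cassette window plane).
TRAINABLE_CLASSES: tuple[str, ...] = tuple(
    c for c in TISSUE_CLASSES if c != "out_of_contact"
)

#: The five healthy skin structures plus the hair-follicle confounder.
HEALTHY_CLASSES: tuple[str, ...] = (
    "dermis",
    "epidermis",
    "inflamed_dermis",
    "fat",
    "muscle",
    "hair_follicle",
)

CONTAMINANT_CLASSES: tuple[str, ...] = ("ink", "substrate")

# Band tables: (centre cm^-1, sigma cm^-1, amplitude).  Bands are kept
# narrow (sigma <= 7) and sparse so that most of the grid is quiet; the
# broad contaminant bands are the exception.
_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "dermis": [  # collagen-dominated
        (855.0, 6.0, 0.75),
        (938.0, 6.0, 0.70),
        (1002.0, 4.0, 0.35),
        (1245.0, 7.0, 0.60),
        (1450.0, 7.0, 0.65),
        (1665.0, 7.0, 1.00),
    ],
    "epidermis": [  # keratin-dominated
        (1002.0, 4.0, 0.80),
        (1127.0, 6.0, 0.45),
        (1208.0, 6.0, 0.40),
        (1340.0, 7.0, 0.55),
        (1450.0, 7.0, 0.85),
        (1655.0, 7.0, 1.00),
    ],
    "inflamed_dermis": [  # collagen backbone + cell-rich additions
        (855.0, 6.0, 0.55),
        (938.0, 6.0, 0.50),
        (1002.0, 4.0, 0.60),
        (1340.0, 7.0, 0.50),
        (1450.0, 7.0, 0.70),
        (1576.0, 6.0, 0.45),
        (1665.0, 7.0, 1.00),
    ],
    "fat": [  # triacylglycerol bands
        (1065.0, 6.0, 0.45),
        (1301.0, 6.0, 0.85),
        (1440.0, 7.0, 1.00),
        (1655.0, 6.0, 0.50),
        (1745.0, 6.0, 0.60),
    ],
    "muscle": [  # actin/myosin-like protein profile
        (940.0, 6.0, 0.50),
        (1002.0, 4.0, 0.55),
        (1340.0, 7.0, 0.60),
        (1554.0, 6.0, 0.35),
        (1450.0, 7.0, 0.70),
        (1655.0, 7.0, 1.00),
    ],
    "hair_follicle": [  # keratin + nucleic-acid content
        (1002.0, 4.0, 0.65),
        (1093.0, 6.0, 0.40),
        (1245.0, 7.0, 0.45),
        (1336.0, 7.0, 0.60),
        (1450.0, 7.0, 0.75),
        (1615.0, 6.0, 0.35),
        (1655.0, 7.0, 1.00),
    ],
    "bcc": [  # elevated nucleic-acid bands relative to healthy skin
        (1002.0, 4.0, 0.50),
        (1093.0, 6.0, 0.80),
        (1340.0, 7.0, 0.70),
        (1486.0, 6.0, 0.75),
        (1575.0, 6.0, 0.65),
        (1450.0, 7.0, 0.55),
        (1660.0, 7.0, 1.00),
    ],
    "blood": [  # haem resonance bands
        (1004.0, 4.0, 0.35),
        (1127.0, 5.0, 0.55),
        (1248.0, 6.0, 0.45),
        (1342.0, 6.0, 0.70),
        (1397.0, 5.0, 0.50),
        (1548.0, 6.0, 0.90),
        (1621.0, 5.0, 1.00),
    ],
    "ink": [  # amorphous-carbon D and G bands (broad)
        (1350.0, 28.0, 0.90),
        (1590.0, 22.0, 1.00),
    ],
    "substrate": [  # fused-silica window, one broad weak feature
        (1060.0, 22.0, 1.00),
    ],
    "out_of_contact": [],  # no material in the sampling plane
}


def template(tissue_class: str, wavenumbers: np.ndarray | None = None) -> np.ndarray:
    """Noise-free template spectrum of one class, peak-normalised to 1.

    The out-of-contact class returns an all-zero spectrum.
    """
    if tissue_class not in _BANDS:
        raise KeyError(f"unknown tissue class: {tissue_class!r}")
    wn = WAVENUMBERS if wavenumbers is None else np.asarray(wavenumbers, float)
    y = np.zeros_like(wn)
    for centre, sigma, amp in _BANDS[tissue_class]:
        y += amp * np.exp(-0.5 * ((wn - centre) / sigma) ** 2)
    peak = y.max()
    if peak > 0:
        y = y / peak
    return y


def spectral_library(
    contrast: float = 1.0, wavenumbers: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Map every tissue class to its template spectrum.

    ``contrast`` is the between-class separability knob: each template is
    linearly mixed with the mean template of the signal-bearing classes,
    ``t' = mean + contrast * (t - mean)``.  At 1.0 (default) the library is
    returned unchanged; towards 0 all classes collapse onto the mean and
    become indistinguishable.  Values are clipped at zero to keep
    intensities physical.  The out-of-contact template stays zero.
    """
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    lib = {c: template(c, wavenumbers) for c in TISSUE_CLASSES}
    if contrast != 1.0:
        mean = np.mean([lib[c] for c in TRAINABLE_CLASSES], axis=0)
        for c in TRAINABLE_CLASSES:
            lib[c] = np.clip(mean + contrast * (lib[c] - mean), 0.0, None)
    return lib
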