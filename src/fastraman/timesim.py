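"""Acquisition-time-reduction simulation.

Shorter acquisition times are emulated by adding zero-mean Gaussian noise
to spectra recorded at a longer exposure: under the shot-noise-like
sigma ~ 1/sqrt(t) model, degrading a spectrum recorded at t0 to a target
exposure t1 < t0 requires extra noise of standard deviation
sigma_hat * sqrt(t0/t1 - 1), where sigma_hat is the recorded spectrum's
own noise level (robust first-difference estimate) — the variances then
add up to exactly those of a genuine t1-second acquisition.

The named configurations map total analysis time to per-round exposures:
30 min = 2 s everywhere, 26 min = 1 s in Round 1, 21 min = 1 s in Rounds
1-2, 20 min = 1 s everywhere.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .phantom import Spectrum
from .spectra import robust_noise_sd


@dataclass(frozen=True)
class TimeConfig:
    """Per-round exposure times in seconds."""

    exposure_r1: float = 2.0
    exposure_r2: float = 2.0
    exposure_r3: float = 2.0
    nominal_label: str = "30min"

    @property
    def exposures(self) -> tuple[float, float, float]:
        return (self.exposure_r1, self.exposure_r2, self.exposure_r3)


#: The four analysis-time configurations, keyed by nominal total time.
TIME_CONFIGS: dict[str, TimeConfig] = {
    "30min": TimeConfig(2.0, 2.0, 2.0, "30min"),
    "26min": TimeConfig(1.0, 2.0, 2.0, "26min"),
    "21min": TimeConfig(1.0, 1.0, 2.0, "21min"),
    "20min": TimeConfig(1.0, 1.0, 1.0, "20min"),
}


def degrade(spectrum: Spectrum, target_s: float, seed: int) -> Spectrum:
    """Simulate a shorter acquisition by adding Gaussian noise.

    A target equal to the recorded exposure is an exact no-op; a longer
    target is rejected (noise cannot be removed).
    """
    t0 = spectrum.exposure
    if target_s > t0:
        raise ValueError(
            f"cannot simulate a longer exposure ({target_s} s) than recorded ({t0} s)"
        )
    if target_s <= 0:
        raise ValueError("target exposure must be positive")
    if target_s == t0:
        return replace(spectrum, intensities=spectrum.intensities.copy())
    sigma_hat = robust_noise_sd(spectrum.intensities)
    extra = sigma_hat * np.sqrt(t0 / target_s - 1.0)
    rng = np.random.default_rng(seed)
    noisy = spectrum.intensities + rng.normal(0.0, extra, spectrum.intensities.size)
    return replace(spectrum, intensities=noisy, exposure=float(target_s))


def degrade_seed(base_seed: int, round_idx: int, x_um: float, y_um: float) -> int:
    """Deterministic per-point seed for the degradation noise (< 2^31)."""
    key = f"degrade:{base_seed}:{round_idx}:{x_um:.3f}:{y_um:.3f}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def rerun_with_config(record, cfg: TimeConfig, seed: int = 0):
    """Re-run the full diagnosis of a recorded layer at reduced exposures.

    Every spectrum is the 2 s recording degraded to its round's exposure;
    the entire decision pipeline (adipose screen, Round-2 scoring, Round-3
    selection and override) is re-executed, so segment selection may
    change with the added noise.  The identity (30 min) configuration
    reproduces the original report bit for bit.
    """
    from .runner import diagnose_record  # local import: runner builds on this module

    return diagnose_record(record, exposures=cfg.exposures, noise_seed=seed)


def concordance(reports_a, reports_b) -> float:
    """Fraction of paired layers whose verdicts agree."""
    if len(reports_a) != len(reports_b):
        raise ValueError("report lists differ in length")
    if len(reports_a) == 0:
        raise ValueError("cannot compute concordance of empty lists")

    def verdict(r) -> str:
        return r if isinstance(r, str) else r.verdict

    same = sum(verdict(a) == verdict(b) for a, b in zip(reports_a, reports_b))
    return same / len(reports_a)
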