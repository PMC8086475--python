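"""Per-segment decision rules, margin-coverage accounting and map rendering.

The decision constants are the algorithm's fixed operating points: a
segment is BCC-positive after Round 2 if strictly more than 45% of its
classified spectra are predicted BCC; a Round-3 raster segment (16
spectra) confirms only if strictly more than 75% (i.e. at least 13 of 16)
are predicted BCC; a segment is labelled blood if strictly more than 70%
of its spectra are predicted blood; it is labelled not-in-contact if every
spectrum's SNR is strictly below 7.  All inequalities are strict, matching
the rules' wording ("higher than", "more than", "below").

Round 3 exists to screen out false positives, with an override table: if
every Round-3 segment confirms, all Round-2 positives stand; if at least
one fails, the unconfirmed Round-2 positives are demoted to clear; if none
confirms, the whole layer is declared BCC-clear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult


@dataclass(frozen=True)
class DecisionConfig:
    round2_bcc_threshold: float = 0.45
    round3_bcc_threshold: float = 0.75
    blood_threshold: float = 0.70
    snr_threshold: float = 7.0
    round3_segment_count: int = 3
    round2_budget: int = 550

    def __post_init__(self) -> None:
        for name in ("round2_bcc_threshold", "round3_bcc_threshold", "blood_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")


@dataclass
class LayerReport:
    """Final verdict and margin-coverage accounting for one layer."""

    verdict: str  # "bcc_positive" | "bcc_clear"
    positive_segment_ids: list[int]
    blood_segment_ids: list[int]
    no_contact_segment_ids: list[int]
    adipose_segment_ids: list[int]
    pct_blood: float
    pct_no_contact: float
    pct_analysed: float
    segment_table: pd.DataFrame = field(default=None, repr=False)
    map_image: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "verdict": self.verdict,
            "positive_segment_ids": list(map(int, self.positive_segment_ids)),
            "blood_segment_ids": list(map(int, self.blood_segment_ids)),
            "no_contact_segment_ids": list(map(int, self.no_contact_segment_ids)),
            "adipose_segment_ids": list(map(int, self.adipose_segment_ids)),
            "pct_blood": float(self.pct_blood),
            "pct_no_contact": float(self.pct_no_contact),
            "pct_analysed": float(self.pct_analysed),
        }
        if self.segment_table is not None:
            d["segments"] = self.segment_table.to_dict(orient="records")
        return d


def label_adipose(
    segment_ids: list[int], round1_predictions: dict[int, str]
) -> tuple[list[int], list[int]]:
    """Split segments into (retained, adipose) from Round-1 predictions.

    A segment whose single Round-1 spectrum is classified as fat is
    flagged adipose and excluded from Rounds 2-3.
    """
    missing = [s for s in segment_ids if s not in round1_predictions]
    if missing:
        raise ValueError(f"segments missing a Round-1 classification: {missing}")
    adipose = [s for s in segment_ids if round1_predictions[s] == "fat"]
    retained = [s for s in segment_ids if round1_predictions[s] != "fat"]
    return retained, adipose


def score_round2(
    predictions: list[str], cfg: DecisionConfig = DecisionConfig()
) -> tuple[float, bool]:
    """BCC fraction of a segment's classified spectra and the 45% rule.

    Positive only if the fraction is strictly greater than the threshold
    (9/20 = 45.0% is negative, 10/20 is positive).
    """
    if not predictions:
        raise ValueError("segment has no classified spectra")
    frac = sum(p == "bcc" for p in predictions) / len(predictions)
    return frac, frac > cfg.round2_bcc_threshold


def select_round3(
    bcc_fractions: dict[int, float],
    areas_px: dict[int, int],
    cfg: DecisionConfig = DecisionConfig(),
) -> list[int]:
    """Up to three segments with the highest BCC probability score.

    The score is the Round-2 BCC fraction; segments with zero score are
    never selected.  Ties rank the larger segment first, then the lower
    segment id.
    """
    cand = [s for s, f in bcc_fractions.items() if f > 0.0]
    cand.sort(key=lambda s: (-bcc_fractions[s], -areas_px[s], s))
    return cand[: cfg.round3_segment_count]


def apply_round3_logic(
    round3_predictions: dict[int, list[str]],
    round2_positive_ids: list[int],
    cfg: DecisionConfig = DecisionConfig(),
    raster_size: int = 16,
) -> tuple[list[int], str]:
    """Confirmatory Round-3 override table.

    Each selected segment must carry exactly ``raster_size`` spectra; it
    confirms iff strictly more than 75% are predicted BCC (>= 13 of 16).
    Final positives are the confirming Round-3 segments, plus every other
    Round-2 positive only when ALL selected segments confirm.  The layer
    verdict is positive iff at least one Round-3 segment confirms.
    """
    if not round3_predictions:
        return [], "bcc_clear"
    passed, failed = [], []
    for seg_id, preds in round3_predictions.items():
        if len(preds) != raster_size:
            raise ValueError(
                f"segment {seg_id}: expected {raster_size} Round-3 spectra, "
                f"got {len(preds)}"
            )
        frac = sum(p == "bcc" for p in preds) / len(preds)
        (passed if frac > cfg.round3_bcc_threshold else failed).append(seg_id)
    if not passed:
        return [], "bcc_clear"
    final = set(passed)
    if not failed:  # every investigated segment confirmed
        final |= set(round2_positive_ids)
    final -= set(failed)
    return sorted(final), "bcc_positive"


def label_blood(
    predictions: list[str], cfg: DecisionConfig = DecisionConfig()
) -> bool:
    """Blood flag: strictly more than 70% of spectra predicted as blood."""
    if not predictions:
        raise ValueError("segment has no classified spectra")
    return sum(p == "blood" for p in predictions) / len(predictions) > cfg.blood_threshold


def label_contact(
    snrs: list[float], cfg: DecisionConfig = DecisionConfig()
) -> bool:
    """Not-in-contact flag: every spectrum's SNR strictly below threshold."""
    if not snrs:
        raise ValueError("segment has no spectra")
    return all(s < cfg.snr_threshold for s in snrs)


def area_metrics(
    segmentation: SegmentationResult,
    blood_ids: list[int],
    no_contact_ids: list[int],
) -> tuple[float, float, float]:
    """Percentages of tissue pixels covered by blood / poor-contact segments.

    The denominator is the total number of pixels that contain the tissue
    layer.  A segment flagged both blood and not-in-contact counts once,
    toward blood.  Returns (pct_blood, pct_no_contact, pct_analysed) with
    the three summing exactly to 100.
    """
    total = int(segmentation.tissue_mask.sum())
    if total == 0:
        raise ValueError("tissue mask is empty")
    blood_px = sum(
        seg.area_px for seg in segmentation.segments if seg.id in set(blood_ids)
    )
    nc_px = sum(
        seg.area_px
        for seg in segmentation.segments
        if seg.id in set(no_contact_ids) and seg.id not in set(blood_ids)
    )
    pct_blood = 100.0 * blood_px / total
    pct_nc = 100.0 * nc_px / total
    return pct_blood, pct_nc, 100.0 - pct_blood - pct_nc


# false-colour overlay: BCC red, blood yellow, poor contact blue
_OVERLAY = {
    "bcc": (255, 0, 0),
    "blood": (255, 255, 0),
    "no_contact": (0, 90, 255),
}


def render_map(
    segmentation: SegmentationResult,
    af_image: np.ndarray,
    positive_ids: list[int],
    blood_ids: list[int],
    no_contact_ids: list[int],
) -> np.ndarray:
    """False-colour greyscale map of the resection surface (uint8 RGB).

    The AF image is the greyscale background; BCC-positive segments are
    painted red, blood segments yellow and poor-contact segments blue.
    A segment carries one colour: BCC beats blood beats no-contact.
    """
    af = np.asarray(af_image, float)
    hi = af.max() if af.max() > 0 else 1.0
    grey = np.clip(255.0 * af / hi, 0, 255).astype(np.uint8)
    rgb = np.stack([grey, grey, grey], axis=-1)
    layers = (
        ("no_contact", no_contact_ids),
        ("blood", blood_ids),
        ("bcc", positive_ids),
    )
    for kind, ids in layers:
        colour = _OVERLAY[kind]
        for seg in segmentation.segments:
            if seg.id in set(ids):
                rgb[seg.rows, seg.cols] = colour
    return rgb
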