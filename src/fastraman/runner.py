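"""End-to-end orchestration: phantom -> segmentation -> staggered sampling
-> classification -> diagnosis -> report.

``run_layer`` executes the whole workflow for one layer and returns both
the :class:`~fastraman.diagnosis.LayerReport` and a
:class:`MeasurementRecord` that can be re-diagnosed at reduced exposures
(see :mod:`fastraman.timesim`).  ``run_cohort`` analyses several synthetic
patients with leave-one-patient-out classifier training, the way the
device generates its maps so that no layer is diagnosed by a model that
saw its own patient's spectra.

All randomness is derived from a single integer seed: spectra take
position-keyed sub-seeds, so a re-run at the same positions reproduces
the same measurements bit for bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scheduler
from .diagnosis import (
    DecisionConfig,
    LayerReport,
    apply_round3_logic,
    area_metrics,
    label_adipose,
    label_blood,
    label_contact,
    render_map,
    score_round2,
    select_round3,
)
from .library import TRAINABLE_CLASSES, WAVENUMBERS
from .phantom import (
    REFERENCE_EXPOSURE_S,
    PhantomSpec,
    Spectrum,
    TissueLayerPhantom,
    generate_layer,
    random_layer_spec,
    spectrum_at,
    training_set,
)
from .segmentation import SegmentationResult, segment_layer
from .spectra import RamanClassifier, snr, train_classifier
from .timesim import TimeConfig, degrade, degrade_seed


def point_seed(base_seed: int, round_idx: int, x_um: float, y_um: float) -> int:
    """Deterministic acquisition seed keyed by stage position (< 2^31)."""
    key = f"acquire:{base_seed}:{round_idx}:{x_um:.3f}:{y_um:.3f}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def derive_seed(base_seed: int, tag: str) -> int:
    return zlib.crc32(f"{tag}:{base_seed}".encode()) & 0x7FFFFFFF


@dataclass
class MeasurementRecord:
    """Everything needed to (re-)diagnose one measured layer.

    Spectra are recorded at the reference 2 s exposure with
    position-keyed seeds, so any re-run that revisits a position sees the
    identical recording; new positions (e.g. a Round-3 raster that moved
    because noisier spectra changed the segment ranking) are acquired on
    demand from the phantom.
    """

    phantom: TissueLayerPhantom
    segmentation: SegmentationResult
    model: RamanClassifier
    decision: DecisionConfig
    seed: int
    base_exposure: float = REFERENCE_EXPOSURE_S
    _cache: dict = field(default_factory=dict, repr=False)

    def acquire(self, round_idx: int, x_um: float, y_um: float) -> Spectrum:
        key = (round_idx, round(x_um, 3), round(y_um, 3))
        if key not in self._cache:
            self._cache[key] = spectrum_at(
                self.phantom,
                (x_um, y_um),
                self.base_exposure,
                point_seed(self.seed, round_idx, x_um, y_um),
            )
        return self._cache[key]


def _empty_report(segmentation: SegmentationResult, af_image: np.ndarray) -> LayerReport:
    pct_blood, pct_nc, pct_an = area_metrics(segmentation, [], [])
    return LayerReport(
        verdict="bcc_clear",
        positive_segment_ids=[],
        blood_segment_ids=[],
        no_contact_segment_ids=[],
        adipose_segment_ids=[],
        pct_blood=pct_blood,
        pct_no_contact=pct_nc,
        pct_analysed=pct_an,
        segment_table=pd.DataFrame(
            columns=["id", "area_px", "mean_af", "round1_class", "n_spectra",
                     "bcc_fraction", "adipose", "blood", "not_in_contact", "bcc_positive"]
        ),
        map_image=render_map(segmentation, af_image, [], [], []),
    )


def diagnose_record(
    record: MeasurementRecord,
    exposures: tuple[float, float, float] = (2.0, 2.0, 2.0),
    noise_seed: int = 0,
) -> LayerReport:
    """Run the three-round decision pipeline on a measurement record.

    ``exposures`` gives the per-round acquisition times; rounds requested
    at less than the recorded exposure use noise-degraded copies of the
    recordings (see :func:`fastraman.timesim.degrade`).
    """
    seg_res = record.segmentation
    phantom = record.phantom
    cfg = record.decision
    pitch = phantom.pixel_pitch_um
    segments = seg_res.segments
    if not segments:
        return _empty_report(seg_res, phantom.af_image)

    def measure(plan, round_idx, exposure):
        out = []
        for p in plan.points:
            s = record.acquire(round_idx, p.x_um, p.y_um)
            out.append(
                degrade(s, exposure, degrade_seed(noise_seed, round_idx, p.x_um, p.y_um))
            )
        return out

    model = record.model
    preds_by_seg: dict[int, list[str]] = {s.id: [] for s in segments}
    snrs_by_seg: dict[int, list[float]] = {s.id: [] for s in segments}
    bcc_points: dict[int, list[tuple[float, float]]] = {s.id: [] for s in segments}

    def classify(plan, specs):
        X = np.stack([s.intensities for s in specs])
        preds = model.predict(X)
        for p, s, cls in zip(plan.points, specs, preds):
            preds_by_seg[p.segment_id].append(str(cls))
            snrs_by_seg[p.segment_id].append(snr(s))
            if cls == "bcc":
                bcc_points[p.segment_id].append((p.x_um, p.y_um))
        return [str(c) for c in preds]

    # Round 1: one spectrum per segment, adipose screen
    r1_plan = scheduler.plan_round1(segments, pitch, exposure_s=exposures[0])
    r1_specs = measure(r1_plan, 1, exposures[0])
    r1_preds = classify(r1_plan, r1_specs)
    round1_class = {p.segment_id: c for p, c in zip(r1_plan.points, r1_preds)}
    retained_ids, adipose_ids = label_adipose(
        [s.id for s in segments], round1_class
    )
    retained = [s for s in segments if s.id in set(retained_ids)]

    # Round 2: density-consistent budgeted sampling over retained segments
    if retained:
        r2_plan = scheduler.plan_round2(
            retained, pitch, budget=cfg.round2_budget, exposure_s=exposures[1]
        )
        r2_specs = measure(r2_plan, 2, exposures[1])
        classify(r2_plan, r2_specs)

    # blood / poor-contact flags use every spectrum captured in a segment
    blood_ids = sorted(
        sid for sid, pr in preds_by_seg.items() if pr and label_blood(pr, cfg)
    )
    nc_ids = sorted(
        sid
        for sid, sn in snrs_by_seg.items()
        if sn and label_contact(sn, cfg) and sid not in set(blood_ids)
    )
    flagged = set(blood_ids) | set(nc_ids)

    # Round-2 scoring on retained, unflagged segments
    fracs: dict[int, float] = {}
    r2_positive: list[int] = []
    for sid in retained_ids:
        if sid in flagged or not preds_by_seg[sid]:
            continue
        frac, positive = score_round2(preds_by_seg[sid], cfg)
        fracs[sid] = frac
        if positive:
            r2_positive.append(sid)

    # Round 3: confirmatory rasters on the top-scoring segments
    areas = {s.id: s.area_px for s in segments}
    selected = select_round3(fracs, areas, cfg)
    final_positive: list[int] = []
    verdict = "bcc_clear"
    if selected:
        anchors = {
            sid: tuple(np.mean(bcc_points[sid], axis=0)) for sid in selected
        }
        sel_segments = [s for s in segments if s.id in set(selected)]
        r3_plan = scheduler.plan_round3(
            sel_segments, anchors, pitch, exposure_s=exposures[2]
        )
        r3_specs = measure(r3_plan, 3, exposures[2])
        X3 = np.stack([s.intensities for s in r3_specs])
        preds3 = [str(c) for c in model.predict(X3)]
        by_seg: dict[int, list[str]] = {sid: [] for sid in selected}
        for p, c in zip(r3_plan.points, preds3):
            by_seg[p.segment_id].append(c)
        final_positive, verdict = apply_round3_logic(by_seg, r2_positive, cfg)

    pct_blood, pct_nc, pct_an = area_metrics(seg_res, blood_ids, nc_ids)
    rows = []
    for s in segments:
        pr = preds_by_seg[s.id]
        rows.append(
            {
                "id": s.id,
                "area_px": s.area_px,
                "mean_af": s.mean_af,
                "round1_class": round1_class[s.id],
                "n_spectra": len(pr),
                "bcc_fraction": (sum(c == "bcc" for c in pr) / len(pr)) if pr else np.nan,
                "adipose": s.id in set(adipose_ids),
                "blood": s.id in set(blood_ids),
                "not_in_contact": s.id in set(nc_ids),
                "bcc_positive": s.id in set(final_positive),
            }
        )
    return LayerReport(
        verdict=verdict,
        positive_segment_ids=sorted(final_positive),
        blood_segment_ids=blood_ids,
        no_contact_segment_ids=nc_ids,
        adipose_segment_ids=sorted(adipose_ids),
        pct_blood=pct_blood,
        pct_no_contact=pct_nc,
        pct_analysed=pct_an,
        segment_table=pd.DataFrame(rows),
        map_image=render_map(seg_res, phantom.af_image, final_positive, blood_ids, nc_ids),
    )


def default_model(
    seed: int,
    n_per_class: int = 200,
    contrast: float = 1.0,
    raman_noise_sd: float = 0.02,
) -> RamanClassifier:
    """Train the default multiclass model from library-drawn spectra."""
    X, y = training_set(
        n_per_class,
        derive_seed(seed, "train"),
        classes=TRAINABLE_CLASSES,
        contrast=contrast,
        raman_noise_sd=raman_noise_sd,
    )
    return train_classifier(X, y, wavenumbers=WAVENUMBERS)


def run_layer(
    spec: PhantomSpec,
    seed: int,
    model: RamanClassifier | None = None,
    decision: DecisionConfig | None = None,
    time_config: TimeConfig | None = None,
    train_n_per_class: int = 200,
) -> tuple[LayerReport, MeasurementRecord]:
    """Analyse one phantom layer end to end.

    Returns the report and the re-usable measurement record.  Fully
    reproducible: the same (spec, seed) yields bit-identical results.
    """
    decision = decision or DecisionConfig()
    time_config = time_config or TimeConfig()
    phantom = generate_layer(spec, derive_seed(seed, "phantom"))
    seg_res = segment_layer(phantom.af_image)
    if model is None:
        model = default_model(
            seed,
            n_per_class=train_n_per_class,
            contrast=spec.contrast,
            raman_noise_sd=spec.raman_noise_sd,
        )
    record = MeasurementRecord(
        phantom=phantom,
        segmentation=seg_res,
        model=model,
        decision=decision,
        seed=derive_seed(seed, "measure"),
    )
    report = diagnose_record(record, exposures=time_config.exposures, noise_seed=seed)
    return report, record


def synthetic_cohort(
    n_patients: int,
    seed: int,
    bcc_prevalence: float = 0.5,
    **spec_kwargs,
) -> list[tuple[str, PhantomSpec, bool]]:
    """Draw (patient_id, layer spec, has_bcc) triples for a cohort run."""
    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    out = []
    for i in range(n_patients):
        with_bcc = bool(rng.random() < bcc_prevalence)
        spec = random_layer_spec(rng, with_bcc=with_bcc, **spec_kwargs)
        out.append((f"P{i+1:03d}", spec, with_bcc))
    return out


def run_cohort(
    layers: list[tuple[str, PhantomSpec]],
    seed: int,
    decision: DecisionConfig | None = None,
    time_config: TimeConfig | None = None,
    train_n_per_class: int = 60,
    amplitude_jitter: float = 0.05,
) -> pd.DataFrame:
    """Analyse a multi-patient cohort with leave-one-patient-out training.

    Each synthetic patient contributes its own training spectra (drawn
    with patient-specific gain jitter); the model diagnosing a patient's
    layer is trained only on the other patients' spectra.  Returns a
    per-layer summary table (verdict plus blood / poor-contact / analysed
    surface-area percentages).
    """
    patients = sorted({pid for pid, _ in layers})
    if len(patients) < 2:
        raise ValueError("cohort analysis needs at least 2 patients")
    per_patient: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pid in patients:
        p_spec = next(s for q, s in layers if q == pid)
        per_patient[pid] = training_set(
            train_n_per_class,
            derive_seed(seed, f"train:{pid}"),
            classes=TRAINABLE_CLASSES,
            contrast=p_spec.contrast,
            raman_noise_sd=p_spec.raman_noise_sd,
            amplitude_jitter=amplitude_jitter,
        )
    rows = []
    for i, (pid, spec) in enumerate(layers):
        others = [p for p in patients if p != pid]
        assert pid not in others  # no self-training, ever
        X = np.vstack([per_patient[p][0] for p in others])
        y = np.concatenate([per_patient[p][1] for p in others])
        model = train_classifier(X, y, wavenumbers=WAVENUMBERS)
        report, _ = run_layer(
            spec,
            derive_seed(seed, f"layer:{i}:{pid}"),
            model=model,
            decision=decision,
            time_config=time_config,
        )
        rows.append(
            {
                "layer": i,
                "patient_id": pid,
                "verdict": report.verdict,
                "n_positive_segments": len(report.positive_segment_ids),
                "pct_blood": report.pct_blood,
                "pct_no_contact": report.pct_no_contact,
                "pct_analysed": report.pct_analysed,
            }
        )
    return pd.DataFrame(rows)
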