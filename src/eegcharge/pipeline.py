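"""End-to-end orchestration: geometry → simulation → charge quantification.

Chains the forward model, synthetic sessions, preprocessing, the sLORETA
inverse and the charge statistics into cohort-level runs; this is what the
CLI commands and the acceptance checks call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charge import ChargeRecord, band_pipeline, default_bands
from .config import RunConfig
from .forward import (LeadField, Montage, ShellModel, SourceSpace,
                      build_source_space, build_spherical_montage,
                      compute_lead_field, default_parcel_spec)
from .preprocess import PreprocessConfig, preprocess_session
from .simulate import (PUNISHMENT, REWARD, ParcelActivation, RawSession,
                       SimulationConfig, make_trial_schedule,
                       simulate_session)
from .sloreta import build_inverse, select_alpha

__all__ = ["Geometry", "build_geometry", "simulate_subject",
           "analyze_session", "run_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Geometry:
    montage: Montage
    source_space: SourceSpace
    lead_field: LeadField
    shells: ShellModel


def build_geometry(cfg: RunConfig | None = None) -> Geometry:
    if cfg is None:
        cfg = RunConfig()
    montage = build_spherical_montage(cfg.n_channels, cfg.scalp_radius_m)
    src = build_source_space(default_parcel_spec(cfg.n_sources_per_parcel),
                             orientation_mode=cfg.orientation_mode,
                             inner_radius=cfg.shell_radii_m[0])
    shells = ShellModel(radii=tuple(cfg.shell_radii_m),
                        conductivities=tuple(cfg.shell_conductivities))
    lf = compute_lead_field(montage, src, shells)
    return Geometry(montage=montage, source_space=src, lead_field=lf,
                    shells=shells)


def simulate_subject(cfg: RunConfig, geom: Geometry, subject_seed: int,
                     keep_sources: bool = False) -> RawSession:
    """One synthetic IGT session under the run configuration."""
    sim = SimulationConfig(
        active_parcels={
            REWARD: (ParcelActivation(cfg.reward_parcel, cfg.effect_band,
                                      cfg.amplitude),),
            PUNISHMENT: (ParcelActivation(cfg.punishment_parcel,
                                          cfg.effect_band, cfg.amplitude),),
        },
        noise_sd=cfg.noise_sd_uv, seed=subject_seed)
    schedule = make_trial_schedule(cfg.n_trials, cfg.iti_s,
                                   seed=subject_seed)
    raw = simulate_session(sim, geom.lead_field, geom.source_space,
                           geom.montage, schedule, keep_sources=keep_sources)
    if cfg.blink_rate_per_min > 0:
        from .simulate import inject_ocular_artifacts
        raw = inject_ocular_artifacts(raw, cfg.blink_rate_per_min,
                                      cfg.blink_peak_uv,
                                      seed=subject_seed + 1)
    return raw


def analyze_session(raw: RawSession, geom: Geometry,
                    cfg: RunConfig | None = None, subject: str = "S001"
                    ) -> tuple[list[ChargeRecord], pd.DataFrame, dict]:
    """Preprocess one session and quantify per-band parcel charge.

    Channels flagged bad in surviving trials are dropped from the inverse
    for that evoked response (no interpolation); the lead field is re-
    referenced over the remaining channels.
    """
    if cfg is None:
        cfg = RunConfig()
    pre_cfg = PreprocessConfig(
        bad_channel_maxmin_uv=cfg.bad_channel_maxmin_uv,
        ocular_maxmin_uv=cfg.ocular_maxmin_uv,
        max_bad_channels=cfg.max_bad_channels)
    evoked, report = preprocess_session(raw, pre_cfg)
    bands = default_bands(raw.sampling_rate)
    lf = geom.lead_field
    inv_full = build_inverse(lf, select_alpha(lf, cfg.alpha_lambda),
                             calibration=cfg.calibration)
    records: list[ChargeRecord] = []
    tables = []
    for cond, ev in evoked.items():
        if ev.bad_channels:
            keep = [i for i, c in enumerate(ev.channel_ids)
                    if c not in ev.bad_channels]
            gain = lf.gain[keep]
            gain = gain - gain.mean(axis=0, keepdims=True)
            sub_lf = LeadField(gain=gain, average_referenced=True,
                               orientation_mode=lf.orientation_mode,
                               n_sources=lf.n_sources)
            inv = build_inverse(sub_lf, select_alpha(sub_lf,
                                                     cfg.alpha_lambda),
                                calibration=cfg.calibration)
            ev_use = _drop_channels(ev, keep)
        else:
            inv, ev_use = inv_full, ev
        recs, table = band_pipeline(ev_use, inv, geom.source_space, bands,
                                    subject=subject, bin_ms=cfg.bin_ms,
                                    aggregation=cfg.aggregation)
        records.extend(recs)
        tables.append(table)
    return records, pd.concat(tables, ignore_index=True), report


def _drop_channels(ev, keep):
    from dataclasses import replace
    return replace(ev, mean=ev.mean[keep],
                   channel_ids=tuple(ev.channel_ids[i] for i in keep),
                   bad_channels=frozenset())


def run_cohort(cfg: RunConfig, geom: Geometry | None = None,
               progress: bool = False
               ) -> tuple[list[ChargeRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze a whole cohort; skip failing sessions.

    Returns all charge records, the pooled tidy ι table, and the
    most-active-parcel frequency table.
    """
    from .charge import tabulate_frequencies

    if geom is None:
        geom = build_geometry(cfg)
    all_records: list[ChargeRecord] = []
    tables = []
    n_ok = 0
    for s in range(cfg.cohort_size):
        subject = f"S{s + 1:03d}"
        try:
            raw = simulate_subject(cfg, geom, subject_seed=cfg.seed + s)
            recs, table, _ = analyze_session(raw, geom, cfg, subject=subject)
        except Exception:
            logger.exception("session %s failed; skipping", subject)
            continue
        all_records.extend(recs)
        tables.append(table)
        n_ok += 1
        if progress:
            logger.info("analyzed %s (%d/%d)", subject, s + 1,
                        cfg.cohort_size)
    if not tables:
        raise RuntimeError("every session failed")
    freq = tabulate_frequencies(all_records, cohort_size=n_ok)
    return all_records, pd.concat(tables, ignore_index=True), freq
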