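"""Seeded generator of synthetic ED-visit cohorts.

The hospital data the pipeline was designed around is private, so every
stage is exercised on simulated cohorts that reproduce its statistical
structure: irregular vital-sign sampling every couple of hours,
per-channel missingness in the 0.72-0.81 range, stays from one hour to
five days (log-normal, median ~8 h), extreme class imbalance (CPR ~0.2%,
death-only ~0.7%), and a deterioration signal — drifting heart rate,
respiratory rate, blood pressure and oxygen saturation — that begins a
configurable number of hours before the event.

Deterioration is anchored to the event (CPR execution time, or the last
measurement for death-only visits, matching the pipeline's T=0
convention): a visit whose stay is shorter than the onset lead arrives
already partway into the drift.  Triage features carry one weak planted
association with outcome (ambulance arrival, odds ratio 3) so the
tabular branch has signal to find.

Missingness is injected per measurement instance per channel.  Because
an instance where every channel is dropped leaves no trace, the
per-channel drop probabilities are re-calibrated by a fixed point so the
*realized* missing rate over surviving instances matches the configured
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CHANNELS, Measurement, Outcome, RawVisit, TriageRecord, VitalChannel
from .preprocess import VALID_RANGES, clean_value

__all__ = ["SimConfig", "CohortSummary", "simulate_cohort", "summarize_cohort"]

# Default per-channel missing-rate targets (observed hospital rates).
DEFAULT_MISSING = {
    VitalChannel.SBP: 0.7180,
    VitalChannel.DBP: 0.7180,
    VitalChannel.HR: 0.7272,
    VitalChannel.BT: 0.7341,
    VitalChannel.RR: 0.7328,
    VitalChannel.SPO2: 0.8147,
}

# Baseline (between-patient mean, between-patient SD, within-visit noise SD)
DEFAULT_BASELINES = {
    VitalChannel.SBP: (125.0, 18.0, 7.0),
    VitalChannel.DBP: (75.0, 11.0, 5.0),
    VitalChannel.HR: (85.0, 13.0, 5.0),
    VitalChannel.SPO2: (97.0, 1.5, 1.0),
    VitalChannel.BT: (36.8, 0.4, 0.2),
    VitalChannel.RR: (18.0, 3.0, 1.5),
}

# Per-hour drift of deteriorating visits (raw units / hour towards the event).
DEFAULT_DRIFT = {
    VitalChannel.HR: 2.0,
    VitalChannel.RR: 0.8,
    VitalChannel.SBP: -2.0,
    VitalChannel.SPO2: -0.5,
}


@dataclass(frozen=True)
class SimConfig:
    n_visits: int = 2000
    prevalence_cpr: float = 0.002
    prevalence_death_only: float = 0.007
    # stay length: log-normal, median ~8 h, clipped to 1 h .. 5 d
    stay_median_h: float = 8.0
    stay_sigma: float = 0.9
    stay_min_h: float = 1.0
    stay_max_h: float = 120.0
    # post-triage measurement instances arrive every couple of hours
    interval_mean_h: float = 2.0
    interval_min_h: float = 0.25
    interval_max_h: float = 6.0
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING))
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    drift_per_h: dict = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    drift_onset_h: float = 12.0
    ambulance_base_p: float = 0.15
    ambulance_event_or: float = 3.0
    tabular_missing_p: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence_cpr < 1 or not 0 <= self.prevalence_death_only < 1:
            raise ValueError("prevalences must lie in (0, 1)")
        for ch, q in self.missing_rates.items():
            if not 0 <= q < 1:
                raise ValueError(f"missing rate for {ch} must be in [0, 1)")


def _calibrated_drop_probs(targets: dict) -> dict:
    """Per-channel drop probabilities whose conditional-on-nonempty missing
    rate equals the targets: fixed point of q_c = t_c (1 - Q) + Q, Q = prod q."""
    q = {c: float(targets.get(c, 0.0)) for c in CHANNELS}
    if all(v == 0.0 for v in q.values()):
        return q
    for _ in range(60):
        Q = float(np.prod([q[c] for c in CHANNELS]))
        q = {c: targets.get(c, 0.0) * (1.0 - Q) + Q for c in CHANNELS}
    return q


def _clamp(channel: VitalChannel, v: float) -> float:
    lo, hi, hi_closed = VALID_RANGES[channel]
    hi_eff = hi if hi_closed else hi - 0.1
    return float(np.clip(v, lo, hi_eff))


def _fmt(v: float) -> str:
    return f"{v:.1f}"


def _odds_shift(p: float, odds_ratio: float) -> float:
    odds = p / (1.0 - p) * odds_ratio
    return odds / (1.0 + odds)


def simulate_cohort(cfg: SimConfig = SimConfig()) -> list[RawVisit]:
    """Generate a cohort of :class:`RawVisit` (same seed, same bytes)."""
    if cfg.prevalence_cpr * cfg.n_visits < 1:
        import warnings
        warnings.warn("expected CPR count below one; cohort may contain no events")
    rng = np.random.default_rng(cfg.seed)
    drop = _calibrated_drop_probs(cfg.missing_rates)
    p_amb_event = _odds_shift(cfg.ambulance_base_p, cfg.ambulance_event_or)
    visits: list[RawVisit] = []
    for i in range(cfg.n_visits):
        vid = f"V{i:06d}"
        u = rng.random()
        is_cpr = u < cfg.prevalence_cpr
        is_death_only = (not is_cpr) and u < cfg.prevalence_cpr + cfg.prevalence_death_only
        is_event = is_cpr or is_death_only

        stay_h = float(np.clip(
            np.exp(np.log(cfg.stay_median_h) + cfg.stay_sigma * rng.standard_normal()),
            cfg.stay_min_h, cfg.stay_max_h))
        stay_s = int(round(stay_h * 3600))

        # post-triage instance times (seconds since triage at t=0)
        times: list[int] = []
        t = 0.0
        while True:
            t += float(np.clip(rng.exponential(cfg.interval_mean_h),
                               cfg.interval_min_h, cfg.interval_max_h))
            if t * 3600 >= stay_s:
                break
            times.append(int(round(t * 3600)))

        # anchor for the deterioration ramp
        if is_cpr:
            anchor_s = stay_s
        elif times:
            anchor_s = times[-1]
        else:
            anchor_s = 0

        baseline = {}
        for ch, (mu, sd_between, _) in cfg.baselines.items():
            baseline[ch] = _clamp(ch, mu + sd_between * rng.standard_normal())

        def value_at(ch: VitalChannel, t_s: int) -> float:
            v = baseline[ch]
            if is_event and ch in cfg.drift_per_h:
                hours_to_event = max(0.0, (anchor_s - t_s) / 3600.0)
                v += cfg.drift_per_h[ch] * max(0.0, cfg.drift_onset_h - hours_to_event)
            v += cfg.baselines[ch][2] * rng.standard_normal()
            return _clamp(ch, v)

        triage_vitals = {ch: _fmt(value_at(ch, 0)) for ch in CHANNELS}

        measurements: list[Measurement] = []
        for t_s in times:
            present = [ch for ch in CHANNELS if rng.random() >= drop[ch]]
            for ch in present:
                measurements.append(
                    Measurement(vid, t_s, ch, _fmt(value_at(ch, t_s))))

        p_amb = p_amb_event if is_event else cfg.ambulance_base_p
        age = int(np.clip(rng.normal(62 if is_event else 54, 19), 18, 100))
        gcs = 15
        if rng.random() < (0.35 if is_event else 0.08):
            gcs = int(rng.integers(7, 15))
        features: dict[str, object] = {
            "age": age,
            "sex": "M" if rng.random() < 0.52 else "F",
            "season": int(rng.integers(1, 5)),
            "revisit": int(rng.random() < 0.05),
            "is_job_related": int(rng.random() < 0.03),
            "department": rng.choice(["medicine", "surgery", "pediatrics"],
                                     p=[0.62, 0.28, 0.10]),
            "day_zone": int(rng.choice([1, 2, 3], p=[0.40, 0.37, 0.23])),
            "arrival_by_ambulance": int(rng.random() < p_amb),
            "major_disease": int(rng.random() < 0.10),
            "judgement_code": str(rng.choice(list("ABCDE"))),
            "triage": int(rng.choice([1, 2, 3, 4, 5],
                                     p=[0.25, 0.35, 0.30, 0.08, 0.02] if is_event
                                     else [0.03, 0.17, 0.45, 0.25, 0.10])),
            "pain_index": int(rng.integers(0, 11)),
            "gcs": gcs,
            "acute_change": int(rng.random() < (0.30 if is_event else 0.05)),
        }
        # sparse tabular missingness exercises mode imputation
        for feat in ("pain_index", "judgement_code"):
            if rng.random() < cfg.tabular_missing_p:
                features[feat] = np.nan

        outcome = Outcome(
            cpr=is_cpr,
            dead=is_death_only or (is_cpr and rng.random() < 0.5),
            cpr_time_s=stay_s if is_cpr else None,
        )
        visits.append(RawVisit(vid, TriageRecord(features, triage_vitals, 0),
                               measurements, outcome))
    return visits


@dataclass
class CohortSummary:
    n_visits: int
    prevalence_cpr: float
    prevalence_ca: float
    missing_rates: dict
    stay_quantiles_h: dict
    event_final6h_mean: dict
    control_final6h_mean: dict


def summarize_cohort(visits: list[RawVisit]) -> CohortSummary:
    """Deterministic summary statistics of a cohort.

    Missing rates are computed over post-triage measurement instances
    (the long-format table): an instance missing channel c counts against
    c.  Final-6-hour class means are event-anchored, so a configured
    positive drift shows up as an event-minus-control gap.
    """
    if not visits:
        raise ValueError("empty cohort")
    n = len(visits)
    n_cpr = sum(v.outcome.cpr for v in visits)
    n_ca = sum(v.outcome.ca for v in visits)

    n_instances = 0
    channel_counts = {c: 0 for c in CHANNELS}
    stays = []
    final6 = {True: {c: [] for c in CHANNELS}, False: {c: [] for c in CHANNELS}}
    for v in visits:
        by_time: dict[int, set] = {}
        for m in v.measurements:
            by_time.setdefault(m.time_s, set()).add(m.channel)
        n_instances += len(by_time)
        for chans in by_time.values():
            for c in chans:
                channel_counts[c] += 1
        last = max(by_time) if by_time else v.triage.triage_time_s
        stays.append((last - v.triage.triage_time_s) / 3600.0)
        if v.outcome.cpr and v.outcome.cpr_time_s is not None:
            anchor = v.outcome.cpr_time_s
        else:
            anchor = last
        for m in v.measurements:
            val = clean_value(m.channel, m.raw_value)
            if val is None:
                continue
            if 0 <= (anchor - m.time_s) / 3600.0 < 6.0:
                final6[v.outcome.ca][m.channel].append(val)
        for c in CHANNELS:
            val = clean_value(c, v.triage.vitals.get(c, ""))
            if val is not None and 0 <= (anchor - v.triage.triage_time_s) / 3600.0 < 6.0:
                final6[v.outcome.ca][c].append(val)

    missing_rates = {
        c: (1.0 - channel_counts[c] / n_instances) if n_instances else float("nan")
        for c in CHANNELS
    }
    qs = np.quantile(np.asarray(stays), [0.1, 0.25, 0.5, 0.75, 0.9]) if stays else []
    stay_quantiles = dict(zip(["q10", "q25", "q50", "q75", "q90"], map(float, qs)))

    def class_means(flag: bool) -> dict:
        return {c: (float(np.mean(vals)) if vals else float("nan"))
                for c, vals in final6[flag].items()}

    return CohortSummary(
        n_visits=n,
        prevalence_cpr=n_cpr / n,
        prevalence_ca=n_ca / n,
        missing_rates=missing_rates,
        stay_quantiles_h=stay_quantiles,
        event_final6h_mean=class_means(True),
        control_final6h_mean=class_means(False),
    )
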