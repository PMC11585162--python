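"""Generate a synthetic ED cohort and inspect its statistical structure.

Prints realized event prevalences, per-channel missing rates and stay
lengths, and writes the cohort to the triage.csv/vitals.csv dialect the
readers consume.
"""

from pathlib import Path

from edewarn.io import VitalChannel, write_visits
from edewarn.simulate import SimConfig, simulate_cohort, summarize_cohort

cfg = SimConfig(n_visits=3000, seed=11)
cohort = simulate_cohort(cfg)
s = summarize_cohort(cohort)

print(f"visits: {s.n_visits}")
print(f"prevalence  CPR={s.prevalence_cpr:.4f}  CA={s.prevalence_ca:.4f} "
      "(CA = CPR or death)")
print("per-channel missing rate over measurement instances:")
for ch, rate in s.missing_rates.items():
    print(f"  {ch.value:>4}: {rate:.3f}   (target {cfg.missing_rates[ch]:.3f})")
print("observed stay quantiles (hours):",
      {k: round(v, 1) for k, v in s.stay_quantiles_h.items()})
hr_gap = (s.event_final6h_mean[VitalChannel.HR]
          - s.control_final6h_mean[VitalChannel.HR])
print(f"final-6h HR gap, event minus control: {hr_gap:+.1f} bpm "
      "(the planted deterioration signal)")

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)
write_visits(cohort, out / "triage.csv", out / "vitals.csv")
print(f"wrote {out}/triage.csv and {out}/vitals.csv")
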