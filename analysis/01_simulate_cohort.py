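#!/usr/bin/env python
"""Simulate the study cohort.

Feature tier: 1985 participants (1386 NI / 401 INH / 133 HNI / 65 HI)
with questionnaire responses, covariates and per-state band log-powers
at the group targets.  Raw tier: one participant per group gets a
2-h two-channel 125 Hz EEG plus hypnogram for the spectral-chain
validation in the next step.

Writes scratch/cohort/participants.csv (feature tier; regenerated on
demand, so it lives with the other bulky intermediates) and
scratch/raw_tier/*.edf|*.csv (raw signals).
"""

from pathlib import Path

from sleepqeeg.edf_io import write_edf, write_hypnogram
from sleepqeeg.synthetic import add_raw_recordings, generate_feature_cohort

SEED = 20260921
RAW_EPOCHS = 240          # 2 h per raw-tier night

out = Path("scratch/cohort")
raw_dir = Path("scratch/raw_tier")
out.mkdir(parents=True, exist_ok=True)
raw_dir.mkdir(parents=True, exist_ok=True)

cohort = generate_feature_cohort(seed=SEED)
df = cohort.participants
df.to_csv(out / "participants.csv", index=False, float_format="%.6g")

print(f"feature tier: {len(df)} participants "
      f"{df['group'].value_counts().reindex(['NI', 'INH', 'HNI', 'HI']).to_dict()}")
for g in ("NI", "HI"):
    m = df[df["group"] == g]["total_sigma"]
    print(f"  {g} total-sleep sigma log-power: {m.mean():.3f} ± {m.std(ddof=1):.3f} "
          f"(n={len(m)})")

add_raw_recordings(cohort, n_epochs=RAW_EPOCHS, seed=SEED + 1)
for pid, (rec, hyp) in cohort.recordings.items():
    write_edf(rec, raw_dir / f"{pid}.edf")
    write_hypnogram(hyp, raw_dir / f"{pid}.csv")
print(f"raw tier: {len(cohort.recordings)} recordings of "
      f"{RAW_EPOCHS * 30 / 3600:.1f} h each -> {raw_dir}/")
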