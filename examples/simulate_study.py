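"""Generate a synthetic activity study and inspect its exclusion ledger.

Builds a 6-participant, 3-session cohort with the default per-stage trial
loss rates, writes it to CSV, and prints how many trials survive each
filtering stage.
"""

import tempfile
from pathlib import Path

import relpa

config = relpa.SimulationConfig(n_participants=6, n_sessions=3, rng_seed=42)
study = relpa.simulate_study(config)

out = Path(tempfile.mkdtemp()) / "study"
relpa.write_study(study, out)
print(f"study written to {out} (participants.csv, signals.csv, labels.csv)")

kept, ledger = relpa.filter_trials(study.records)
for stage, count in ledger.to_dict().items():
    print(f"  {stage:>25}: {count}")

# The ledger mirrors a field protocol: of the scheduled trials, some are
# abandoned mid-trial, some lose a sensor stream, and some carry invalid
# (sub-10) Borg ratings; only 'analyzable' trials feed the classifier.
p = study.participants[0]
print(f"\nfirst participant: age {p.age}, resting HR {p.hr_rest:.0f} bpm, "
      f"predicted HRmax {relpa.hr_max(p.age):.0f} bpm")
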