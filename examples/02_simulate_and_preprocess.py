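"""Simulate one participant's EEG session and preprocess it.

Simulates a 20-trial session (64-channel, 512 Hz) with condition-dependent
mu/beta desynchronization, blink and spike artifacts, then runs the fixed
preprocessing chain (1 Hz high-pass, mastoid re-reference, blink
regression, epoching, artifact rejection) and prints how many epochs
survive and why trials were dropped.  With the default artifact rates a
handful of epochs carry >100 µV spikes and are rejected.
"""

from collections import Counter

from erdvoice import make_cohort, make_schedule, simulate_eeg
from erdvoice.preprocess import preprocess_pipeline

profile = make_cohort(6, rng_seed=1)[0]
schedule = make_schedule(20, rng_seed=2)
raw = simulate_eeg(profile, schedule, rng_seed=3)
print(f"simulated {raw.data.shape[0]} channels x {raw.duration_s:.0f} s, "
      f"{len(raw.events)} events")

perception, production = preprocess_pipeline(raw)
for name, ep in (("perception", perception), ("production", production)):
    reasons = Counter(r for r in ep.reasons if r != "none")
    print(f"{name}: kept {int(ep.kept.sum())}/{ep.n_trials} epochs"
          + (f", rejected: {dict(reasons)}" if reasons else ""))
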