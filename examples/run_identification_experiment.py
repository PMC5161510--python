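"""Simulate a yes/no identification session and analyze it with
signal-detection statistics.

One participant sees 672 trials (12 per morphological profile for each of
14 types of sound: 10 imitators, sketches Q1-Q3, and the referents, always
last).  A simulated equal-variance Gaussian observer answers each trial;
the analysis tallies hits and false alarms per 12-trial cell and computes
d' (with the log-linear correction), ln(beta) (positive = liberal), and
the unbiased percent correct.
"""

from vocsketch.psychophysics import ExperimentDesign, analyze_responses, build_trial_table
from vocsketch.synthetic_data import ObserverSpec, simulate_observer

trials = build_trial_table(ExperimentDesign(), seed=1)
print(f"trial table: {len(trials)} trials, blocks {sorted(trials.block.unique())}")

observer = ObserverSpec(dprime=1.5, criterion=-0.2, seed=42)  # slightly liberal
responses = simulate_observer(trials, observer)
results = analyze_responses(trials, responses)

print(f"\nper-cell results ({len(results)} cells of 12 trials):")
print(results[["type_of_sound", "profile", "n_hit", "n_fa", "dprime", "ln_beta", "upc"]].head(8).to_string(index=False))

by_profile = results.groupby("profile")[["dprime", "ln_beta", "upc"]].mean()
print("\nmeans by morphological profile (true d' = 1.5, liberal criterion):")
print(by_profile.round(3).to_string())
print(
    "\nRecovered d' sits close to (slightly below) the simulated 1.5 — the "
    "log-linear correction shrinks extreme counts — and ln(beta) > 0 "
    "reflects the liberal criterion."
)
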