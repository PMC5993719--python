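"""Mitotic phase durations from time-lapse event tables.

Simulates a control-like cohort (prometaphase 14.4 +/- 7.6 min) and a
confined-like cohort (23.1 +/- 14.1 min), computes per-cell durations with
censoring, cohort statistics, the long-prometaphase fraction, and compares
the two cohorts with a Mann-Whitney test.
"""

from spheroidgeom import long_prometaphase_fraction, mann_whitney
from spheroidgeom.phantom import generate_mitosis_events
from spheroidgeom.timing import cohort_summary, phase_durations

cohorts = {
    "control": generate_mitosis_events(
        n=104, prometaphase_mu_min=14.4, prometaphase_sigma_min=7.6, seed=6
    ),
    "confined": generate_mitosis_events(
        n=78, prometaphase_mu_min=23.1, prometaphase_sigma_min=14.1, seed=7
    ),
}

samples = {}
for name, events in cohorts.items():
    s = cohort_summary(events)["prometaphase"]
    frac = long_prometaphase_fraction(events, cutoff_min=40.0)
    print(f"{name}: prometaphase {s.mean_min:.1f} ± {s.sd_min:.1f} min "
          f"(n={s.n} fully monitored); "
          f">40 min in {100 * frac.fraction:.0f}% of determinate cells")
    samples[name] = [
        d.prometaphase_min for d in map(phase_durations, events)
        if d.prometaphase_observed
    ]

res = mann_whitney(samples["control"], samples["confined"])
print(f"Mann-Whitney control vs confined: U={res.U:.0f}, "
      f"p={res.p_value:.2g} ({res.method})")
# Censored cells (condensation before the movie, or no plate seen) enter
# the >40 min fraction only when their lower bound settles the question.
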