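"""Study-level constants used across the pipeline.

Every tunable that the analysis fixes a priori lives here so that run
manifests can record them and tests can reference a single source.
"""

#: Tumbling aggregation window for infrared detections, in seconds.
WINDOW_S = 75.0

#: Minimum number of detections within a window to count as an interaction.
MIN_DETECTIONS = 2

#: Survey ratings strictly above this value constitute a tie.
RATING_THRESHOLD = 3

#: Age bands (years): young <= 30 < middle <= 45 < elderly.
AGE_BAND_EDGES = (30.0, 45.0)

#: Tenure bands (months): newcomer <= 12 < consolidated <= 72 < long_term.
TENURE_BAND_EDGES = (12.0, 72.0)

#: Number of multiple imputations for production runs.
N_IMPUTATIONS = 100

#: HMC chains and retained draws per chain per imputed dataset.
CHAINS = 2
DRAWS = 500

#: Weakly informative prior scales.
PRIOR_SCALE_FIXED = 2.0      # Normal(0, 2^2) on fixed effects and hypermeans
PRIOR_SCALE_SIGMA = 1.0      # Half-Normal(0, 1) on random-effect SDs

#: Organisational contexts.
CONTEXTS = ("uni", "lab", "bus")

#: Seconds per day; presence schedules and window anchoring use civil days.
DAY_S = 86400.0
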