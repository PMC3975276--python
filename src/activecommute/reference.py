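"""Published reference values used as worked-example inputs.

Weekday group summaries reported by the observational study of UK commuters
that motivates this pipeline's design: mean ± sd total activity volume (cpm)
and MVPA minutes per weekday for usual walkers and usual car commuters, and
the mean daily journey vs total MVPA minutes for walkers providing GPS data.
They serve as fixed inputs to the percent-difference and contribution
arithmetic (e.g. in the worked example and the acceptance script); nothing in
the pipeline is fitted to them.
"""

WEEKDAY_CPM_WALK = 524.6
WEEKDAY_CPM_CAR = 364.6
WEEKDAY_MVPA_WALK = 78.1
WEEKDAY_MVPA_CAR = 49.8

JOURNEY_MVPA_MIN = 38.0
TOTAL_MVPA_MIN = 80.3
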