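# Simulation scenario for `hetfdr simulate` / `hetfdr benchmark`.
# Any SimConfig field may be overridden; omitted fields keep the
# calibrated defaults (see docs/methods.md).
m: 1000            # phenotypes per replicate
n_active: 50       # phenotypes with non-zero pooled effect
n_het: 10          # subset of active with a between-group difference
n_major: 8000      # majority-stratum sample size
ratio: 0.25        # minority / majority sample-size ratio
mu: 0.08           # common-effect magnitude
delta: 0.075       # heterogeneous-effect magnitude
sigma: 1.0         # residual scale: se_g = sigma / sqrt(n_g)
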