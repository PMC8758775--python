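"""Quantify barrier tightness from tracer filling kinetics.

Builds noisy sigmoidal filling curves for the three chip channels (the
endothelial MVEC channel fills first, the stromal channel later, the RPE
channel last), fits the half-filling time t50 of each, and reports pairwise
lag times: a positive lag means the target channel fills later, i.e. the
barrier in between is tighter.
"""

from choroidchip import PermeabilityRunConfig, TraceSpec, run_permeability

config = PermeabilityRunConfig(
    synthetic_traces={
        "MVEC": TraceSpec(t50_s=300.0, slope=4.0, noise_sd=0.03, rng_seed=1),
        "stromal": TraceSpec(t50_s=600.0, slope=4.0, noise_sd=0.03, rng_seed=2),
        "RPE": TraceSpec(t50_s=900.0, slope=4.0, noise_sd=0.03, rng_seed=3),
    },
    molecule_label="0.377 kDa tracer",
)
fits, lags = run_permeability(config)

for channel, fit in fits.items():
    print(f"{channel:8s} t50 = {fit.t50_s:7.1f} s  (slope {fit.slope:.2f}, "
          f"rms residual {fit.fit_quality:.4f})")
print()
print(lags[["source", "target", "lag_s"]].to_string(index=False))
# The MVEC->RPE lag spans two barriers (endothelium + RPE) and exceeds the
# MVEC->stromal lag (endothelium only): the outer blood-retina barrier is
# the tighter one.
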