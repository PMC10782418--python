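"""Denoising vortices in action: contaminated mixture, incomplete match.

A 40:60 two-component mixture is spiked with 15% contaminant signal at a
position far from every library resonance.  The estimator routes exactly
that mass to the mixture vortex (p0) at cost kappa_mixture per unit,
leaving the component proportions unbiased — no peak picking, no manual
exclusion regions.
"""

from otnmr import (
    Distortion,
    GridSpec,
    MixtureScenario,
    PeakSpec,
    deconvolve,
    estimation_errors,
    make_mixture,
)

scenario = MixtureScenario(
    component_peaklists=(
        (PeakSpec(2.0, 0.06, 2, shape="gaussian"), PeakSpec(3.1, 0.06, 1, shape="gaussian")),
        (PeakSpec(5.9, 0.06, 2, shape="gaussian"), PeakSpec(7.0, 0.06, 1, shape="gaussian")),
    ),
    proportions=(0.4, 0.6),
    grid=GridSpec(0.0, 10.0, 800),
    distortions=(
        Distortion(
            "contaminant",
            peaks=(PeakSpec(9.5, 0.03, shape="gaussian"),),
            fraction=0.15,
        ),
    ),
)
mixture, library, truth, f = make_mixture(scenario)
result = deconvolve(mixture, library)
errors = estimation_errors(result.proportions, truth)

print(f"contaminant fraction injected : {f:.3f}")
print(f"p0 recovered by the estimator : {result.p0:.4f}")
print(f"reported proportions          : {tuple(round(float(p), 4) for p in result.proportions)}")
print(f"true proportions              : {truth.tolist()}")
print(f"AvRE                          : {errors.avre:.2f}%")
print()
print("p0 matches the injected contaminant fraction: signal farther than")
print("kappa_mixture (0.25 ppm) from all library resonances is cheaper to")
print("remove than to match, so it is labeled noise instead of biasing p.")
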