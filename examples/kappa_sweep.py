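"""Map estimation error over the two denoising penalties.

Reproduces the penalty-tuning workflow: deconvolve a contaminated
mixture for every (kappa_mixture, kappa_components) cell of a small
grid and tabulate the L1 estimation error (sum of absolute proportion
differences) together with the noise fractions.  Low kappa_mixture
removes contamination aggressively; very low values start discarding
genuine low-concentration signal.
"""

from otnmr import (
    Distortion,
    GridSpec,
    MixtureScenario,
    PeakSpec,
    make_mixture,
    parameter_sweep,
)

scenario = MixtureScenario(
    component_peaklists=(
        (PeakSpec(2.0, 0.05, 2, shape="gaussian"), PeakSpec(3.1, 0.05, 1, shape="gaussian")),
        (PeakSpec(5.9, 0.05, 2, shape="gaussian"), PeakSpec(7.0, 0.05, 1, shape="gaussian")),
    ),
    proportions=(0.2, 0.8),
    grid=GridSpec(0.0, 10.0, 600),
    distortions=(
        Distortion(
            "contaminant",
            peaks=(PeakSpec(8.9, 0.03, shape="gaussian"),),
            fraction=0.10,
        ),
    ),
)
mixture, library, truth, _ = make_mixture(scenario)

frame = parameter_sweep(
    mixture,
    library,
    kappa_mixture_grid=[0.05, 0.25, 1.0],
    kappa_components_grid=[0.05, 0.22, 1.0],
    p_true=truth,
)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("Each row is one deconvolution run. l1_error stays near zero wherever")
print("kappa_mixture is small enough to discard the 10% contaminant (p0 ~ 0.1).")
print("Note the degenerate corner at high kappa_mixture with very low")
print("kappa_components: discarding the entire library side (p0' = 1) becomes")
print("cheaper than matching, and the estimate collapses — both penalties must")
print("stay above the typical per-unit matching cost.")
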