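"""Quantify a simple two-component mixture from spectrum files.

Simulates two Lorentzian component spectra and their 35:65 mixture,
writes them to disk as two-column CSV (the format a spectrometer export
or a text conversion would produce), then runs the full file-based
workflow: read, preprocess (normalize), deconvolve, report.
"""

import tempfile
from pathlib import Path

from otnmr import (
    ComponentLibrary,
    GridSpec,
    MixtureScenario,
    PeakSpec,
    deconvolve,
    make_mixture,
    preprocess,
    read_spectrum,
    write_spectrum,
)

scenario = MixtureScenario(
    component_peaklists=(
        (PeakSpec(2.0, 0.05), PeakSpec(2.8, 0.05)),   # aliphatic doublet analogue
        (PeakSpec(6.0, 0.05), PeakSpec(7.1, 0.05)),   # aromatic analogue
    ),
    proportions=(0.35, 0.65),
    grid=GridSpec(0.0, 10.0, 800),
)
mixture, library, truth, _ = make_mixture(scenario)

workdir = Path(tempfile.mkdtemp(prefix="otnmr_demo_"))
write_spectrum(workdir / "mixture.csv", mixture)
for name, comp in zip(library.names, library):
    write_spectrum(workdir / f"{name}.csv", comp)

# file-based round trip, exactly what the CLI does internally
mix = preprocess(read_spectrum(workdir / "mixture.csv"))
lib = ComponentLibrary(
    tuple(
        preprocess(read_spectrum(workdir / f"{name}.csv")).with_label(name)
        for name in library.names
    ),
    library.names,
)
result = deconvolve(mix, lib)

print(f"spectra written to {workdir}")
print(f"true proportions      : {tuple(round(float(t), 4) for t in truth)}")
print(f"estimated proportions : {tuple(round(float(p), 4) for p in result.proportions)}")
print(f"p0  (mixture noise)   : {result.p0:.4f}")
print(f"p0' (library noise)   : {result.p0_prime:.4f}")
print(f"objective (ppm cost)  : {result.objective:.6f}")
print()
print("The estimated proportions are the fractions of total mixture signal")
print("assigned to each component; with a clean, complete library both noise")
print("fractions are ~0 and the transport cost is essentially zero.")
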