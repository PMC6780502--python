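# fsmi — fluorescence sandwich microarray immunoassay analysis

`fsmi` is an analysis pipeline for antibody microarrays read out as
fluorescence sandwich immunoassays (FSMI): panels of polyclonal capture
antibodies printed in triplicate on a slide, incubated with an environmental
sample, revealed with fluorescently labelled tracer antibodies and scanned at
635 nm.  Such chips are used to profile microbial biomarkers in extreme
environments — hypersaline mines, acidic lakes, sulfidic springs, glaciers —
where the pattern of positive antigen–antibody signals acts as a fingerprint
of the microbial community.

The package is aimed at people who build or use these chips and need a
tested, reproducible route from raw spot-intensity tables to biological
conclusions: spot-level quality control, positive calls against the
control-spot null, immunograms, cluster/phylum abundance profiles,
cross-reactivity maps and detection-limit calibration.  A built-in forward
simulator generates assays with known ground truth, so every stage can be
validated without laboratory data.

## The model

Each antibody *i* is quantified from its replicate spots as

```
F_i = F_sample,i − F_blank,i − m · F_avcontrol
```

where `F_sample,i` and `F_blank,i` are the mean background-subtracted
replicate intensities of antibody *i* in the sample assay and in a parallel
buffer-only blank, `F_avcontrol` is the mean intensity of the assay's control
spots (BSA, buffer, pre-immune antiserum), and the stringency multiplier *m*
defaults to 2.5.  Antibody *i* is called **positive** iff `F_i > 0`.
Replicate sets whose sample standard deviation exceeds 0.2× their mean are
excluded from quantification, as are flagged/defective spots.

The simulator models the sandwich signal with a saturating binding law:
loading `θ_i = Σ_j a_ij c_j` (affinities `a_ij ∈ [0,1]`, antigen
concentrations `c_j` in cells/mL) gives noise-free signal
`S_i = s_max · t(d) · θ_i/(k_half + θ_i)`, with `t(d)` a unimodal tracer-
dilution response peaking near 1/850.  Observed intensities add truncated-
Gaussian background and lognormal multiplicative noise.

## Worked example

Simulate a sample containing two antigens against the packaged 26-antibody
panel, quantify it against its parallel blank, and profile the calls:

```python
import statistics
from fsmi import *
from fsmi.profile import build_immunogram, build_group_profile
from fsmi.calibrate import lod_survey, half_log_concentrations

chip = masechip()                       # 26 antibodies, 24 assay fields/slide
aff = AffinityMatrix.identity(chip.antibody_ids)
comp = SampleComposition({"IVJ8C1": 1.0e6, "MASE-BB-1": 5.0e4})
sample, blank, truth = simulate_assay_pair(chip, aff, comp, seed=7)

quant = quantify_assay(sample, blank, chip)
print(f"control baseline F_avcontrol = {quant.f_avcontrol:.1f}")
for peak, ab, f in build_immunogram(quant, chip).peaks:
    print(f"peak {peak:2d}  {ab:12s}  F = {f:.1f}")
for g, v in build_group_profile(quant, chip, "cluster").rel_abundance.items():
    if v:
        print(f"{g}: {v:.1f}%")

lods = lod_survey(chip, half_log_concentrations(1e2, 1e6), seed=7)
vals = [v for v in lods.values() if v is not None]
print("median LOD =", statistics.median(vals), "cells/mL")
```

prints

```
control baseline F_avcontrol = 157.9
peak  6  MASE-BB-1     F = 19439.9
peak 23  IVJ8C1        F = 60047.0
anaerobic isolates: 33.3%
halophilic cultures: 66.7%
median LOD = 1000.0 cells/mL
```

Exactly the two spiked antigens are called positive; their immunogram peaks
carry the chip-order peak numbers (6 and 23).  The halophile signal is near
saturation (`s_max = 60000`), the weaker isolate signal sits a third of the
way up the binding curve.  The weighted cluster profile splits 2:1 toward the
halophilic cultures because that cluster holds fewer antibodies on the chip
(5 vs 10), so one hit in it weighs more.  The titration survey places the
median detection limit at 10³ cells/mL, inside the expected 10³–10⁴ decade.

The same stages are scriptable from a shell:

```
fsmi simulate assay --chip masechip --seed 7 --antigen IVJ8C1=1e6 --out sim/
fsmi quantify --sample sim/sample.tsv --blank sim/blank.tsv --out quant.tsv
fsmi profile --quant quant.tsv --group cluster --mode rel --out profile.tsv
fsmi simulate checkerboard --seed 7 --out cb/
fsmi crossreact --assays cb/ --out matrix.tsv --graph recognition.graphml
fsmi calibrate lod --chip masechip --seed 7 --out lods.tsv
```

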