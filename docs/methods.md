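# Methods

## Scope and data model

The pipeline starts at spot-level result tables (a simplified GenePix-style
dialect: `Block, Row, Column, ID, Name, F635 Median, B635 Median, Flags`,
tab-delimited, plus `# key=value` metadata lines) and a chip definition
(antibody identities, immunogen sources, cluster/phylum annotation, control
inventory, slide grid).  Image segmentation, scanner control and upstream
sequencing pipelines are out of scope; an external phylum-abundance table is
consumed only as a plain TSV.

Two panels are packaged.  The 26-antibody anaerobe/halophile panel is a
transcription of its published composition table; its cluster and phylum
columns are package annotation derived from standard genus-level taxonomy
(the published table lists only IDs, immunogens and references).  The
168-antibody life-detector panel is a **synthetic fixture**: its full public
description is limited to summary constraints (168 antibodies, 46 of them
against Proteobacteria-derived targets, lettered clusters a–j plus three
sole-antibody groups, a handful of named IDs at known peak positions, more
than 50 control spots per field).  The fixture satisfies every one of those
constraints and fills the rest deterministically
(`fsmi/data/make_ldchip168.py` regenerates it); it supports layout and
profiling machinery, not biological claims.

## Quantification

Per antibody and assay pair (sample + parallel buffer-only blank):

1. **Background subtraction** — `max(0, F635 − B635)` per spot.  The clamp
   reflects non-negative fluorescence and is configurable off
   (`clamp_negative`) for sensitivity analysis.
2. **Replicate QC** — defective spots (non-zero `Flags`) are dropped; a
   replicate set with sample SD (n−1) above `cv_threshold` (default 0.2)
   times its mean is excluded (`excluded_cv`).  The CV rule is read as
   SD > 0.2×mean, i.e. CV > 20% — the common replicate-consistency
   convention; the alternative reading (SD > 1.2×mean) would exclude almost
   nothing.  In the full pipeline the CV rule is **gated on signal**: it
   applies only when the replicate mean exceeds the assay's control baseline.
   Near-baseline replicate sets are background-dominated, their CV is
   essentially noise/0, and excluding them would discard every blank-side
   antibody and every sub-LOD titration point; keeping them is safe because
   an aggregated near-zero value can only produce a negative call.
3. **Control baseline** — `F_avcontrol` is the mean background-subtracted
   intensity of all valid control spots (BSA, buffer, labelled pre-immune
   dilution) of the **sample** assay.  Which assay supplies the baseline is
   not fixed by the source procedure; the sample assay is chosen so that the
   blank enters the equation exactly once, through `F_blank`, keeping the two
   subtraction terms independently testable.
4. **Final fluorescence and call** —
   `F = F_sample − F_blank − m·F_avcontrol` with stringency multiplier
   `m = 2.5`; positive iff `F > 0` (strict).  `F_sample`/`F_blank` are the
   aggregated replicate intensities (mean by default; median available).
   F is computed per antibody, not per spot, because calls, immunogram peaks
   and profiles are per antibody.

## Simulator

The generator emulates triplicate-spotted fields with interleaved controls,
a parallel blank, titration ladders and single-antigen checkerboards.

Signal: loading `θ_i = Σ_j a_ij c_j`; noise-free signal
`S_i = s_max · t(d) · θ_i/(k_half + θ_i)`.  `t(d)` is a Gaussian in
log10 dilution (`exp(−Δlog10²/2w²)`), 1 at the optimum and 0 at zero tracer —
the simplest unimodal response with an interior optimum, reflecting that an
over-concentrated tracer raises background while an over-diluted one starves
the sandwich.  Cognate pairs have affinity 1 by convention; antigens carry
their cognate antibody's ID.

Noise: observed foreground = truncated-Gaussian background
(`N(background_mean, background_sd)` floored at 0) plus `S_i · exp(σz)`
lognormal multiplicative noise; BSA/buffer controls carry background only;
pre-immune spots are printed from labelled antiserum and fluoresce at
`control_level · exp(σz)` above background; spots fail independently with
`defect_prob` (foreground 0, flag set — the dialect has no NaN).  All draws
come from one `numpy` generator seeded per assay, so identical seeds give
byte-identical files.

Defaults (single source of truth `fsmi/data/defaults.yaml`; units in
comments there):

| parameter | default | rationale |
|---|---|---|
| `s_max` | 60 000 | near the 16-bit scanner ceiling |
| `k_half` | 10⁵ cells/mL | places the call boundary in the 10³ decade |
| `tracer_optimum` | 1/850 | centre of the reported 1/800–1/900 working range |
| `tracer_log_width` | 0.5 decades | 1/500 and 1/5000 visibly sub-optimal |
| `background_mean`, `background_sd` | 200 ± 50 | dim, noisy glass background |
| `sigma` | 0.1 | replicate CV of true signals ≈ 10%, inside the 20% QC ratio |
| `control_level` | 400 | labelled pre-immune spots are intentionally visible; drives a baseline ≈ 150 and hence a calling cutoff ≈ 2.5·150 |
| `defect_prob` | 0.01 | occasional missing/tiny spots |

These values are emulation choices, fixed once: with them the default
pipeline yields blank-vs-blank false-positive rates ≈ 0, cognate sensitivity
≈ 1 at 10·k_half, and per-antibody detection limits of 10³ cells/mL on the
half-log titration ladder — inside the 10³–10⁴ decade reported for this
class of assay.

What the simulator does **not** model: spatial artefacts (scratches,
gradients, print-tip effects), field-to-field carry-over, hook effects at
extreme antigen excess, and matrix effects such as salt interference.
Passing tests therefore demonstrate the correctness of the analysis logic
under a plausible noise model, not performance on real extracts.

## Calibration

* **Best tracer dilution**: the tested dilution maximizing
  `f_final/(f_blank + ε)` with ε = 1 fluorescence unit; ties break toward
  the more dilute option (cheaper, lower background).  Signal-to-blank
  rather than absolute brightness, since the aim is discrimination.
* **LOD**: the smallest *tested* concentration from which every higher
  tested concentration reaches the required positive fraction (default 1.0 —
  all replicate assays positive).  No interpolation between points: the
  procedure being emulated steps through dilutions, and detection limits are
  reported to the half-decade.  Scanning from the top enforces monotonicity;
  an isolated positive below a negative never sets the LOD.
* **Calibration curve**: piecewise-linear interpolation of the median
  `f_final` against log10 concentration, defined only on the tested range
  (queries outside it raise, rather than extrapolate).

## Cross-reactivity

Checkerboard assays (each antigen alone at a saturating 10⁶ cells/mL)
populate an antigen × antibody matrix of final fluorescences and calls;
QC-excluded combinations stay missing (NaN), never imputed.  Specificity
classes: *specific* (cognate detected, nothing else), *cross_reactive* (any
non-cognate call), *non_reactive* (no call); an antibody without an observed
cognate assay is never silently classified specific.  The recognition graph
has one directed edge antibody → antigen per call; cognate recognitions are
self-loops kept in the data and dropped only for display.  Mutual
recognition between two antibody/antigen pairs appears as two independent
directed edges.  Sample-profile annotation marks a positive *ambiguous* when
its antibody's checkerboard column contains non-cognate antigens (listed as
alternative explanations) — flagging only; no attempt to invert the call
matrix into antigen composition.

## Profiles

Group profiles divide each group's hit count by the number of that group's
antibodies on the chip and rescale the rates to 100%.  The normalization
formula is a package decision (the source describes it only as weighting by
each group's representation); rate-then-renormalize is the simplest reading
that yields percentages, and it preserves the support set — a group is
non-zero after normalization iff it had a hit.  The comparison against an
external phylum table reports a presence/absence agreement fraction
(detected by both / detected by either) and a Spearman rank correlation over
the shared phyla; both are deliberately simple, descriptive statistics
defined by this package.

## Problem sizes and determinism

The test suite validates the statistical invariants at the scale the package
documents them: 200 simulated assay pairs for false-positive rate and
sensitivity, 100 checkerboard seeds for matrix recovery, triplicate
titrations over the nine-point half-log ladder for the 26-antibody LOD
survey.  Property tests (hypothesis) run derandomized; all simulation seeds
are fixed in the tests, and simulator determinism is asserted as byte
equality of written files.
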