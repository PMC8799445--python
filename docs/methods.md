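# Methods

This note documents the models, algorithms and numerical choices behind
`lfadev`, what the synthetic data generators do and do not emulate, and the
known limitations.

## Factorial design and run splitting

A design is a list of factors (antibodies, matrices, concentrations in
µg/mL), a replicate count, and exclusion rules. Enumeration is the
Cartesian product over factors in declaration order with levels in declared
order and the replicate index innermost; excluded assignments are dropped
before replicate expansion. Condition ids are readable strings
(`capture=MAb001;matrix=blank;rep=2`) rather than hashes so that worklists
diff cleanly across re-runs.

Exclusions are deliberately restricted to two forms: conjunctions of
per-factor level tests, and "all named factors are zero". The second form
is what removes the all-diluent point from a concentration grid — e.g. a
three-antibody 4-level grid yields 63 usable mixtures out of 64 grid
points, because a mixture with no antibody at all is not a meaningful
strip. Richer predicate languages were considered and rejected: these two
forms cover the screening designs the package targets without inventing a
DSL.

Run splitting packs conditions sequentially into runs of at most the
deck's strip capacity, always producing `ceil(n / capacity)` runs. When a
replicate group would straddle a run boundary, the current run is closed
early *only if* that does not increase the total run count, so replicate
adjacency is best-effort rather than guaranteed. Slots are filled holder
by holder in slot order; there is no randomisation of run order by default
(an opt-in seeded shuffle can be layered on top by the caller).

## Mixture planning

Each target component must come from exactly one single-component stock;
the transfer volume is `V = c_target · V_final / c_stock` and the diluent
(a distinguished all-zero "buffer" stock) tops up the final volume. The
recipe invariants — volumes sum exactly to the final volume, and the
achieved concentration recomputed from the transfers matches the target to
a relative 1e-9 — are enforced at construction time. Infeasibility is
diagnosed explicitly: over-concentrated targets, summed stock volumes
exceeding the final volume, and exhausted stock.

Multi-component stocks are rejected rather than solved as a linear system;
single-analyte stocks are the norm in antibody screening, and the general
problem (non-negative least squares over stock combinations) is left as an
extension. Recipes carry exact volumes; `quantize_recipe` rounds to the
instrument resolution (default 0.1 µL — a typical small-volume pipetting
channel resolution; the real value belongs in instrument config) with the
diluent absorbing the rounding, and reports the relative concentration
error introduced.

Serial dilutions are constant-fold: step *k* sits at `top / fold^k`,
prepared by carrying `V_step / fold` µL of the previous solution into
fresh diluent. An explicitly passed carryover that contradicts the fold is
an error rather than silently renormalised.

## Worklist scheduling

The scheduling model: all times are integer seconds (reproducible diffs);
time zero is the first batch of the run; one pipetting gantry executes one
batch at a time, occupying it for a per-batch duration that collapses
aspirate/dispense/tip-handling into a single configurable number (the
defaults are placeholders, not calibrated values). Liquid classes are
opaque labels passed through to the worklist.

Expansion is step-major (step 1 for every strip, then step 2 …), which
aligns strips into stable cohorts; batching then merges consecutive
transfers that share step, action, source labware, volume and liquid class,
up to the channel count (8 by default). Mixture preparation transfers
(stock → mixture tube) are emitted before all strip transfers when
preparation is on-deck (a config switch; off-deck preparation simply omits
them).

Scheduling is greedy earliest-deadline-first. A ready liquid batch (all
predecessors scheduled) runs at `max(now, earliest_start)` unless doing so
would push a ready imaging batch past its deadline; otherwise the most
urgent imaging batch runs. Imaging batches may use their whole tolerance
window (`target ± tol`, default ±60 s, with the target itself a protocol
parameter — e.g. 1800 or 2100 s after sample): starting as early as
`target − tol` lets a backlog of imaging cohorts stay inside their windows
when imaging a cohort takes longer than dispensing to it. Ties break by
batch id, which follows condition order, so output is deterministic. When
a deadline cannot be met the scheduler raises an error proposing a smaller
run (half the current strip count — a coarse but monotone suggestion; the
caller can re-split and retry).

Inter-step delays are start-to-start: step *j* of a strip must start at
least `min_delay_after_previous` seconds after step *j−1* started. This
matches how assay timing is specified (e.g. "sample 2 minutes after
conjugate"), and makes delay satisfaction independent of batch size.

The CSV dialect is fixed and documented in `lfadev.schedule`:
UTF-8, comma-separated, header
`run,batch,channel,action,source_labware,source_pos,dest_holder,dest_slot,dest_well,volume_ul,liquid_class,scheduled_start_s,condition_id`,
one row per transfer or imaging event, imaging rows leaving volume/source
blank. Parsing a written worklist reproduces it field-for-field.

The discrete-event simulator is the independent check on the scheduler: it
replays a worklist against the protocol and reports — never raises —
violations of per-strip step completeness and order, inter-step delays,
imaging windows, single-gantry exclusivity, channel capacity, and running
stock balances. Because the CSV dialect carries no step index, the
simulator maps each condition's events onto protocol steps by time order,
which is unambiguous for well-formed worklists and flags count mismatches
otherwise. Driving a physical robot (vendor method generation) is out of
scope; the simulator stands where the instrument's own scheduler would
validate execution.

## Test-line quantification

The pipeline is profile → peak → baseline → height:

1. **Width-averaged profile**: mean signal across the strip width at each
   position along the flow axis, within the given ROI (0-based, half-open
   coordinates). Colour images convert as `signal = 255 − luminance`
   (Rec. 601 weights) so a dark line on white nitrocellulose reads high; a
   single-channel option exists, and grayscale input is taken as already
   signal-scaled unless inversion is requested.
2. **Peak location**: argmax of a 3-px moving-average-smoothed profile
   within `expected ± search_half_width`. Smoothing suppresses single-pixel
   noise from biasing the argmax; the reported height is read from the
   *unsmoothed* profile so the peak is not attenuated. Ties equidistant
   from the expected position (including a flat window) fall back to the
   expected position.
3. **Baseline**: the straight line through the median levels of two
   flanking windows (default 10 px wide, offset 12 px — about 3σ of a
   typical line — from the peak). Medians make the flanks robust to
   speckle; the linear form absorbs global offsets exactly (offset
   invariance to <1e-6) and linear illumination gradients.
4. **Signal**: baseline-subtracted peak height, clipped at zero, with the
   unclipped value retained for diagnostics.

The flanking windows sit in the Gaussian tail of the line, so the baseline
is biased high by roughly `amplitude · exp(−(offset/σ)²/2)` — under 0.3 %
at the default geometry. On synthetic strips (amplitudes uniform in
[5, 50], sloped backgrounds, pixel noise sd 2) the recovered-vs-true
regression sits at slope ≈ 1.00 with R² ≈ 0.999.

The ROI is given (from deck layout slot coordinates or one-file-per-strip
images), never discovered: strip-edge detection, perspective correction
and flat-fielding are out of scope, and the readout is colorimetric only.

## Synthetic data

`render_strip` draws `background + slope·x + A·exp(−(x−c)²/2σ²)` along the
flow axis, constant across the width, plus iid Gaussian noise, quantised
and clipped to the bit depth (8 or 16). Defaults (σ = 4 px, background 20,
slope up to 0.1 intensity/px, noise sd 2) are camera-scale values chosen to
look like a consumer CMOS image of a latex test line. Gaussian rather than
Poisson noise is appropriate at these averaged intensities and is
configurable. What it does **not** emulate: membrane texture, flow
artefacts, line-width variation, lighting fields, strip misalignment —
so passing recovery tests demonstrates the correctness of the extraction
arithmetic, not robustness to every real-world artefact.

`simulate_screen` generates pair-screen tables. Each capture and detection
antibody has a latent affinity; a pair's effective affinity is the product
times a pair-specific epitope-compatibility term, because a sandwich pair
only works when the two antibodies bind non-overlapping epitopes — a purely
rank-one affinity product cannot represent a small set of strong pairs
without lighting up entire rows and columns. The condition mean is a
saturating (Michaelis–Menten-shaped) function of effective affinity with an
optional hook-effect term (off by default) that depresses signal at very
high affinity, mirroring the high-dose decline sometimes seen in mixture
grids. Blank-matrix conditions sit at the blank level; replicates share
their condition mean and differ only by noise. The generator is a data
source for validating analytics, not an inference target.

`planted_screen_truth` plants *k* strong selective pairs (disjoint in both
antibodies) whose blank-subtracted mean equals `snr × blank_level`
(defaults: blank level 2, noise sd 0.2, snr 5), over a weak random
background whose pair signals stay below about a third of the planted
level. Recovery of the planted top-3 by the cross-reactivity ranking is
essentially deterministic at these settings; the acceptance check requires
≥ 95 % over 100 seeds.

`random_schedule_case` generates scheduling instances that are feasible by
construction: imaging targets are placed beyond a generous bound on the
gantry work between a strip's sample dispense and its image, and per-cohort
imaging durations never exceed sample-dispense durations (a camera snapshot
is faster than a pipetting cycle), so imaging keeps pace with cohort
spacing.

## Screening analytics

Blank subtraction is per pair: the antigen-matrix replicate mean minus the
same pair's blank-matrix mean (so blanks map to zero exactly). S−N is that
difference; S/N divides by the pair's blank mean and is undefined (NaN)
when the blank mean is not positive. The noise term is pair-specific by
default with a plate-wide (global blank) option, since screening practice
varies on this point. Heatmaps are replicate means over the full capture ×
detection grid with missing cells left as NaN, never imputed; both raw and
blank-subtracted versions are emitted because either may be wanted for
display.

Cross-reactivity ranking sorts pairs by descending on-target
blank-subtracted signal and filters out pairs whose off-target signal
exceeds a threshold (default 3× the blank noise sd). The output is a
ranked report plus the full scatter table (off-target vs on-target) —
final pair selection is a human decision, not an automated pick.
`method_correlation` is the standard product-moment R with the two-sided
t-transform p-value (scipy), guarded against degenerate input. Published
clinical correlation values from physical screens are not reproducible
from synthetic data and are not targets of any test here; the tests verify
the computation analytically (affine input → R = ±1) and by Monte Carlo
(shared-variance construction with known population R).

## Problem sizes and determinism

The test and acceptance workloads use 200 synthetic strips for imaging
recovery, 1000 random mixtures for mass balance, 200 generated runs (up to
96 strips each) for scheduler closure, and 100 seeded 16 × 16 screens for
analytics recovery — sizes at which the checked statistics are stable to
well within their thresholds while the whole suite runs in seconds. All
randomness flows through `numpy.random.default_rng` seeded from a single
integer (sub-seeds via `SeedSequence`), so every number in the acceptance
output is reproducible from `--seed`.

## Known limitations

- Scheduling is greedy EDF, not optimal: instances exist that a solver
  could schedule but the heuristic refuses (it then proposes a smaller
  run). At the 96-strip scale this has not been observed for realistic
  timing parameters.
- Mixture planning handles single-component stocks only.
- The imaging pipeline assumes the line lies inside the given search
  window on a locally linear background; curved illumination across the
  line region biases the baseline.
- Per-batch durations and pipetting resolution are configuration
  placeholders, not instrument calibrations.
- The CLI `worklist` command resolves reagent references against stocks;
  recipe-backed mixtures are currently a library-level feature
  (`build_worklist(recipes=...)`).
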