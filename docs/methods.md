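# Methods

## Model representation and flux balance analysis

A model is a set of compartments, metabolites and reactions with signed
stoichiometric coefficients (negative = consumed), per-reaction flux
bounds and a designated objective reaction. Compartment ids follow the
host–microbe convention used throughout: `c`/`e` microbe cell and its
extracellular surroundings, `cm`/`em` host cytosol and extracellular
space, `o` the OMV interior, `lu` the shared gut lumen. Boundary
pseudo-reactions carry an origin tag: `exchange` (lumen ↔ system
boundary, negative flux = uptake, BiGG convention), `source`/`sink`
(probe reactions creating/destroying one metabolite), `omv_transport`,
`gapfill`, `original`.

FBA maximizes one reaction's flux subject to steady state (`S v = 0`)
and bounds, solved with HiGHS via `scipy.optimize.linprog`. Numerical
conventions:

- **Infinity cap ±1000 flux units.** "Unbounded" bounds are stored as
  ±1000 (common COBRA practice) so every LP is bounded and vertex
  enumeration oracles terminate.
- **Tolerances.** LP feasibility 1e-9; a flux counts as non-zero above
  `flux_epsilon` = 1e-6; flux-*consistency* (blocked-reaction and
  gap-filling) uses a larger `consistency_epsilon` = 1e-4 so that
  consistency is not decided at solver noise level.
- **Units.** Bounds are treated as opaque flux units (g/gDW/h in the
  datasets this package targets); no conversion is performed anywhere.
- An infeasible LP after a knockout is scored as zero growth.

SBML I/O uses Level 3 Version 1 with the FBC v2 package (bounds as
shared parameters, objective as an FBC objective). Organism and origin
tags travel as key–value pairs in SBML notes, the same mechanism
cobrapy uses, which keeps the files readable by other COBRA tools (the
test suite has cobrapy re-read and re-optimize a written model as an
independent cross-check).

## Metabolomics presence calling and export inference

Replicate tables are long-format: one row per (metabolite, sample,
replicate), samples described by medium (RM/DM), compartment
(cell/medium/OMV) and time point (TP1/TP2, `blank` for pre-inoculation
medium, NA for OMV preparations pooled over growth). A replicate
*detects* a metabolite when its intensity is present and positive;
missing values are non-detections. A metabolite is *present* in a
sample when detected in at least two of three replicates; for other
replicate counts the rule generalizes to `k ≥ n−1` (configurable via
`presence_min_detected_offset`). Replicate consistency is the fraction
of (metabolite, sample) pairs detected in all or none of their
replicates, among metabolites detected anywhere.

Export inference composes two stated criteria: a one-sample two-tailed
t-test of the TP2 medium replicates against the pre-inoculation blank
mean, Benjamini–Hochberg across all tested metabolites at q = 0.05,
gated by a TP1 → TP2 mean increase (blank mean stands in when TP1 is
absent). Intensities are used on the scale provided — no log transform
by default, since scaled intensities are already normalized; metabolites
with fewer than two TP2 replicates are skipped with a warning.
Zero-variance t-tests return p = 0 (with a warning) when the common
value differs from the reference, p = 1 otherwise.

The Stokes–Einstein computation uses the exact 2019 SI Boltzmann
constant; `r_h = k_B T /(6π η D_t)` is its own inverse, which the tests
exploit as a round-trip identity at 1e-12 relative tolerance.

## OMV expansion

Host entities that sit in the generic `c`/`e` compartments (tagged
`host`) are first relocalized to `cm`/`em` with ids re-suffixed; the
transformation is an isomorphism, so every feasible flux distribution
is preserved (tested). Expansion then adds compartment `o` and, per
cargo metabolite, species in `c`, `o` and `cm` (created where absent)
plus two irreversible transports `TOMV_<base>_c_o` and
`TOMV_<base>_o_cm` with bounds [0, 1000] — mass can only move
microbe → vesicle → host, and FVA confirms no reverse flux. Cargo not
observed in vesicles under a given growth medium has both its
transports closed ([0, 0]) for simulations in that medium.
KEGG-style ids are resolved through a KEGG↔BiGG dictionary; ids with no
entry are reported as skipped rather than failing the expansion,
mirroring the exclusion of non-mappable metabolites upstream. Dictionary
merges are last-writer-wins with `manual` provenance overriding `base`,
and duplicate BiGG targets collapsed in favor of the manual entry.

## Gap filling

A metabolite is *unconnected* in consumable (producible) mode when a
temporary source (sink) on it cannot carry `flux_epsilon` of flux; a
reaction is *blocked* when its FVA range is within
`consistency_epsilon` of zero. Candidate repairs come from a
compartment-free universal reaction database (TSV of equations in a
`a A + b B <=> c C` dialect) instantiated into the target compartment
with bounds derived from a reversibility label
(reversible/forward/backward).

Selection is an exact set-selection MILP solved with HiGHS through
`scipy.optimize.milp`: one steady-state flux vector per unconnected
target, a shared binary indicator per candidate reaction, big-M
coupling `|v| ≤ 1000·y`, each target's probe forced above the
consistency threshold, objective = number of candidates used. A second
solve at the optimal cardinality minimizes exact power-of-two weights
over lexicographically sorted candidate ids, making the selected set
deterministic and reproducible. The exact program was preferred over an
iterative LP heuristic because at the instance sizes this package
targets (tens of model reactions, up to a few dozen candidates) it is
fast and directly guarantees the minimal-cardinality contract that the
test suite verifies against an independent brute-force subset
enumeration. Targets unreachable even with the full database are
reported unresolved, not fatal. Currency metabolites are not excluded
from candidate stoichiometries (no flag is set by default).
Exporter-style repairs can be offered through an optional transporter
pool that enters the same selection.

Reversibility reconciliation overrides each selected reaction's
estimated reversibility with its curated value where the two disagree,
resets bounds to the curated direction, logs the override and re-checks
target connectivity — a target whose only consuming reaction flips to
the producing direction is honestly re-flagged as unconnected.

## Classification protocols

To probe one organism endogenously, the other organism's lumen
interface (all its organism-tagged reactions touching a lumen
metabolite) is closed, every OMV transport is closed, and diet uptake
bounds are applied at the lumen exchanges. Consumability then maximizes
a temporary source on the metabolite, producibility a temporary sink;
the flag is `optimum > flux_epsilon`. Metabolite essentiality (microbe)
closes every reaction whose stoichiometry contains the metabolite in
the cell compartment, applies the growth medium (exchange lower bounds
−100 for medium components; all exchanges for rich media) and any
observed-uptake forcing (sources with a small non-zero lower bound,
`forced_uptake_min` = 0.01 — a value well below any uptake bound,
fixed once and exposed in the config), maximizes biomass, and calls the
metabolite essential when growth falls below 0.1 h⁻¹. All operations
are transactional — they act on copies or restore bounds — and the
tests assert bit-identical model state afterwards.

The route partition behind the expansion summary is computed as: cargo
whose host-cytosol species is producible with OMV transports closed can
transfer *directly* (microbe export through the lumen plus host
import); cargo producible only with transports open is *OMV-only*.

## Synthetic data: what it emulates and what it does not

The generators stand in for inputs that real analyses cannot ship and
always return the planted ground truth alongside the artifact. All randomness
flows through `numpy.random.default_rng(seed)` (PCG64); identical
parameters and seed give byte-identical outputs.

**Host–microbe model.** Each organism gets lumen nutrients with
exchanges, uptake transports, three-step linear pathways to biomass
precursors, and a biomass reaction consuming every precursor. A
configurable fraction of pathways has a redundant parallel branch:
linear-pathway intermediates are essential by construction, redundant
ones are not. Planted special cases: metabolites produced but never
consumed (the creatinine pattern: producible, not consumable), cargo
consumed but never produced endogenously, directly exported
host-importable cargo (`dex*`) and vesicle-only cargo (`vonly*`).
Default scale (3 pathways per organism, ≲ 80 reactions total) keeps
every brute-force oracle fast.

**Gap-fill instances.** Targets are reaction-less metabolites planted in
the host cytosol; the database holds the unique reaction chain that
degrades each into the host's waste pool plus decoy reactions over
fresh metabolite bases — trivially mass-balanced dead ends that can
never substitute for a planted repair. Necessity and sufficiency of the
planted set are verified at generation time, making it the unique
minimum. A configurable number of planted reactions carries a curated
reversibility opposing the estimate, so reconciliation demonstrably
flips their targets back to unconnected.

**Metabolomics tables.** Three replicates across RM/DM ×
cell/medium/OMV × TP1/TP2 with pre-inoculation blanks; presence truth
drawn per sample with OMV presence nested inside cell presence;
Bernoulli detection noise around the truth; super-pathway labels from
the eight standard top-level categories. The medium compartment
emulates what batch growth does to spent medium: exported products are
absent from blanks and rise to `export_effect_size` (default 5) noise
standard deviations by TP2; by default 85% of the medium's own
components are depleted by the same magnitude; flat profiles are the
minority. This matters statistically: with mostly-null test sets the
Benjamini–Hochberg step-up operates far below its nominal level for
n = 3 (df = 2) t-tests and no realistic effect size is recoverable at
high sensitivity, whereas under the realistic mostly-changed
composition BH behaves near-nominally and 5σ effects are recovered with
sensitivity ≈ 0.95 at observed FDR below 1.5q.

**Annotation bundles.** Synthetic KEGG↔BiGG dictionaries over the
model's metabolite bases, pathway annotations padded with 60 extra
mapped background compounds (pathway databases cover far more compounds
than one model, and the enrichment background must reflect that), and a
uniform-uptake diet stand-in. `enrichment_factor` is the relative rate
of planted-pathway members among query draws — factor 1 reduces exactly
to uniform sampling, factor f plants a genuine f-fold
over-representation. Pathway and query sizes (12/12) were fixed by a
prospective power calculation so that a 5-fold planting is detectable
in ≥ 90% of seeds while the null configuration stays clean in ≥ 95%.

What passing tests on these fixtures shows — and does not: they verify
the algorithms (LP/MILP correctness, set logic, statistical
calibration, transactional state handling) under known truth; they do
not validate biological conclusions on real data, mimic real KEGG
stoichiometry, mass-spectrometry intensity distributions, lipid
structures, or the curation noise of real metabolomics panels.

## Statistics

χ² enrichment is Pearson's test on a 2×2 table, df = 1, no continuity
correction (the default matches common enrichment practice; a corrected
variant is not applied anywhere in the pipeline), upper-tail p; a zero
marginal yields p = 1 with a warning. BH is the standard step-up
procedure (statsmodels) with rejection at q ≤ 0.05. Metabolite set
enrichment is implemented as over-representation analysis: one-sided
hypergeometric per pathway, BH across pathways; "no pathway
significant" is a first-class outcome. The background set is an
explicit required argument everywhere — enrichment conclusions are
meaningless without it, and the choice is deliberately never implicit.
Numeric property comparisons (lipid chain length, saturation) default
to a two-sided Mann–Whitney U test — exact null for small untied
samples, tie-corrected normal approximation otherwise — because a
rank test needs no distributional assumption the data cannot support;
chain lengths and double-bond counts are expected as annotations in the
input table, never parsed from names.

## Pipeline

`run_pipeline` executes the stages in analysis order (measurements →
expansion → gap fill → classification → enrichment → route counts) from
a YAML/dict config that either names input files or requests synthetic
generation from the run seed. Stage sub-seeds are derived as seed+1,
seed+2, … so stages are independently reproducible. Reports are written
atomically (temp file + rename), a failed run writes a partial report
marked incomplete together with the error record, and every stage
warning lands in the report's warning ledger. All derived counts in the
report are recomputed from the stage artifacts it cites.

The problem sizes used by the default configuration and the acceptance
script (≈ 40-metabolite panels, ≲ 80-reaction models, databases of ≤ 12
candidates, 200-replicate statistical simulations) were chosen so every
brute-force oracle and simulation completes in seconds while still
exercising each code path; they are package defaults, not limits of the
method.

## Known limitations

- No thermodynamic FBA, flux sampling, or gene–protein–reaction
  evaluation; annotations are carried as strings.
- Gap filling instantiates candidates within a single compartment
  (plus the optional transporter pool); it does not invent
  inter-compartment transports.
- The exact MILP selection scales to hundreds, not tens of thousands,
  of candidate reactions; genome-scale universal databases would need
  the iterative-LP style of selection this package deliberately does
  not implement.
- Enrichment p-values assume a well-chosen background; the package
  computes the tests but cannot decide the background for you.
- The lumen/diet abstraction ignores spatial structure, transit, and
  absorption kinetics.
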