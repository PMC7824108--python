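# Methods

## Labeling model

AminoxyTMT sixplex chemistry attaches one tag per derivatizable site: a
carboxy group (activated by DMTMM) or a phosphate monoester (activated by
EDC). Site counts per species are structural constants: free fatty acids and
monocarboxy oxylipins have one carboxy; 20-carboxy-LTB4 and tetranor-PGDM have
two; LPA and PA each have one phosphate monoester. LPC and LPE are
phosphodiesters — both remaining phosphate oxygens are bonded to carbon — and
cannot be labeled; neither can DAG. These species are routed to a native
(underivatized) SRM method instead.

The TMT precursor rule is the instrument method's literal arithmetic:

    Q1 = (M_mono − k·1.00783 + k·303.25) / k,  charge = k, positive mode

where k is the tag count. 303.25 is the nominal per-tag mass offset at
triple-quadrupole unit resolution, and 1.00783 the hydrogen replaced per
coupling. For k = 2 the species is emitted as its divalent ion — the natural
extension of the printed singly-labeled rule, isolated in `tmt_precursor` so
it can be swapped if an instrument prefers different arithmetic. An
`exact_tag` mode substitutes a user-supplied calibrated tag mass; absent a
user value it falls back to the nominal 303.25 (the package does not guess an
exact reagent composition, and never substitutes silently). Reporter products
default to the unit-resolution ladder 126.15…131.15 (spacing exactly 1.00);
exact sixplex reporter fine masses are available via
`default_channels(exact_reporters=True)` for high-resolution use.

Collision energy defaults to 46 eV in positive mode for derivatized
compounds; it is a per-list override (vendor software sometimes reports the
equivalent setting with opposite sign).

## Masses and formulas

Element masses are hard-coded IUPAC values (monoisotopic to six decimals,
average to three) so emitted m/z values are reproducible with no external
dependency; the test suite cross-checks them against pyteomics' independent
element table. Adduct ions use the proton mass (1.007276 Da): [M+H]+ for
LPC/LPE, [M+NH4]+ for DAG (ammonium bicarbonate mobile phase), [M−H]− for
native LPA/PA. Shorthand composition rules (total carbons c, double bonds d):

| class | formula | label sites |
|-------|---------|-------------|
| FA(c:d)  | C_c H_{2c−2d} O2          | 1 carboxy |
| LPA(c:d) | C_{c+3} H_{2c+7−2d} O7 P  | 1 phosphate monoester |
| PA(c:d)  | C_{c+3} H_{2c+5−2d} O8 P  | 1 phosphate monoester |
| LPC(c:d) | C_{c+8} H_{2c+18−2d} N O7 P | none |
| LPE(c:d) | C_{c+5} H_{2c+12−2d} N O7 P | none |
| DAG(c:d) | C_{c+3} H_{2c+4−2d} O5    | none |

Per-chain notation (`PA(18:1/18:1)`) is summed to totals; sn-position and
double-bond geometry are out of scope, so positional isomers such as 12-HETE
and 20-HETE share a formula and are distinguished only by name and retention
metadata. The oxylipin registry ships the panel standards and is extensible
by CSV; tetranor-PGDM's default formula is C16H24O7 (a C16 prostane-dioic
acid) but only its two-carboxy site count matters to the pipeline, so the
formula is registry-configurable.

## Native method and validation notes

The six panel species' native transitions (LPC(16:0) 496.35→184.1, LPE(18:1)
480.3→339.3, DAG(18:1/18:1) 636.6→339.3 positive; LPA(16:0) 409.4→153.1,
LPA(18:1) 435.4→153.1, PA(36:2) 699.6→153.1 negative) are instrument-tuned
values stored verbatim, not re-derived: unit-resolution Q1 settings are
routinely nudged off the exact mass. Novel LPC/LPE species get computed rules
([M+H]+; phosphocholine 184.1 product, or loss of phosphoethanolamine
C2H8NO4P = 141.019 Da). `validate_transitions` audits any list by recomputing
every precursor from its formula: the sixplex lists agree to 0.01 m/z by
construction, the stored native Q1s agree within 0.3 m/z except
DAG(18:1/18:1), whose stored 636.6 is ~2 m/z below the computed [M+NH4]+
(638.57) and matches no common adduct of C39H72O5; it is flagged, stored
as printed, and left to the operator.

## Quantification

Ratios are computed per replicate against the bridging channel of the same
run (each LC/MS run carries its own bridge), so any per-set multiplicative
factor cancels identically — the property is tested with random scale factors
spanning two orders of magnitude. Zero or missing bridge areas invalidate
their whole (set, species, replicate) group; imputation would silently break
the method's core guarantee. Ratios stay in linear space.

Fold changes divide by the per-species mean ratio at a reference
(condition, time). Two modes exist because cross-run linkage is a design
choice: `bridge` mode (default) assumes the bridging channel of every set
carries the same reference aliquot (pooled QC, 0 h), which makes fold changes
exact under arbitrary set effects; `raw` mode divides raw areas and assumes
cross-run response stability, a caveat the code logs. The simulator
demonstrates the contrast: raw-mode error grows with the set-effect scale
while bridge mode is invariant.

## QC statistics

CV% = 100·sd/mean with the sample (n−1) standard deviation — the spreadsheet
convention such validation tables are computed with. Dilution linearity is
the Pearson correlation between relative concentration x = 1/fold-dilution
and per-level mean area (means, matching a five-point spreadsheet CORREL
usage; a pooled-points option exists). x = 1/fold is the default because a
proportional response then gives r = +1, whereas correlating against the raw
fold factor gives a strongly negative r on the same data; the x-axis mode is
recorded in the report. Default thresholds: CV ≤ 30%, r ≥ 0.94 (the assay's
observed validation floor).

## Simulator

Peak areas are multiplicative lognormal:

    area[s,i,c,r] = T[i,c] · S[s] · B[c] · R[i] · ε

- `T` — true abundance relative to the bridge (bridge channel ≡ 1: the common
  pooled-QC 0 h aliquot in every set). Configurable per (species, condition,
  time); defaults to 1.
- `S ~ LogN(0, set_effect_sigma)` per set; default σ = 0.5, large run-to-run
  scale variation the bridge must remove.
- `B ~ LogN(0, channel_bias_sigma)` fixed per channel; default σ = 0. This is
  the one nuisance bridging does **not** cancel (a labeling-efficiency
  character of each reagent channel); it defaults off and exists as an
  explicit stressor so users can see the method's limit.
- `R ~ LogN(0, response_sigma)` per species (default σ = 0.5), cancelling in
  all relative quantities.
- `ε ~ LogN(0, noise_sigma)` per measurement; default σ = 0.1, giving
  CV ≈ 100·√(exp(σ²)−1) ≈ 10%, inside the 1.8–28.4% envelope observed in the
  assay's validation.

The stability design mirrors the study layout: six channels (five pooled
disease conditions + QC bridge), time points 0 h and 20 h, three replicates —
one sixplex set per (time, replicate). The dilution design produces expected
area ∝ 1/fold over levels ×1…×16 with each level on its own reporter channel.
All randomness flows from one `numpy` Generator seeded by the config, so
output is bit-identical across runs.

What the simulator does *not* emulate: chromatographic peak shape and
integration, reporter-ion isotopic impurity (not part of this workflow's
processing), enzymatic kinetics of serum lipid degradation (stability trends
are configured, not modeled), and detection limits. Passing recovery tests
therefore validate the normalization arithmetic and statistics, not
instrument behavior.

## Test and acceptance problem sizes

Unit and property tests run on panels of 4–20 species. The Monte-Carlo
recovery check uses 200 species × 6 channels × 2 time points × 3 replicates
(7,200 records) at noise σ = 0.1, asserting the median per-species |bias| is
below 0.05 for true folds in [0.25, 4]; the lognormal-CV calibration check
uses 20 species × 5 levels × 25 replicates so the small-sample sd bias
(~1%) is negligible against a 15% relative tolerance. These sizes keep the
full suite under a few seconds while leaving Monte-Carlo error well inside
the asserted bounds.

## Known limitations

- Unit-resolution arithmetic throughout by default; exact-mass options are
  provided but the shipped defaults mirror a triple-quadrupole method.
- The native method covers the six panel species plus computed LPC/LPE rules;
  other classes must be added to the registry.
- No isotopic-impurity correction between reporter channels and no absolute
  quantification — the workflow is deliberately relative, anchored to the
  bridging sample, and species undetected in the bridge cannot be quantified.
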