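# Methods

`pre60s` implements the post-identification half of a bait-resolved
SWATH/DIA affinity-purification study of large-ribosomal-subunit (pre-60S)
precursors: starting from long-format peptide-assay tables of the shape
produced by OpenSWATH → pyProphet → TRIC, it filters identifications,
normalizes run intensities on a core r-protein anchor set, imputes missing
assays, rolls peptides up to proteins, and derives the study's two core
readouts — per-factor residence profiles along a maturation axis, and
mutant-vs-control accumulation classes for genetically trapped particles.
A discrete dependency model of the cytoplasmic maturation pathway predicts
trapped-particle compositions for comparison with those classes. A
synthetic data generator with known ground truth makes every stage
testable without any external download.

## The quantification procedure

All stages operate on one table shape: one row per peptide precursor per
MS run, with run/condition/replicate labels, a protein group (paralog
groups such as `RPL19A/RPL19B` are atomic), an intensity (absent or empty
= missing), an identification error score (m-score, lower is better), and
decoy/proteotypic flags.

**Filter cascade.** In order:

1. *m-score filter.* Keep peptide assays with m-score `< 0.01`, but only
   for protein groups that pass a protein-level gate: at least one
   non-decoy peptide row with m-score `< 0.00000208508` (the value
   corresponds to a 1% protein-level FDR in the upstream scoring). Both
   comparisons are strict ("below"); the gate is evaluated on the
   unfiltered table. Decoy rows are dropped here — they exist only to
   calibrate upstream error rates.
2. *Anchor normalization* (between the two filter halves; see below).
3. *Proteotypic filter.* Only peptides mapping to a single protein group
   are quantified.
4. *Replicate-consistency filter.* An assay is kept — across all
   conditions — iff it has an observed intensity in **every** replicate of
   at least one condition. "Identified" means an observed (non-missing)
   intensity in that run.
5. *Minimum-peptide filter.* Protein groups with fewer than 2 distinct
   surviving peptides are removed.

Every filter is a pure row selection (idempotent, intensity-preserving),
and each is checked against an independent brute-force row-enumeration
oracle in the test suite. Whether the replicate rule runs before or after
the m-score filter is not observable from the procedure's description
alone; the cascade order above is the default and the alternative order is
available via `FilterConfig(replicate_before_mscore=True)`.

**Anchor normalization.** A set of twelve core 60S r-protein groups of
assumed constant stoichiometry (RPL28, RPL14B, RPL14A, RPL3,
RPL19A/RPL19B, RPL35A/RPL35B, RPL12A/RPL12B, RPL27A/RPL27B, RPL2B/RPL2A,
RPL14A/RPL14B, RPL7B/RPL7A, RPL1A/RPL1B — kept verbatim from the analysis
this reproduces, including the curious co-occurrence of RPL14A, RPL14B and
RPL14A/RPL14B as three distinct identifiers; duplicates are de-duplicated
by string only) anchors each run's intensity scale. The *anchor summary*
of a run is the mean over anchor groups of the group's summed peptide
intensities; averaging across anchor proteins rather than pooling peptides
keeps peptide-rich anchors from dominating (a peptide-pooling variant is
available). Each run is rescaled by a single multiplicative factor so its
anchor summary reaches a common level.

The common level defaults to **1.0**: intensities are thereafter expressed
relative to the run's mean anchor-protein intensity. This choice makes
normalization *exactly* invariant to any per-run rescaling of the input —
a run-level batch effect (purification yield, injection amount) is
absorbed completely, to floating-point precision — which is the property
the rest of the pipeline relies on. Setting `target="grand_mean"` instead
restores the dataset's average anchor level (preserving the input's
absolute scale) at the cost of that exact invariance, since the grand mean
itself moves when a run is rescaled. All downstream readouts are
scale-free, so the two variants differ only by one global constant. A
log-scale variant (`mode="log"`, geometric mean across anchors) is
provided; a three-anchor variant of the anchor list is available as
`THREE_PROTEIN_ANCHORS`.

**Imputation.** After all filters, every missing (assay × run) cell is
filled with `u · m`, where `u ~ Uniform(0.7, 0.9)` independently per cell
and `m` is the assay's lowest observed intensity anywhere in the dataset.
The replicate-consistency filter guarantees each surviving assay has
observed values. Imputed cells are flagged, and the per-protein imputed
fraction is propagated to the final matrices. Draws are consumed in
sorted (protein group, peptide, run) order, so results are independent of
input row order; the seed is mandatory and recorded in the run manifest.
Note the floor is *shallow*: an assay observed only at a flat plateau has
`m` close to the plateau, so "absent" can only be distinguished from
"present" when the data contain genuine low observations. This matters
for detecting depletion (see limitations).

**Rollup.** Peptide-assay intensities are summed to a protein intensity
per run (meaningful because a peptide's ionization efficiency is a peptide
property, constant across runs). Per condition, the arithmetic mean and
the sample (n−1) standard deviation over replicate runs are reported.
The rollup requires a complete grid — i.e. runs after imputation — and
errors otherwise, listing missing cells.

## Profiles and classes

**Residence profiles.** Each protein's condition means over a selected
(ordered) condition set are divided by their maximum, giving values in
[0, 1] with the maximum exactly 1 ("maximum enrichment"). Ties at the
maximum break toward the earliest condition. The automated *stage
assignment* labels each protein with the maximal contiguous run of
conditions within `plateau_tol` (default 0.25) of 1 that contains the
maximum — a surrogate for the manual, structure-informed grouping such
heat maps receive; no model-based clustering is attempted.

**Fold changes.** Per protein, fold change = condition mean divided by
the mean of the condition with the highest protein intensity (the
reference), with per-condition SDs divided by the same reference. The
fold-change matrix and the scaled profile matrix are identical when
computed on the same condition set; both are kept because they are
reported differently (heat map vs bar plots).

**Accumulation classes.** For a (mutant, control) condition pair, the
ratio of condition means classifies each protein as *accumulated*
(ratio ≥ 2), *depleted* (ratio ≤ 0.5) or *unchanged*. The thresholds are
explicit surrogates for a visual clustering step that has no published
cutoff, and are prominent in the configuration. A zero control mean gives
an infinite ratio, classed accumulated and flagged. Proteins whose means
rest on imputed values are classed normally, with the imputed fraction
reported alongside.

## The pathway model

Cytoplasmic pre-60S maturation is encoded as a DAG of discrete events —
`release(factor)`, `recruit(factor)`, `load(r-protein)` — where an event
fires only once all its prerequisites have fired. The shipped default
graph (`src/pre60s/data/pathway.yaml`, an editable YAML file: the graph is
data, not code) encodes: Drg1-ATPase release of Rlp24 initiating the
pathway (Bud20 release coupled to it); Rei1 recruitment requiring Rlp24
release, Arx1 release requiring Rei1, Reh1 recruitment following Rei1
release; Nog1 release requiring both Rlp24 release and Nog1's own
G-domain; Yvh1 recruitment (hence Mrt4 release) and uL16/eL40 loading
gated by Nog1 release; Nmd3 release upon uL16 accommodation; and Tif6 and
Reh1 release triggered by Nmd3 release.

Two perturbation handles disable blockable events: `Drg1DN` (ATPase-dead
Drg1, equivalently diazaborine) blocks `release(Rlp24)`; `Nog1DN`
(G-domain mutant) blocks `release(Nog1)`. Given blocks, a reachability
closure predicts the trapped particle: a factor **accumulates** if it is
pre-loaded (or recruitable) but its release is unreachable; it is **not
recruited** if its recruitment event is unreachable. The model is purely
qualitative — no rates, no stochastic timing.

Factors whose co-trapping is observed but whose mechanism is speculative
(Sqt1, Tma16, Mex67, Ecm1, Arb1; also the Nsa2-release dependency) are in
the graph but flagged `inferred: true` and excluded from the `core_factors`
set used for exact cross-checks. Reh1 sits outside the core set for a
different reason: its encoded recruitment chain (via Rei1 release) makes
it unrecruitable under a Drg1 block, whereas trapped-particle data show it
accumulating there — a known tension between the drawn pathway and the
measurements that the model preserves rather than hides.

One consequence of the two-set semantics is worth stating: as a blocked
set widens, the not-recruited set and the union (accumulated ∪
not-recruited) grow monotonically, and accumulated *pre-loaded* factors
are never rescued — but a recruit-dependent factor can legitimately move
from accumulated to not-recruited when a wider block removes its
recruitment (Reh1 under `{Nog1DN}` → `{Drg1DN, Nog1DN}` is the canonical
example). The property tests assert exactly this form.

`consistency_check` tabulates, per factor, the prediction against the
enrichment-derived class and reports precision/recall of the predicted
accumulated set; factors absent from the quantification are "untestable".

## The synthetic study

The generator emulates a bait-resolved AP-MS study along the maturation
axis Ssf1 (early nucleolar) → Rix1 (nucleoplasmic) → Arx1 (export-ready)
→ Lsg1 (cytoplasmic), three replicate purifications per condition, plus
mutant-trapped conditions (`Lsg1:Drg1DN`, `Lsg1:Nog1DN`). Observed
intensity follows a multiplicative model:

    I = abundance × occupancy(condition) × peptide_efficiency
        × run_factor × exp(N(0, log_noise_sd))

with missingness as absent rows. Defaults, with rationale (all are
`SimulationParams` fields; intensities are in arbitrary units around
10^5):

| parameter | default | why |
| --- | --- | --- |
| occupancy profile | plateau 1 over a contiguous residence interval, residual 0.05 outside | factors recruit and release in blocks; released factors leave sub-stoichiometric traces and co-purification background, which is what gives real heat maps their low-but-nonzero minima. With residual exactly 0, the imputation floor (0.7–0.9 × assay minimum) sits at ~0.75 of a flat plateau and absent conditions become indistinguishable from resident ones — the generator would then misrepresent the contrast real data have |
| `log_noise_sd` | 0.1 | replicate *composition* noise of a peptide assay (~10% CV). Purification-yield variability between replicate pull-downs is deliberately carried by the run factor instead, because anchor normalization absorbs exactly that |
| `run_effect_range` | U(0.7, 1.4) | bait recovery and injection amount vary visibly between pull-downs |
| dropout | logistic in log10 intensity, midpoint 10^2.5, slope 1.5 | intensity-dependent missingness; ~5% overall at these abundances, typical of TRIC-aligned SWATH |
| m-scores | confident 10^U(−9,−3); poor 10^U(−3,0) with probability logistic in log10 intensity (midpoint 10^3, slope 2) | identification confidence tracks signal strength; abundant r-protein peptides are confidently identified in every run (which is what makes anchor normalization workable), while weak assays score erratically. An intensity-independent poor-score model would let a dominant anchor peptide vanish from single runs and corrupt the normalization in ways real data do not show |
| abundances | factors 10^N(5, 0.8); anchors 10^N(5, 0.3) | anchors are stoichiometric core r-proteins — one copy per particle — so their spread is tight; factor abundances span ~2 orders |
| peptides/protein | U{3..8}, efficiencies 10^N(0, 0.8) | realistic peptide counts; efficiency spread means protein sums are dominated by a few peptides |
| decoys | 10% of rows, identifiers disjoint from targets, intensities from the low target tail, m-scores 10^U(−3,0) | enough decoy mass to exercise the gate |
| trap design | 20% of factors trapped at 4× occupancy, 5% recruitment-impaired (occupancy 0) per mutant condition | clear but not caricatural enrichment effects |

`default_dataset(seed)` assembles the canonical study: 100 factors + 12
anchors, 6 conditions × 3 replicates (~10,700 rows), with
deterministically chosen trap sets. Everything is reproducible from the
seed alone; two calls with equal parameters are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no retention-time structure, chromatographic
interference or peak-boundary errors; no correlated (batch-wise)
missingness; no interference-driven intensity bias in shared windows; no
compositional competition between baits for the MS duty cycle; occupancy
is exactly plateau-shaped, whereas real residence profiles have graded
edges; decoy scores are drawn from a fixed band rather than a learned
error model. Parameter recovery on this generator demonstrates the
pipeline's algebra and its robustness to the modelled noise sources, not
immunity to those unmodelled ones.

## Numerical choices and degenerate inputs

- Strict `<` at both m-score thresholds; ties at row maxima break to the
  earliest condition in the configured order and are logged.
- Condition SDs use the n−1 denominator; a single-replicate condition has
  an undefined (NaN) SD.
- Proteins with no positive mean across the selected conditions are
  excluded from profiles with a warning; a zero control mean in a
  comparison yields an infinite ratio, classed accumulated and flagged.
- `plateau_tol` ∈ [0, 1); the stage interval is the maximal contiguous
  super-threshold run containing the argmax, so an isolated
  within-tolerance condition elsewhere does not extend the interval.
- The imputation RNG is a named, seeded generator; the manifest (config,
  config hash, seed, per-stage row counts, package version) suffices to
  re-run a pipeline byte-identically (`run_from_manifest`).
- An anchor group with no observed assay in some run is an error naming
  both the anchor and the run; assays with no observed value at all are an
  error at imputation (the replicate filter prevents this in the normal
  pipeline).

## Known limitations

- Depletion calling is weak by construction: the shallow imputation floor
  (0.7–0.9 × assay minimum) means a protein absent from the mutant but
  observed at a flat plateau elsewhere bottoms out near 0.7–0.8 × its
  minimum, not near zero, so only proteins with genuinely low observed
  intensities somewhere in the dataset can fall below the 0.5 ratio. The
  accumulated class, the study's primary readout, is unaffected.
- The stage assignment is a threshold rule, not an inference; proteins
  with condition-mean noise comparable to `plateau_tol` get ragged
  intervals. On the canonical study ~95–98% of intervals are exact.
- The pathway model is qualitative reachability over a hand-encoded
  graph; it cannot express partial blocks, kinetic competition, or
  dosage effects, and inferred edges are placement hypotheses, not
  established mechanism.
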