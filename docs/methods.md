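# Methods

## Scope and model

`fragrank` implements candidate ranking for small-molecule identification
from a single high-resolution MS/MS spectrum. The model has three parts:

1. **Combinatorial bond-dissociation fragmentation.** The candidate's
   heavy-atom graph is cleaved top-down, one bond per step, up to a tree
   depth *d* (default 2, i.e. at most two successive cleavages). An acyclic
   cleavage produces the two connected components as child fragments; a
   ring cleavage produces a single open-ring intermediate with the same
   atom set, which counts against the depth and can be cleaved further.
   Hydrogens are implicit (per-heavy-atom counts) and C–H bonds are never
   cleaved. Fragments are stored as bitsets over parent atom and bond
   indices plus the cumulative bond dissociation energy (BDE) of the
   removed bonds; identical (atom set, bond set) states reached by
   different removal orders are merged keeping the cheapest energy.
   Open-ring intermediates whose atom set equals the parent's are not
   matchable (their neutral mass is unchanged); for matching, only the
   cheapest fragment per distinct atom set matters.

2. **Peak matching.** Fragment ions are singly charged. The precursor ion
   type fixes the adduct mass offset (electron mass included; ten species
   from [M+H]+ to [M+CH3COO]−). Integer hydrogen shifts (default
   {−1, 0, +1}) accommodate homolytic/heterolytic cleavage variants. The
   mass window is additive, m/z·ppm·1e−6 + Da (defaults 5 ppm, 0.001 Da).
   Each peak receives at most one fragment: the one with the smallest
   cumulative BDE among all in-window candidates (i.e. the smallest score
   denominator), ties broken by smaller |shift|, then smaller fragment
   mass, then bitset order.

3. **Weighted evidence combination.** The fragmenter score is
   Σ_p RelMass_p^α RelInt_p^β / (ΣBDE)^γ over matched peaks with
   α = 1.84, β = 0.59, γ = 0.47. RelMass is the peak m/z divided by the
   precursor ion m/z and RelInt the peak intensity divided by the
   spectrum's base-peak intensity, so both lie in (0, 1]; these two
   definitions are conventions of this implementation (only "relative"
   quantities are prescribed by the method). A matched precursor fragment
   has zero cleaved energy; its denominator is taken as 1 to keep the term
   finite. Auxiliary terms: combined reference counts (binary selection of
   sources, summed); substructure inclusion N/max(N′) and exclusion
   (n−N)/max(n−N′) with a zero-max guard, each SMARTS pattern contributing
   at most one hit; binary suspect membership by InChIKey first block; and
   the retention-time score below. Every raw term is normalized to its
   maximum over the candidate list (all-zero lists stay zero), and the
   final score is the weighted sum of normalized terms. Stereoisomers are
   deduplicated afterwards on the InChIKey first block, keeping the best
   final score (ties: lexicographically smallest identifier).

## Retention-time score

A linear calibration log P = a·RT + b is fitted by ordinary least squares
to user-provided (RT, log P) standards measured under the same
chromatographic conditions; at least two distinct retention times are
required and fewer than ten points trigger a warning. A candidate with
partition coefficient log P_C scores the normal density

(1/(σ√(2π))) · exp(−|log P_pred − log P_C|² / (2σ²)),  σ = 1.5 (log P units).

The candidate log P source is tagged on the model (a user-supplied column
such as `UserLogP`, or the internal Crippen estimate computed from the
structure) and must match between training set and candidates; the
pipeline enforces this by tag. The two-step workflow for external log P /
log D models is supported by `rescore`, which re-imports a pipe-separated
results table with new columns and recombines without re-fragmenting.

## Parameters that matter

| parameter | default | unit | note |
|---|---|---|---|
| tree depth | 2 | cleavage steps | deeper = more fragments, slower, more false matches |
| match tolerance | 5 ppm + 0.001 Da | m/z window | additive; instrument dependent |
| hydrogen shifts | {−1, 0, +1} | H units | rearrangement allowance for real spectra |
| α, β, γ | 1.84, 0.59, 0.47 | – | fragmenter exponents |
| σ | 1.5 | log P | spread of the retention score |
| term weights ω | fragmenter-only | – | study-specific; ≈(0.5, 0.2, 0.3) for frag/RT/refs is a reasonable default |

## Bond dissociation energies

The BDE table is a text resource (`data/bde_default.txt`,
`element element order energy` in kJ/mol) of standard mean bond enthalpies
for H, C, N, O, F, Si, P, S and halogen pairs; aromatic bonds use a
dedicated entry equal to the mean of the pair's single- and double-bond
values, and unknown pairs fall back to 348 kJ/mol (the C–C single value).
Because the fragmenter score is normalized across candidates, rankings are
sensitive mainly to relative, not absolute, energies. Users can supply
their own table via `BDETable.from_file`.

## Synthetic data: what it emulates and what it does not

The `synthetic` module makes every pipeline stage testable offline.

* **Toy library** (~34 molecules): small organics with exact-mass isomer
  groups, the four triazine herbicide isobars, one salt. Deterministic.
* **Decoys** emulate exact-mass database retrieval: 3–8 random
  formula-preserving perturbations per decoy. The primary move swaps the
  element labels of two sites with equal total bond order (preserves
  formula, skeleton and bond-energy profile while relocating
  heteroatoms); the fallback move migrates one end of a single bond to an
  atom with a spare hydrogen. Perturbations that introduce weak
  hetero–hetero single bonds (O–O, N–N, N–O, N–Cl, O–Cl) are rejected:
  such peroxide/hydrazine-type isomers are rare in real compound
  databases and would be artificially favoured by the BDE denominator.
  Decoys are InChIKey-first-block distinct and kept below Morgan-Tanimoto
  0.7 to the truth.
* **Spectra**: signal peaks are the truth's own fragment ions, sampled
  without replacement with probability ∝ RelMass^α / BDE^γ — collision-
  induced spectra are dominated by fragments that form easily and retain
  most of the precursor. Intensities are uniform in a configurable range;
  m/z jitter is Gaussian (default 0.0002 Da, far inside the matching
  window); noise peaks land at uniform m/z outside every true fragment
  window. No rearrangement chemistry, no isotope patterns, no
  collision-energy dependence and no intensity/stability correlation are
  modelled.
* **RT training sets** invert a known line logP = a·RT + b over computed
  Crippen log P values of sampled library structures, plus Gaussian RT
  noise; with zero noise the OLS fit recovers (a, b) exactly.

### The recovery benchmark and its settings

`recovery_benchmark` runs 50 seeded cases of one truth plus 10 decoys
with zero jitter and zero noise peaks, 12 signal peaks (merged reference
spectra typically carry 10–20), and scores candidates fragmenter-only and
fragmenter-plus-references. Three deliberate design choices:

* **Benchmark truths** are restricted to molecules that can produce a
  structure-specific spectrum (≥ 6 heavy atoms, ≥ 1 heteroatom, ≥ 4
  acyclic bonds). Rigid single-ring hydrocarbons yield only ring-arc
  fragments and alkanes only homologous series — peak sets that many
  isomers explain equally or more cheaply, making identification
  ill-posed for any bond-dissociation score. Such molecules stay in the
  library for fragmenter unit tests.
* **Matching uses a zero hydrogen-shift set**: the generator produces no
  rearranged ions, so ±1 shifts would only admit spurious decoy matches
  that the simulation never created. The package default remains
  {−1, 0, +1} for real spectra.
* **Reference counts** model the truth as an established compound: decoy
  counts are uniform in [1, 100] while the truth's count is a boost
  factor (default 5) above that range, mirroring the several-fold gap
  between reference standards and their obscure isomers observed in
  curated examples.

Passing this benchmark therefore shows that the pipeline is internally
consistent — the correct structure explains its own idealised spectrum
better than substantially different isomers, and orthogonal evidence
breaks residual near-ties. It does not show that real spectra, with
rearrangements, missing peaks and near-degenerate database isomers
(e.g. co-eluting butylazine isobars, keto-positional sugars), can be
identified at the same rate; on real data the fragmenter alone is known
to rank only a minority of compounds first, which is precisely why the
weighted combination exists.

## Numerical choices and degenerate inputs

* Monoisotopic masses come from an embedded principal-isotope table
  (proton 1.0072765 Da, electron mass folded into adduct offsets) so mass
  arithmetic is reproducible independent of toolkit version.
* Normalization guards all-zero term lists (scores stay 0). Empty
  spectra, empty candidate lists after filtering and empty suspect sets
  are warnings, not errors; disconnected structures are an error for the
  fragmenter and must be filtered first.
* OLS uses `numpy.polyfit` (degree 1); a singular design (all RTs equal)
  raises.
* The weight simplex is sampled by sorted uniform spacings (flat
  Dirichlet), seeded.
* Determinism: fragment output is sorted by atom/bond bitsets; dedup ties
  keep the lexicographically smallest path; result rows sort by
  (−score, identifier); all randomness flows from explicit integer seeds.

## Known limitations

* No rearrangement rules or neutral-loss heuristics: fragments arise from
  bond cleavage only, with hydrogen-shift matching as the sole
  rearrangement allowance.
* Singly charged ions only; no isotopologue handling inside MS/MS.
* The BDE table is a generic mean-enthalpy set, not compound-specific.
* Online database retrieval (PubChem/ChemSpider/KEGG) is declared in the
  parameter dialect but intentionally unimplemented; local CSV/SDF stand
  in.
* Tautomers may differ in InChIKey first block and then escape
  deduplication.
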