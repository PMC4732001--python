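# fragrank

Identification of small molecules from high-resolution tandem mass spectra
(MS/MS) by *in silico* fragmentation and weighted combination of evidence.

Non-target screening in metabolomics and environmental analysis constantly
produces accurate-mass MS/MS spectra of unknown compounds for which no
reference spectrum exists. Given such a spectrum, a candidate list retrieved
from a compound database by exact mass or molecular formula may hold dozens
to thousands of isomers. `fragrank` ranks those candidates by combining the
spectral evidence with orthogonal information — retention time, literature
and patent reference counts, substructure knowledge and suspect lists — so
that the measured compound ends up near the top of the list.

## Method

Each candidate structure *C* is fragmented combinatorially: starting from
the full molecular graph, bonds are removed one at a time up to a tree depth
(default 2). Acyclic cleavages split a fragment in two; ring cleavages yield
an open-ring intermediate for further cleavage. Fragments are stored as
bitsets of retained atom and bond indices with the cumulative bond
dissociation energy (BDE) of the cleaved bonds. Fragment ions (singly
charged, with the adduct of the precursor ion type and optional integer
hydrogen shifts) are matched to the measured peaks within an additive mass
window (m/z · ppm + Da). The fragmenter score is

S_Frag(C) = Σ_p RelMass_p^α · RelInt_p^β / (Σ_{b∈B_f} BDE_b)^γ

summed over matched peaks *p*, with α = 1.84, β = 0.59, γ = 0.47; when
several fragments fit a peak, the one with the lowest denominator is
assigned. Auxiliary terms include max-normalized combined reference counts,
binary suspect-list membership (matched on the first InChIKey block),
substructure inclusion/exclusion scores over SMARTS pattern hits, and a
retention-time score: a linear calibration log P = a·RT + b is fitted by
least squares to user-provided standards, and each candidate is scored with
the normal density (σ = 1.5) of its log P deviation from the prediction.
Every term is normalized to its maximum over the candidate list, and the
final score is the weighted sum

S_Final(C) = ω_Frag·S_Frag + ω_RT·S_RT + ω_Refs·S_Refs + … + ω_n·S_n.

Candidates are deduplicated per InChIKey first block (best-scoring
stereoisomer retained) and written sorted by final score. Ranking quality is
quantified by pessimistic and expected ranks and the relative ranking
position (RRP); a seeded sampler over the weight simplex supports weight
optimisation.

## Worked example

The package ships a synthetic-data module that emulates a complete
identification case without any database download: a truth compound
(here the herbicide terbutylazine, C9H16ClN5, neutral mass 229.1094 Da),
six formula-preserving structural decoys, a simulated [M+H]+ spectrum of
the truth, a retention-time calibration file and reference counts.

```python
from pathlib import Path
from fragrank import read_parameters, run_pipeline
from fragrank.synthetic import SimulationConfig, make_toy_library, write_fixture_files

out = Path("demo"); out.mkdir(exist_ok=True)
truth = {r.identifier: r for r in make_toy_library()}["terbutylazine"]
cfg = SimulationConfig(seed=20, mz_jitter_sd=0.0, n_noise_peaks=0)
paths = write_fixture_files(out, truth, cfg, n_decoys=6)

(out / "params.txt").write_text(f"""\
PeakListPath = {paths['peaks']}
DatabaseType = LocalCSV
LocalDatabasePath = {paths['candidates']}
NeutralPrecursorMass = {truth.monoisotopic_mass:.4f}
PrecursorIonType = [M+H]+
ScoreTypes = FragmenterScore,RetentionTimeScore,CombinedReferenceScore
ScoreWeights = 0.5,0.2,0.3
ReferenceSources = ChemSpiderReferenceCount
RetentionTimeTrainingFile = {paths['rt_training']}
ExperimentalRetentionTime = 8.0
UserLogPColumn = UserLogP
""")

ranked, report = run_pipeline(read_parameters(out / "params.txt"))
for c in ranked[:4]:
    print(f"{c.identifier:24s} "
          f"frag={c.normalized_terms['FragmenterScore']:.3f} "
          f"rt={c.normalized_terms['RetentionTimeScore']:.3f} "
          f"refs={c.normalized_terms['CombinedReferenceScore']:.3f} "
          f"final={c.final_score:.3f}")
```

prints

```
terbutylazine            frag=1.000 rt=1.000 refs=1.000 final=1.000
terbutylazine-decoy-6    frag=0.732 rt=0.537 refs=0.686 final=0.679
terbutylazine-decoy-2    frag=0.641 rt=0.771 refs=0.562 final=0.643
terbutylazine-decoy-1    frag=0.472 rt=0.968 refs=0.219 final=0.496
```

The truth attains the maximum of every normalized term — it explains all
simulated peaks with its own fragments, its reference count is highest, and
its log P sits closest to the retention-time prediction — so its final
score under the weights (0.5, 0.2, 0.3) is 1.000 and it ranks first. The
same run is available from the shell as `fragrank run demo/params.txt`,
and `fragrank rescore` re-ranks an exported result table with externally
computed score columns (e.g. vendor log D predictions) without
re-fragmenting.

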