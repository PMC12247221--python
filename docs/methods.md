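# Methods

This note records the models, procedures and numerical choices behind
`specsim`, in the order data flows through the pipeline.

## Structure standardization and similarity

Chemical identity is the *planar 2-D structure*. A raw SMILES is
standardized in a fixed order:

1. **Largest covalently bonded fragment** (salt/counter-ion removal). Ties
   are broken by heavy-atom count, then by lexicographically smallest
   canonical SMILES, so the choice is deterministic.
2. **Charge neutralization** (RDKit `Uncharger`). Permanent ions that
   cannot be neutralized (e.g. quaternary ammonium) are kept charged and
   flagged via `Structure.residual_charge` rather than dropped.
3. **Stereochemistry removal.**
4. **Canonical tautomer selection** (RDKit `TautomerEnumerator`), standing
   in for "most energetically stable": the enumerator's scoring function is
   a deterministic, widely used proxy. Tautomer canonicalization differs
   across RDKit versions, so the toolkit version in the environment pins
   the behavior; regenerate cached structure tables after upgrading RDKit.

Neutralization is applied *before* tautomer canonicalization. The reverse
order is defensible too; this order was fixed once because the tautomer
scorer assumes a neutral molecule more often than not, and it is applied
uniformly everywhere.

Structure identity everywhere downstream is `inchikey14`, the first
(connectivity) block of the InChIKey — two structures differing only in
stereochemistry or protonation collapse to one identity, by design.

Fingerprints are 2048-bit RDKit path (Daylight-like) fingerprints with
toolkit-default path parameters (minPath 1, maxPath 7). Tanimoto similarity
of two all-zero fingerprints is undefined and raises rather than returning
a conventional value; an empty fingerprint upstream means a degenerate
molecule that should have been caught earlier.

## Spectrum I/O and harmonization

MGF has no single standard, so the written dialect is fixed: `TITLE`
(spectrum id), `PEPMASS`, and optional `ADDUCT`, `COLLISION_ENERGY`,
`IONMODE` key–value headers; peaks at 6 decimal places. Because the writer
is deterministic, write→read→write is byte-stable, which makes split and
pipeline reruns diffable. Richer metadata travels in a companion CSV keyed
by spectrum id (CSV values override MGF headers on attach), or in a
combined one-record-per-spectrum JSON.

**Adducts.** A curated table of the common positive-mode adducts maps raw
spellings to canonical forms and each canonical form to exactly one
(mass offset, charge) pair. Unknown spellings map to *missing*, never to a
guess. The table is a shipped, user-editable YAML file.

**Collision energy.** An ordered rule list (also shipped YAML) extracts eV
values from free-text compound-name/instrument fields
(`CollisionEnergy:35`, `40 eV`, `CE: 12.5`). The first matching rule wins.
Normalized collision energy (percent, NCE) is *not* converted: it depends
on precursor m/z and charge, so such annotations yield missing. Public
libraries do not publish their full annotation conventions; the shipped
rules are a reconstruction and deliberately extensible.

**Instrument propagation.** Free-text instrument annotations are tokenized
(lowercase, split on non-alphanumerics) and looked up in per-category token
tables (ionization, mass analyzer, dissociation, manufacturer); model names
imply manufacturers (Q-Exactive → Orbitrap + Thermo). If two tokens
disagree within one category the whole annotation is ambiguous and all four
fields are left missing — hybrid-instrument strings (e.g. "LTQ Orbitrap")
intentionally fall into this case rather than being half-guessed. Explicit
provenance values override anything derived.

## Quality filters

Selection order is fixed: library exclusion → missing structure → ion mode
→ precursor ≤ 1500 Da → precursor validation → peak preprocessing →
significant fragmentation. The kept set would be the same under any order
of these per-spectrum rules; the per-rule drop attribution would not, which
is why the order is part of the contract and the report satisfies
`kept + Σdrops = input`.

* **Precursor validation**: theoretical m/z = (monoisotopic mass + adduct
  offset) / |charge|; ppm error uses the theoretical value in the
  denominator; keep iff ≤ 50 ppm. Spectra with a missing/unknown adduct or
  structure are unverifiable and rejected.
* **Peak preprocessing**: "rescaling intensities" is realized as base-peak
  normalization (max = 1.0); then peaks with relative intensity strictly
  below 0.1 % are removed (a peak exactly at the threshold is kept); then
  peaks outside the inclusive [10, 2000] m/z window. Rescaling precedes
  both filters. The operation is idempotent whenever the base peak lies
  inside the m/z window (the overwhelmingly common case); if the base peak
  itself is out of range a second pass renormalizes.
* **Significant fragmentation**: strictly more than 4 peaks with relative
  intensity strictly above 2 % — exactly 4 fails.

## Three-phase split

Train–test similarity of a structure is its maximum Tanimoto similarity to
any training structure (0.0 for an empty training set); for a test pair it
is the mean of the two structures' values.

1. **Dissimilar seeding.** Every structure is binned by its maximum
   similarity to any *other* structure into `n_tt_bins` evenly spaced bins
   on [0.4, 1.0]; up to `data_points_per_bin` per bin are drawn uniformly.
   Structures whose maximum similarity falls below 0.4 are pooled into one
   underflow bin so the most isolated structures stay eligible — without
   it, the structures that motivate the whole exercise could never be
   seeded.
2. **Random-walk densification.** A graph joins structures with similarity
   strictly above 0.7; roots are drawn without replacement among nodes of
   degree strictly greater than 3 (i.e. ≥ 4); each root contributes itself
   plus all nodes visited on a 4-step uniform random walk. Walks may
   revisit nodes; the returned set is deduplicated. If fewer roots are
   eligible than requested, all eligible roots are used and a warning is
   logged.
3. **Erosion balancing.** Test structures are binned by train–test
   similarity. Starting at the lowest underfilled bin, the deficit is drawn
   from the next non-empty bin above (continuing to higher bins when the
   next one is too small); for each drawn structure every training
   structure with similarity strictly above the underfilled bin's upper
   bound is removed, which pushes the drawn structure's train–test
   similarity to at most that bound. The loop stops when every bin is full
   or when the number of removed training structures reaches
   `max_train_erosion` (default 0.8) of the original training pool; a move
   whose removals would cross the cap is truncated at the cap and not
   recorded as completed. Completed moves are recorded in
   `SplitResult.moves` as (structure, bound) pairs so the post-condition —
   recomputed train–test similarity ≤ bound — is auditable after the fact.
   Erosion only ever shrinks the training set, so no test structure's
   train–test similarity ever increases during balancing.

The validation set is drawn uniformly from the surviving training pool at
the end (only its size is prescribed by the protocol). All three phases
derive their randomness from one seed (phases use seed, seed+1, seed+2), so
a split is reproducible byte-for-byte through its JSON serialization.

**Bin-count note.** The balancing loop defaults to 12 bins of width 0.05 on
[0.4, 1.0] to match the audit grid below; the loop's `n_tt_bins` is
configurable (some descriptions of this family of protocols use 13 bins
over the same interval, which the config accommodates).

**Coverage grid.** Ordered test pairs are binned over 10 pairwise-similarity
bins ([0, 1], width 0.1) × 12 train–test-similarity bins ([0.4, 1.0], width
0.05). Bins are left-inclusive; the top bin of each axis also includes the
right edge, so similarity exactly 1.0 is counted. Pairs with mean
train–test similarity below 0.4 stay in the split but fall outside the
grid. A cell is *covered* at ≥ 200 ordered pairs (100 unique pairs);
coverage is the fraction of the 120 cells covered. The region of interest —
train–test similarity in (0.55, 0.85), pairwise similarity > 0.5, 30 cells —
is reported separately because it captures structurally related molecules
distant from training, the regime analog search and molecular networking
care about.

## Pair datasets and epoch sampling

*All-Pairs* is the exhaustive enumeration of ordered pairs of distinct
spectra: exactly n·(n−1) records. Self-pairs (same spectrum id) are always
excluded; distinct spectra of the same structure are allowed and pair with
target 1.0. *Filtered* pairs additionally require the same ionization
method, mass analyzer and adduct, collision-energy difference strictly
below 5 eV *when both energies are annotated* (strict mode instead rejects
pairs with a missing energy), and precursor mass difference strictly below
200 Da. A required field that is missing on either side fails its criterion
— the match cannot be verified — except collision energy, whose skip rule
is explicit. By construction strict ⊆ filtered ⊆ all-pairs.

Epoch sampling first covers every training structure (one uniformly drawn
pair containing each inchikey14), then draws similarity bins equiprobably
among non-empty bins and samples one pair per drawn bin until
`pairs_per_epoch`. Within an epoch, within-bin selection is uniform without
replacement (a shuffled queue per bin, reshuffled if exhausted); across
epochs, with replacement. Two bin schemes:

* `uniform10`: ten equal-width bins on [0, 1].
* `biased20`: twenty bins with edges `e_i = (i/20)^0.3`.

The edge transform direction matters: with `e_i = (i/n)^0.3` the 10th edge
is `0.5^0.3 ≈ 0.812`, and since bins are drawn equiprobably, half of all
drawn pairs land above it. (Under the uniform 10-bin scheme and a
within-bin-uniform similarity distribution, the fraction above 0.81 is
0.1·1 + 0.1·0.9 = 19 %.) The inverse transform would instead concentrate
bins at *low* similarity, contradicting the 50 %-above-0.81 target, which
is how the direction was fixed. The known distortion of the scheme — broad
low-end bins under-sampling the top of their own range on right-skewed
data — is accepted as a property of the method, not corrected.

Epochs are written to HDF5 (keys `epoch_0000`, …, columns: spectrum id
pair, inchikey14 pair, target similarity); test pairs to Parquet with
train–test similarity attached.

## Metrics

All metrics consume a prediction table (query spectrum, candidate spectrum,
predicted score, true Tanimoto, structure keys, mean train–test
similarity); they are pure functions, and a helper aggregates mean ± sd
across tables from multiple model seeds.

* **Binned RMSE**: 10 equal-width ground-truth-similarity bins,
  left-inclusive, top bin closed; empty bins are reported missing and
  excluded from the *bin-averaged* RMSE (the unweighted mean of per-bin
  values over a range, e.g. bins above 0.6), which prevents the huge
  low-similarity population from drowning out the regime of interest.
* **Top Candidate Similarity** at k: per query, sort candidates by
  predicted score (ties broken by candidate id so results are
  reproducible), take the maximum true similarity among the first k,
  average over queries. Non-decreasing in k. Queries with fewer candidates
  than k use all available and are flagged.
* **Theoretical maximum**: the default (`best`) mode is the mean over
  queries of the maximum true similarity among eligible candidates — the
  bound a perfect ranker attains at every k, constant in k. A second
  (`kth`) mode reports the mean of the k-th highest true similarity, a
  per-rank variant. Both are exposed because the two readings answer
  different questions ("what could any ranker achieve" vs "how deep does
  the candidate pool stay good"); the default is the one used as an upper
  bound in plots.
* **Top-Rank** at k: ground-truth candidates are dense-ranked per query
  with ties grouped at the structure level (all candidates sharing a true
  similarity value share one rank, the next value takes rank j+1). The
  true top-k set is every candidate with ground-truth rank ≤ k; the metric
  is the minimum predicted rank within that set, averaged over queries
  (e.g. true top-3 at predicted ranks [21, 42, 13] → 13). Non-increasing
  in k. Queries whose candidates are all removed by the identical-structure
  exclusion are skipped and counted.
* **Identical-structure exclusion** uses inchikey14 (planar identity), so
  stereoisomers of the query count as identical.
* **Train–test stratification** partitions rows by mean train–test
  similarity into 0.05-wide bins on [0.4, 1.0] and applies any metric per
  bin.

## Modified cosine baseline

Defaults: fragment tolerance 0.10 Th (inclusive comparison), m/z power 0.0,
intensity power 0.50 applied to base-peak-normalized intensities
(normalization cancels in the cosine ratio, so this matches
raw-intensity implementations). Peak i of A may match peak j of B directly
or shifted by the precursor mass difference. Among candidate matches a
one-to-one assignment is chosen greedily by descending weight product
(ties broken by peak indices); the score is the assigned product sum over
the product of weight norms. Greedy assignment mirrors the common reference
implementations and is a known point of inter-implementation variation; an
exact maximum-weight assignment mode (`exact=True`, via
`scipy.optimize.linear_sum_assignment` restricted to candidate matches) is
provided for cross-checks, and the greedy score is never above it. The
score is symmetric (the shifted condition mirrors under Δ → −Δ) and equals
plain cosine when Δ = 0.

## Synthetic fixtures

The generator's purpose is statistical realism, not chemical fidelity:

* **Structures**: up to 22 scaffold chemotypes (alkylbenzenes, phenols,
  pyridines, indoles, fatty acids, morpholines, …) each extended with a
  growing alkyl chain. Homologous series give high within-family path-
  fingerprint similarity and low between-family similarity; the default
  20 families × 15 members (300 structures) span the full Tanimoto range,
  with mean within-family minus between-family similarity ≈ 0.66. All
  generated structures are unique by inchikey14 and already standardized.
* **Spectra**: the on-bits of a coarse 256-bit path fingerprint map
  deterministically to (m/z, intensity) peaks (top 40 kept), so shared
  substructure ⇒ shared peaks and modified-cosine similarity correlates
  with Tanimoto (Spearman ≈ 0.9 at default noise; the regression floor
  asserted in tests is 0.3). Poisson noise peaks (default rate 3/spectrum)
  and lognormal intensity jitter (default sd 0.1) degrade the correlation
  monotonically. Precursor m/z is exact for the drawn adduct
  ([M+H]+ 70 % / [M+Na]+ 20 % / [M+NH4]+ 10 %).
* **Metadata**: collision energy is missing with probability 0.7072 — the
  realistic missingness rate for public test libraries — and otherwise
  drawn from {10, 20, 35, 55} eV; instrument profiles alternate between an
  ESI/Orbitrap/HCD/Thermo and an ESI/TOF/CID/Bruker configuration.
* **Planted defects**: defective copies appended at known counts (default
  3 each) — 120 ppm precursor error, 3-peak sparse spectra, excluded
  library tag, 1600 Da precursor, missing structure — each failing exactly
  one selection rule, so the rejection report can be checked exactly.

What passing tests on this fixture do *not* show: robustness to real
fragmentation chemistry (rearrangements, neutral losses unrelated to shared
substructure), centroiding artifacts, isotope clusters, chimeric spectra,
negative mode, or adducts outside the shipped table.

## Problem sizes and determinism

The shipped tests run the split contract at ~300 structures, filter
conservation at ~200 spectra, sampler analytics at 10⁵ draws (tolerance
±0.02 against the analytic values 0.50 and 0.19), and oracle equivalences
at ≤ 10 queries × 50 candidates and ≤ 6-peak spectra — sizes at which every
guarantee is checked exhaustively or against brute force while the suite
stays fast. All randomness flows from explicit seeds (`numpy` Generators);
reruns of any stage with the same config are identical, byte-for-byte where
serialization is involved.

## Known limitations

* The shipped collision-energy and instrument rule tables are best-effort
  reconstructions of undocumented library conventions; real deployments
  should extend the YAML files.
* Negative ion mode passes through harmonization untouched; the adduct
  table is positive-mode.
* `phase3_balance_by_erosion` recomputes the train–test similarity vector
  each iteration (O(|test|·|train|) per move); fine up to a few thousand
  structures, not tuned beyond that.
* Greedy modified cosine can differ from exact assignment on adversarial
  peak layouts; shipped tests show equality on small random spectra, not a
  general guarantee.
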