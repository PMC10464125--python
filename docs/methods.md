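# Methods

## Problem and model

Gut microbiome studies establish two kinds of curated associations that do
not share a taxonomic level. Differential-abundance surveys (16S,
metagenomics) resolve microbes reliably only to **genus**, so
disease–microbe links are directed genus-level records: a genus is
*increased* or *decreased* in a disease relative to healthy controls.
Metabolic reconstructions and culture studies record which metabolites a
specific **strain** (or species) produces; these links are presence-only.

`metabolink` infers disease–metabolite associations by composing the two
tables through the taxonomy:

1. **Harmonize.** Exact duplicates on the association key are collapsed
   (first occurrence's evidence kept). Every disease–microbe pair recorded
   with *both* directions is removed entirely — both records, not a
   majority vote: the curation sources carry no vote weights, so dropping
   the pair is the only defensible rule, and the removed pairs are listed
   in the report so the choice is auditable. Production links cannot
   contradict (no direction), so they are only deduplicated.
2. **Propagate.** If a genus is increased (decreased) in a disease, every
   strain of that genus is assumed increased (decreased). Strain
   membership is decided by the genus-rank ancestor in the lineage, so
   species- and subspecies-rank taxa count as strain-level members.
3. **Count.** For each disease, `M` and `N` are the numbers of increased
   and decreased strains; for each (disease, metabolite), `m` and `n` are
   the producers among them.
4. **Score.** `S_as = m/M − n/N`, `S_ac = (m+n)·|S_as|`; meaningful iff
   `|S_as| > 0.05` and `S_ac > 1`, strictly. Positive scores are
   marker-like, negative drug-like.
5. **Validate.** Predicted signs are compared with experimentally observed
   up/down changes; the consistency fraction is computed over labeled
   pairs that are scored *and* meaningful.

## The strain universe

`M`, `N`, `m`, `n` are all counted over the *strain universe*: the
distinct taxids present in the harmonized production table. Strains known
to the taxonomy but absent from the production table cannot contribute
producers, and counting them in `M`/`N` would make the denominators depend
on how complete the taxonomy dump happens to be. Restricting to the
universe makes every count reproducible from the input tables alone. The
counts are over strains, not genera: the score is defined by counting
producing *strains*, and `m`/`n` are strain-level by construction, so a
genus-level `M`/`N` would mix levels.

Consequence worth knowing: a disease genus whose strains produce nothing
contributes nothing to `M`/`N`. Fixtures that want a panel of a given size
must give every panel strain at least one production link, as real
production tables do by construction.

## Numerical and procedural choices

- **Zero denominators.** `M = 0` or `N = 0` makes the corresponding ratio
  0. Diseases with single-direction microbe sets then score exactly ±1,
  which is the intended degenerate behaviour, and the formula is total.
- **Suppressed pairs.** Pairs with `m + n = 0` are not emitted: their
  `S_ac` is 0, they can never pass the strict thresholds, and emitting
  them would grow output as diseases × metabolites.
- **Ranking.** Within a disease, output is sorted by ascending `S_as`
  (most drug-like first), ties by descending `S_ac`, then ascending
  metabolite id. The tie-breaks are a determinism choice so "k-th
  strongest" is well defined.
- **Printing.** `S_as` renders to 3 decimals, `S_ac` to 2, consistency
  percentages to 1, all rounding half away from zero (3.125 → "3.13");
  Python's native banker's rounding would disagree on exact halves.
  Negative zero is normalized to "0.000". Writers can append
  full-precision columns, and the reader prefers them when present.
- **Zero scores in validation.** `S_as = 0` counts as inconsistent with
  either observed direction; direction agreement is sign agreement only.
- **Error posture.** Unknown direction tokens and malformed identifiers
  are row-level errors with line numbers, never silent skips. Unresolvable
  taxids during propagation are collected into a skip report rather than
  aborting, since curation tables routinely contain retired taxids. A
  lineage with orphan parents, duplicate taxids, more than one self-parent
  node, or a parent cycle is rejected at construction.
- **Non-genus disease taxids.** A disease–microbe record at species rank
  is mapped to its genus-rank ancestor with a warning (and to its own
  subtree if no genus ancestor exists); mixed-rank curation input should
  not silently lose records.

## Synthetic data generator

The generator emulates the structure the method assumes: a three-level
taxonomy (root → genera → strains; deeper lineages add nothing because
only genus ancestry is consulted), Bernoulli disease–genus associations
with configurable direction frequency, Bernoulli background production
links, and *planted* signal metabolites produced exclusively by all
strains of one direction of a designated disease — so a planted drug-like
metabolite attains the minimum possible score `S_as = −n/N` for that
disease, and recovery has a closed-form expectation. Validation labels
derive from the planted ground truth, optionally flipped with probability
`label_noise`.

Defaults describe a moderate desk-scale instance: 5 diseases, 10 genera of
3 strains, 50 metabolites, association density 0.4, balanced directions
(`p_increase = 0.5`), background production density 0.1, two planted
metabolites of each kind, noise-free labels. These sizes keep the full
test suite and the property checks (oracle equivalence over 100 random
instances, 1000 random count quadruples) in the seconds range while
leaving every disease a non-trivial panel.

What the generator does *not* emulate: real marginal distributions of
association counts, correlated production profiles within genera,
abundance magnitudes (directions are binary), retired/renamed taxids, and
the long-tailed metabolite frequencies of real reconstructions. Passing
tests therefore show algorithmic correctness and calibration on the
planted structure, not performance on any real corpus.

Randomness is a single seed expanded via `numpy.random.SeedSequence.spawn`
into per-table streams, so changing, say, the metabolite count never
perturbs the taxonomy draw; identical configs produce byte-identical
bundles.

## Known limitations

- The genus→strain assumption is deliberately coarse: strain-level
  heterogeneity within a genus is invisible to the method.
- Scores have no probabilistic calibration; `S_ac` is an evidence-count
  weight, not a p-value.
- Contradiction removal discards information when sources genuinely
  disagree; the report lists the dropped pairs so users can arbitrate
  upstream if they wish.
- Validation requires a single observed direction per (disease,
  metabolite) pair; context-dependent experimental changes must be
  resolved before input.
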