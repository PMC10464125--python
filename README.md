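# metabolink

Quantitative inference of disease–metabolite associations from curated gut
microbiome tables.

Microbiome surveys report which microbial **genera** are increased or
decreased in a disease; metabolic reconstructions report which metabolites
individual **strains** produce. `metabolink` connects the two: it
harmonizes the curated tables, propagates genus-level directions to the
strain level through a taxonomy lineage, and scores every
(disease, metabolite) pair.

## The scores

For a disease with `M` increased and `N` decreased strains (after
genus→strain propagation), and a metabolite produced by `m` of the
increased and `n` of the decreased strains:

```
S_as = m/M − n/N              (association strength, in [−1, 1])
S_ac = (m + n) · |S_as|       (confidence)
```

A ratio with a zero denominator contributes 0, so diseases whose microbes
all move in one direction still score (their pairs come out exactly ±1).
A pair is **meaningful** when `|S_as| > 0.05` and `S_ac > 1` (both strict).
A strongly positive `S_as` marks the metabolite as a potential disease
marker (it is made by disease-enriched microbes); a strongly negative
`S_as` marks it as a candidate drug or diagnostic marker (made by
disease-depleted microbes). Predicted signs can be checked against
experimentally observed metabolite changes (up/down in disease) and
summarized as a direction-consistency fraction.

## Worked example

Suppose a disease panel has 7 increased and 8 decreased strains, and a
metabolite is produced by 0 of the increased and 5 of the decreased
strains:

```python
>>> from metabolink import CountQuad, association_strength, confidence
>>> q = CountQuad(m=0, n=5, M=7, N=8)
>>> association_strength(q)
-0.625
>>> confidence(q)
3.125
```

`S_as = 0/7 − 5/8 = −0.625`: the metabolite is made almost exclusively by
microbes depleted in the disease, so it is a drug-like candidate. The
confidence `S_ac = 5 · 0.625 = 3.125` (printed as `3.13`; tables render
`S_as` to 3 decimals and `S_ac` to 2, rounding half away from zero) is
well above the threshold of 1, so the pair is meaningful.

The same computation end-to-end from the shell, on a seeded synthetic
bundle with planted signal metabolites:

```sh
metabolink simulate --seed 1 --out-dir demo
metabolink score --disease-microbe demo/disease_microbe.tsv \
    --microbe-metabolite demo/microbe_metabolite.tsv \
    --lineage demo/lineage.tsv \
    --out demo/scored.tsv --summary-out demo/summary.tsv
metabolink validate --scored demo/scored.tsv --labels demo/validation.tsv \
    --out demo/report.tsv
```

which prints (`head -3 demo/scored.tsv` and the validation summary):

```
disease_id  metabolite_id  m  n  M  N  s_as    s_ac  meaningful  label
D000001     47             0  6  9  6  -1.000  6.00  true        drug_like
D000001     50             3  6  9  6  -0.667  6.00  true        drug_like

experimental pairs:        4
scored and meaningful:     4
direction-consistent:      4
consistency:               100.0%
```

Metabolite 47 is one of the planted drug-like metabolites: it is produced
by all 6 decreased strains of disease D000001 and no increased strain, so
it attains the minimum possible score `S_as = −6/6 = −1` and ranks first.
The noise-free validation labels derived from the planted ground truth are
all sign-consistent, hence 100.0%.

Every subcommand writes a `run_manifest.json` (input digests, parameters,
row counts) next to its outputs so chained runs are auditable.

## Layout

- `src/metabolink/model.py` — domain types, identifier validation
- `src/metabolink/io.py` — canonical TSV readers/writers
- `src/metabolink/taxonomy.py` — lineage index (simple TSV and NCBI taxdump)
- `src/metabolink/harmonize.py` — deduplication, contradiction removal
- `src/metabolink/propagate.py` — genus→strain propagation
- `src/metabolink/scoring.py` — S_as / S_ac, filtering, ranking, summaries
- `src/metabolink/validation.py` — direction-consistency validation
- `src/metabolink/synthetic.py` — seeded synthetic bundle generator
- `src/metabolink/cli.py` — `metabolink` console script

See `docs/methods.md` for the model, its assumptions, and design choices.
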