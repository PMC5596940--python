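# biodtm

Dynamic topic modelling of time-sliced biomedical abstracts with a
dictionary-restricted vocabulary.

The package turns a MEDLINE-format export of time-stamped abstracts into a
fitted dynamic topic model over discrete time slices and renders topic
evolution as top-word tables, topic-strength trajectories and a ThemeRiver
stacked-stream SVG. The model vocabulary is restricted to a biomedical
dictionary built from pluggable term-list files.

## Pipeline

1. **`biodtm.corpus_io`** — parse PubMed MEDLINE exports (PMID/TI/AB/DP
   tagged records), assign publication years to configurable time slices,
   and read/write the sparse LDA-C-style corpus triplet
   (`-mult.dat` / `-seq.dat` / `-vocab.dat`).
2. **`biodtm.biodict`** — build a stemmed-unigram dictionary from term-list
   files (one term per line); multi-word terms are split into unigrams,
   stop-filtered, Porter-stemmed and deduplicated across sources.
3. **`biodtm.preprocess`** — tokenize title+abstract, stem, keep only
   dictionary stems, then prune the vocabulary with a corpus-total frequency
   floor and a tf-idf quantile cut.
4. **`biodtm.dtm_core`** — fit the dynamic topic model: per-topic
   natural-parameter chains tied by a Gaussian random walk across slices
   (`phi[k][t] = softmax(b[k][t])`), inferred by variational EM — exact LDA
   mean-field E-step, MAP M-step on each chain via proximal gradient ascent
   with backtracking. The tracked bound is monotone.
5. **`biodtm.topic_analysis`** — per-slice and whole-period top words, and
   per-slice topic strengths (expected token share, columns sum to 1).
6. **`biodtm.themeriver`** — symmetric stacked-stream layout with monotone
   cubic interpolation between slice anchors, rendered to deterministic SVG.
7. **`biodtm.synthetic_data`** — ground-truth corpora from the exact
   generative process the model fits, emitted either as count matrices or as
   pseudo-MEDLINE text, so the full pipeline runs with no downloads.
8. **`biodtm.stemming`** — a self-contained implementation of the classic
   Porter algorithm (e.g. `apoptosis → apoptosi`, `memory → memori`).

## CLI

All commands live under one entry point:

```sh
# generate a synthetic fixture corpus (pseudo-MEDLINE + term list + truth)
biodtm simulate --out sim/ --seed 3 -k 3 --slices 5 --vocab 50 --docs-per-slice 40

# build the dictionary from term-list files
biodtm build-dict sim/terms.txt --out dict

# MEDLINE -> filtered corpus triplet (+ drop report)
biodtm preprocess --medline sim/medline.txt --dict dict.dict \
    --out corpus --config cfg.yaml

# fit the model, export tables/strengths, render the river
biodtm fit --corpus corpus --out model -k 20 --seed 1
biodtm topics --model model --corpus corpus --out tables -n 10
biodtm river --strengths tables-strengths.csv --out river.svg
```

A YAML config file can supply the slice scheme (`slices: [[1975, 1995], ...]`;
the default is the 16-slice scheme 1975–1995, 1996–2000, 2001–2003,
2004–2005, then yearly 2006–2017), pipeline filter settings (`pipeline:`) and
fit hyperparameters (`fit:`). Flags override file values. Every command is
deterministic under a fixed seed and writes a JSON manifest (version, seed,
config hash) next to its outputs. `biodtm river --year-axis` places slice
anchors proportionally to calendar years instead of uniformly.

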