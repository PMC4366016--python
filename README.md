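# ontosieve

Dictionary-based ontology concept recognition that adapts to the ontology it
is given. Before indexing, the toolkit (1) decides whether the ontology needs
case-sensitive processing from the distribution of case-sensitive token
shapes across its concepts, and (2) measures the information gain of every
label token via a divergence-from-randomness model combined with bigram
pointwise mutual information, generating alternative labels that omit
uninformative tokens (e.g. `adenine aminase activity` → `adenine aminase`).
Documents are then annotated by exact-boundary matching against a positional
concept-token vector space, and predictions are scored against gold standoff
annotations with exact-span P/R/F1.

## Layout

| Module | Role |
| --- | --- |
| `ontosieve.lexicon_io` | OBO / JSON lexicon parsing, normalization, entity profiles, corpus statistics |
| `ontosieve.case_sensitivity` | token shape rules, per-concept flags, the CSS statistic and its −1 threshold |
| `ontosieve.dfr_gain` | binomial divergence-from-randomness information gain per (profile, token) |
| `ontosieve.mutual_info` | bigram PMI, IQR independence interval, positional MI, balance scores |
| `ontosieve.variant_generation` | outlier detection and alternative-label generation |
| `ontosieve.index_retrieval` | positional vector space, candidate windows, exact-match scoring, annotation |
| `ontosieve.evaluation` | gold standoff TSV loading, micro-averaged exact P/R/F1 |
| `ontosieve.synthetic_fixtures` | seeded synthetic ontologies and corpora with planted structure |
| `ontosieve.pipeline` / `ontosieve.cli` | orchestration of the four experimental arms and the CLI |

## CLI

```bash
# generate a seeded fixture (OBO ontology + documents + gold TSV)
ontosieve fixtures make --seed 7 --out fx/

# case-sensitivity census
ontosieve css report fx/ontology.obo

# information gain and bigram MI tables
ontosieve gain table fx/ontology.obo
ontosieve mi stats fx/ontology.obo --n 0.5

# alternative labels (named per-ontology m/n/k presets)
ontosieve variants generate fx/ontology.obo --n 0.5
ontosieve variants generate fx/ontology.obo --preset craft-PRO

# index, annotate, evaluate
ontosieve index build fx/ontology.obo -o index.json --case auto --ig --n 0.5
ontosieve annotate index.json fx/doc*.txt -o pred.tsv
ontosieve eval pred.tsv fx/gold.tsv

# the four experimental arms (baseline / case / gain / both) in one report
ontosieve run --config run.yaml --arms
```

`run.yaml` takes the `RunConfig` fields, e.g.:

```yaml
lexicon: fx/ontology.obo
case_mode: auto        # auto | on | off
use_ig: true
m: 1.0
n: 0.5
k: 3.0
documents: [fx/doc000.txt, fx/doc001.txt]
gold: fx/gold.tsv
out_dir: out/
```

## Formats

* **Lexicons**: OBO 1.2/1.4 flat files (`[Term]` stanzas; all synonym scopes
  are included; obsolete terms are skipped) or JSON
  `{id: {"labels": [...], "synonyms": [...]}}`.
* **Gold / predicted annotations**: TSV `doc_id <TAB> start <TAB> end <TAB>
  concept_id` with 0-based half-open character offsets.
* **Index**: a documented JSON layout (`rows` + metadata), round-trippable
  via `ConceptTokenIndex.save` / `.load`.

Mentions with gaps are out of scope, and all exact matches are reported
(no longest-match-only suppression).
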