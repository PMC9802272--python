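# ibdtopics

Dictionary-based content analysis of social-media discourse about
inflammatory bowel disease (IBD) and psychological distress.

People with IBD (Crohn's disease, ulcerative colitis) use platforms such
as Reddit and Twitter to seek support, and the topics they raise when
expressing distress — symptom flares, medication, diet, surgery — point
to where support is most needed. `ibdtopics` implements the full lexical
pipeline such a study runs, as a tested, reusable package for
health-communication researchers and text-mining practitioners:

1. **Corpus ingest** — JSON Lines / CSV post records with platform
   metadata (subreddit, retweet flag, timestamps); round-trip safe.
2. **Cleaning filters** — case-insensitive disease-relevance keywords
   (`crohn`, `ibd`, `colitis`, …) with off-topic exclusion contexts
   (*Investor's Business Daily*, veterinary diagnoses), retweet removal,
   and same-user duplicate removal (earliest copy kept).
3. **Distress extraction** — a unigram + bigram distress lexicon
   ("afraid", "scared", "feel alone", "hard to manage"); a post is
   retained iff at least one entry fires.
4. **Topic classification** — eight non-mutually-exclusive topic
   dictionaries (*symptoms, medication, nutrition, procedures, marijuana,
   stigma, ostomy, intimacy*) plus per-topic **false-positive phrase
   dictionaries**: a match like "tired" (symptoms) inside "tired of
   explaining" is suppressed by span overlap, while genuine co-mentions
   elsewhere in the post survive.
5. **Validation tooling** — purposive stratified sampling (60
   classifier-positive + 60 classifier-negative posts per topic = 960),
   Krippendorff's nominal alpha (α = 1 − D_o/D_e from the coincidence
   matrix of pairable values), percent agreement, and discrepancy
   adjudication for human-vs-computer comparison.
6. **Co-occurrence network** — an undirected graph over the 8 topics with
   edge weight w(a,b) = #{posts mentioning both a and b}; node strength
   (weighted degree) ranks topic centrality; GraphML / DOT / edge-list
   exports.
7. **Descriptive reporting** — corpus characteristics, subreddit and
   hashtag rankings, topic prevalence, and single/multi-topic breakdowns
   with a half-up whole-percent convention ("<1%" for nonzero sub-half
   shares).
8. **Synthetic corpora** — a seeded generator that plants gold topic and
   distress labels in platform-realistic posts (280-character tweets,
   hashtags, hyperlinks, duplicates, retweets), so every stage is
   testable without redistributable platform data.

## Worked example

```sh
ibdtopics synth --seed 5 --n 500 --out corpus.jsonl
ibdtopics filter --in corpus.jsonl --out filtered.jsonl
ibdtopics classify --in filtered.jsonl --out assignments.jsonl
ibdtopics network --assignments assignments.jsonl --out-dir net/
```

The `network` command prints the topic centrality ranking, e.g.:

```
symptoms    122
medication  82
procedures  73
nutrition   72
marijuana   30
stigma      13
ostomy      8
intimacy    2
```

i.e. among posts mentioning ≥2 topics, *symptoms* co-occurs with other
topics 122 times — the hub of the distress discourse — while *intimacy*
is the least integrated topic. The same run writes `net/network.graphml`,
`net/network_edges.csv` (weight-sorted edge list) and an 8×8
co-occurrence matrix CSV.

The same pipeline is available in one shot from a YAML config
(`ibdtopics run --config pipeline.yaml`), which also writes a
`manifest.json` recording seeds, config hashes and per-stage filter
reports (retained + removed = input, per rule), and as plain library
calls (`ibdtopics.relevance_filter`, `ibdtopics.classify_corpus`, …).

Equivalent Python:

```python
import ibdtopics as it

corpus = it.generate(it.GeneratorConfig(seed=5, n_posts={"reddit": 500, "twitter": 500}))
corpus, _ = it.relevance_filter(corpus, it.default_relevance())
corpus, _ = it.remove_retweets(corpus)
corpus, _ = it.dedup_same_user(corpus)
corpus, _ = it.distress_filter(corpus, it.default_distress())
assignments = it.classify_corpus(corpus, it.default_topics(), it.default_false_positives())
print(it.gold_evaluation(assignments, corpus).micro_precision)  # 1.0 in strict mode
print(it.rank_centrality(it.build_network(assignments))[0])     # ('symptoms', ...)
```

## Lexicon configuration

The shipped lexicons are illustrative stand-ins assembled from the
vocabulary quoted in published IBD-distress content analyses; full
curated keyword lists drop in as YAML (see `ibdtopics.lexicons`):

```yaml
topics:
  symptoms:
    terms: [flare, pain, diarrhea, "flare up", "crohn*"]   # '*' = substring
    false_positives: ["tired of explaining"]
```
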