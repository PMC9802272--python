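# Methods

## The procedure

`ibdtopics` operationalizes a dictionary-based content analysis of
social-media discourse about inflammatory bowel disease (IBD) and
distress. The unit of analysis is a single post (a Reddit submission or
comment, or a tweet). The pipeline is purely lexical: every stage reduces
to matching curated term/phrase sets against a normalized view of the
post text, so the method is transparent, deterministic and auditable —
at the cost of missing distress expressed only in subtext, a limitation
inherent to the approach rather than to this implementation.

Stages, in execution order:

1. **Normalization.** Text is lower-cased; URLs collapse to a sentinel
   token; within-word apostrophes are stripped ("Crohn's" → "crohns");
   tokens are maximal alphanumeric runs, each retaining its character
   span in the raw text. All downstream matching shares this view, which
   makes every rule case-insensitive by construction.
2. **Relevance.** A post is study-relevant iff its normalized text
   contains at least one IBD keyword and no exclusion-context phrase.
   Keywords match as *substrings* of the joined token text so that
   "crohn" catches "crohns" and hashtag compounds ("#crohnsdisease");
   exclusion contexts ("my dog has", "investors business daily") are
   normalized phrase matches and remove non-human or finance senses of
   the keywords.
3. **Cleaning.** Retweets are removed (metadata flag first, the "RT @"
   text prefix as a fallback; reddit posts are never touched). Same-user
   duplicates — identical author and identical normalized text — keep the
   earliest copy by timestamp, falling back to corpus order; identical
   text from different authors, and posts with empty authors, are never
   merged.
4. **Distress extraction.** A post survives iff at least one distress
   unigram matches as an exact token, or a distress phrase matches as
   consecutive tokens. Exact-token matching for unigrams prevents
   "scared" firing inside unrelated compounds; phrase adjacency reads
   bigrams strictly (no gaps).
5. **Topic classification.** Eight non-mutually-exclusive topic
   dictionaries (symptoms, medication, nutrition, procedures, marijuana,
   stigma, ostomy, intimacy). Single-word terms match exact tokens by
   default, with a per-entry `*` suffix enabling substring mode;
   multi-word terms match consecutive tokens. A second, per-topic
   **false-positive dictionary** then eliminates spurious hits.
6. **Validation support.** Stratified purposive sampling, Krippendorff's
   alpha, percent agreement, adjudication (below).
7. **Network and reporting.** Post-level topic co-occurrence network and
   descriptive summary tables.

## False-positive elimination

The motivating failure mode: "tired" belongs to the symptoms dictionary,
but "I'm tired of explaining my disease" is not a symptom mention. Two
semantics are implemented because the underlying design is genuinely
ambiguous:

- `overlap` (default): a topic match is discarded only when its character
  span overlaps a false-positive phrase occurrence for that topic. A post
  containing both "tired of explaining" and "diarrhea" keeps its
  symptoms label via the surviving span. This preserves genuine
  co-mentions and is the default for that reason.
- `veto`: any false-positive occurrence drops the whole topic for the
  post — the more aggressive reading.
- `off`: no elimination (used to quantify what the second dictionary
  buys; see the trap experiment below).

False-positive phrases are scoped strictly to their own topic key: an
intimacy FP phrase can never suppress a symptoms match even when the
spans coincide.

## Krippendorff's alpha

Reliability of binary topic codes is measured with Krippendorff's alpha
at the nominal level, the only level meaningful for present/absent codes:
α = 1 − D_o/D_e, computed from the coincidence matrix of pairable values.
Each unit with m ≥ 2 non-missing labels contributes each ordered pair of
its values with weight 1/(m−1); D_o is the off-diagonal mass, D_e is
derived from category marginals with the n−1 correction. This
formulation handles missing labels and any number of coders, and admits
a "computer" coder column, which is how the human-vs-computer comparison
is assembled: two human coders are reduced to one consensus column by
adjudication (concordant units keep the shared label, discordant units
take an explicit resolution), then paired with the classifier's output.

Degenerate case: when every pairable value falls in one category,
D_e = 0 and alpha is undefined; the package returns `None` with a
warning rather than 1.0, to avoid overstating reliability on
single-category strata. Per-topic reliability across the 8 topics is
summarized by the mean and range of the defined alphas.

Percent agreement is provided only for the complete two-coder case and
is reported alongside alpha, never instead of it.

The test suite and the acceptance script verify the implementation
against an independent brute-force oracle that enumerates every ordered
pair of pairable values directly; agreement is required to 1e-12 on
hundreds of random small matrices including missing data.

## Validation sampling

The purposive design draws, for each topic, `n_pos` classifier-positive
and `n_neg` classifier-negative posts (default 60 + 60 across 8 topics =
960 stratum draws), without replacement within each stratum, from a
seeded generator. A post drawn for several strata appears once in the
aggregated unit list but remains in every stratum ledger. Strata smaller
than the plan raise an error naming the topic and stratum; with rare
topics (intimacy at ~2% prevalence) the classified pool must be large
before every 60-positive stratum is feasible, which is why the
acceptance script classifies 12 000 posts per platform for this step.

## Co-occurrence network

Only posts with ≥ 2 assigned topics contribute; a post with k topics
increments each of its C(k,2) unordered topic pairs once, regardless of
how many term matches support each topic. Two conservation laws follow
and are property-tested: Σ edge weights = Σ_p C(k_p, 2), and node
strength equals both the incident-edge sum and direct per-post counting.

Published sociograms of this kind size nodes by "in-degree centrality",
terminology that cannot apply literally to an undirected co-occurrence
graph; the package reads it as weighted degree (node strength) and
offers plain degree behind a flag. Centrality ranking breaks ties
lexicographically. Exports: GraphML (round-trip safe), weight-sorted
edge-list CSV, an 8×8 co-occurrence matrix CSV, and a minimal DOT
rendering with node size proportional to strength — publication-quality
layout is out of scope.

## Reporting conventions

- Percentages: round half-up to a whole percent; a nonzero share that
  rounds to 0 renders "<1%". This convention reproduces every per-topic
  percentage of the reference prevalence tables from their printed
  integer numerators and denominators (verified by a unit-test sweep).
- Single/multi-topic shares (exactly 1 / exactly 2 / 3+) are reported
  among posts with at least one topic.
- Means and SDs to two decimals; SD is sample (n−1) by default,
  population SD behind a config switch.
- Unique users count post authors only, not users mentioned in text.
- Hyperlink totals count occurrences; "posts containing hyperlinks"
  counts posts with ≥ 1. Hashtags are normalized by lowercasing and
  stripping non-alphanumerics; totals keep duplicates, unique counts do
  not.

Two printed-number inconsistencies in the reference tables are
documented rather than reproduced: the Reddit mean posts/user (printed
2.12, but 40 625/18 891 = 2.15 under any rounding), and the Reddit "3+
topics" share (printed 22%, but 7350/32 189 = 22.83% rounds to 23%
under the convention that reproduces every other entry). Tests assert
our convention's values and flag the discrepancy in their docstrings.

## Synthetic corpus generator

The generator emulates exactly the features the lexical pipeline reacts
to, and nothing else — no grammar, no discourse structure, no real user
networks. Passing tests on synthetic corpora therefore demonstrate the
*mechanics* of the pipeline (matching, elimination, accounting,
sampling), not classifier performance on real language, where curated
lexicons face polysemy and ellipsis the generator does not model.

Per-post construction: an IBD keyword phrase (so the post survives
relevance filtering), one signal term per gold topic, a distress marker
iff the gold distress flag is set, an optional false-positive trap
phrase inserted *independently* of gold labels, background filler, and —
platform-specific — hashtags, hyperlinks, and a 280-character budget for
tweets that trims filler but never planted signals (infeasible required
content raises an error). Same-user duplicates and retweets are injected
on top of the `n_posts` originals; every post carries a `synthetic_role`
tag so tests can isolate subsets. All randomness flows from one
`numpy` generator seeded by `seed`; identical configs give byte-identical
corpora.

Gold-label models:

- `independent`: each topic is an independent Bernoulli draw at its
  configured prevalence. Used whenever an exact binomial reference
  distribution is wanted for recovered prevalence.
- `mixture` (default): the per-post topic count is drawn from the
  configured mixing distribution (truncated geometric on {0..4} with
  ratio 1/2 by default), then that many distinct topics are drawn
  successively without replacement with probability proportional to the
  prevalence weights. `implied_prevalence` computes the exact marginal
  inclusion probabilities by enumerating the draw sequences, so the
  mixture model is testable to the same standard.

Vocabulary modes: `strict` (default) enforces pairwise-disjoint
per-topic signal vocabularies, disjoint from filler and distress
markers, which makes exact recovery (precision = recall = 1.0) a
theorem about the construction and hence a meaningful regression test;
`confusable` plants a shared ambiguous term ("gut", a symptoms
dictionary entry) in posts of any topic to exercise precision < 1 paths.
The trap inventory pairs each topic with a phrase that embeds one of its
dictionary's ambiguous terms in a non-topical sense ("tired of
explaining", "war on drugs", "diet coke", "plastic surgery", "pot of
coffee", "what a shame", "shopping bag", "expiration date"); with
elimination off these produce a measurable false-positive rate, with
elimination on the rate returns to zero — the experiment that motivates
the second dictionary.

### Default rates

| parameter | default | basis |
|---|---|---|
| topic prevalences | .57/.30/.27/.17/.08/.04/.03/.02 | long-form-platform topic profile of the reference tables |
| posts per user | ≈ 2 (author pool = n/2) | reference corpus characteristics |
| hyperlink rate | .04 reddit / .25 twitter | reference corpus characteristics |
| hashtag rate | .31 (twitter) | reference corpus characteristics |
| tweet length | ≤ 280 chars | platform limit |
| distress rate | .40 | approximate yield of the distress filter on a long-form relevant corpus |
| fp trap rate | .10 | rate used by the elimination experiment |
| retweet rate | .10, duplicate rate .05, irrelevant rate .05 | unreported upstream of the reference corpora; chosen once as plausible platform noise |
| n_posts | 2000/platform | default study scale for property tests |

The acceptance script uses 2000 posts/platform for recovery and
elimination measurements, 12 000/platform for the validation-sampling
step (so every 60-positive stratum is feasible for the rarest topics),
500 random matrices for the alpha oracle and 500 random assignment
collections for network conservation.

## Numerical and design choices

- Timestamps are ISO-8601 UTC throughout; the corpus interchange format
  is JSON Lines (CSV export flattens label sets to semicolon-joined
  strings and carries unknown metadata as a JSON column). Unknown extra
  fields round-trip opaquely.
- Malformed records are skipped and counted at ingest (well-formed +
  skipped = lines read); a duplicate post id is a hard error naming the
  id; a file with no well-formed record among any is a format error.
- Tie-breaks are always lexicographic (centrality ranking, rank tables)
  and documented where they appear.
- Dedup keeps the earliest copy; which copy the original workflow kept
  is unknowable, and the choice only affects which timestamp survives.
- The iterative human lexicon-refinement loop is a workflow, not an
  algorithm: lexicons are versioned YAML configs, and the package does
  not automate their refinement.

## Known limitations

- The shipped lexicons are deliberately small illustrative stand-ins;
  substantive conclusions about real corpora require the full curated
  keyword lists as config drop-ins.
- No stemming, lemmatization, spelling correction, language detection,
  or embedding/supervised classification — out of scope by design.
- Alpha confidence intervals (bootstrap) are an extension point, not
  implemented.
- Live platform acquisition (archive downloads, scraping) is out of
  scope; the package starts from serialized corpora.
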