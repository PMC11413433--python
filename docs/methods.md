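# Methods

This note records the models, procedures, parameter choices and known
limitations of the `icdaug` pipeline, in the order data flows through it.

## Code space and hierarchy

Codes follow the ICD-10 surface grammar: an uppercase letter, two
alphanumerics (together the three-character *family head*), an optional
subcategory suffix of up to four alphanumerics with at most one dot.
Seven-character procedure-style codes parse under the same rule provided
they begin with a letter. The working hierarchy is family-only by default —
each leaf's single ancestor is its head — because within-family structure
is what the error analysis interrogates. A deeper hierarchy (family →
block → chapter) can be loaded from a `node_id,parent_id,level` CSV, and
the hierarchical metrics are depth-general, so both settings are
supported; neither is asserted as the only valid one.

## Selection of augmentation targets

Selection runs on a per-split label population table (population = number
of documents carrying the label; labels are sets per document):

1. *few-shot common codes*: train population in [1, 5] and at least one
   dev and one test document;
2. *retained families*: families of those codes that also contain a
   frequent member (train population strictly greater than 100) and a
   zero-shot member (train population 0, test population ≥ 1; the dev
   count is unconstrained, since zero-shot is defined relative to
   training). Membership is judged over all observed codes, not only the
   few-shot candidates;
3. ten retained families are sampled uniformly without replacement;
4. *generation codes*: every code in a chosen family with train
   population strictly below 100, split into a few-shot part (present in
   training) and a zero-shot part (test-only).

Note the two stages use different population windows: the initial scan is
capped at 5, while generation codes admit anything below 100. The wider
second window is deliberate — cloning targets all under-populated family
members, not only the scan's candidates.

## Silver standard

For each few-shot generation code, its training documents are cloned
round-robin until the code's population reaches 100. Original records
keep their label sets; each clone drops k non-relevant labels, with k
uniform on {0..min(5, available)} — zero drops included, since exact
clones are then handled by the duplicate rule. For each zero-shot code,
every training document containing one of its siblings yields a request
with one uniformly chosen sibling replaced by the zero-shot code, capped
at 100 documents per code (`zero_shot_cap`): in a desk-scale code space
frequent siblings appear in hundreds of documents, and without the cap
zero-shot codes would receive several times more synthetic examples than
the few-shot codes' 100, distorting the balance the cloning step sets up.
Setting `zero_shot_cap=None` restores the uncapped rule.

Duplicate label sets (exact set equality with any earlier record, order-
stable) are flagged and assigned generation temperature 0.1; unique sets
get 0.0, i.e. deterministic generation.

## Document generation

Prompts list one `CODE: Description` line per label plus eight constraint
blocks: a 4000-word cap, social and family history, anonymization,
no codes in the body, explicit numeric values, a concrete concept for
"other"-umbrella descriptions, omission of "unspecified", and a trailing
numbered diagnosis list with bracketed codes. The generator interface is
`generator(prompt, temperature, seed) -> text`, so a hosted-model adapter
can be slotted in without touching the pipeline; the built-in generator is
a deterministic template engine that parses the label lines back out of
its own prompt and honours every constraint. At temperature 0 its output
is a pure function of the prompt (seed-independent, mimicking a
deterministic decoder); at positive temperature the seed perturbs the
phrasing but never the code list.

Post-processing extracts bracketed codes from the trailing
discharge-diagnoses section only (stray bracketed codes elsewhere are
logged, not extracted), then scrubs every code mention from the body. The
code pattern used for extraction and scrubbing requires a leading
uppercase letter, a three-character head, at most one dot, up to four
subcategory characters, **and at least one digit** — the digit requirement
keeps uppercase English words out of the scrubber's reach.

Coding-task responses parse structured-first: a JSON array of objects with
keys `diagnosis` and `icd_code` is taken at face value; anything else
falls back to a pattern scan accepting `diagnosis ... icd_code ...` pairs
and `text [CODE]` surface forms. Codes are de-duplicated keeping the
first diagnosis string; an unparseable response yields an empty list with
a parse-mode flag.

## Reference coder

A convolutional per-label-attention model: word embeddings (dim 32), one
1-D convolution (64 filters, kernel 3, tanh), per-label attention over
positions, per-label sigmoid outputs. Training is binary cross-entropy
for exactly 20 epochs with Adam (learning rate 1e-2, batch 16), dev-set
mean average precision recorded every epoch, and the best epoch's
parameters kept (ties to the earliest). mAP is macro: average precision
of each label's document ranking, averaged over labels with at least one
positive. Prediction thresholds probabilities at 0.5 by default — the
threshold is a documented package default, exposed in `CoderConfig`.

The implementation is vectorized numpy with analytically derived
gradients (verified against numerical differentiation to ~1e-7 relative
error), float32 arithmetic, and per-batch trailing-pad trimming. Sequence
length is capped at 80 tokens by default, which covers the synthetic
documents this package trains on; raise `max_len` for longer corpora.
Labels absent from training are excluded from the model's output space —
they score zero downstream, which is precisely why zero-shot codes need
augmentation. With 92 labels, 32 filters measurably underfit (dev mAP
0.73 vs 0.96 at 64 on the separable fixture); capacity should scale with
the label count.

## Evaluation

Flat micro/macro precision/recall/F1 are computed from per-label
TP/FP/FN counts. Conventions: per-label F1 is 0 when P + R = 0; codeset
labels with zero gold and zero predicted instances enter the macro
denominator with all-zero scores (fixed-label-space convention). The
macro therefore depends on the codeset, which is always explicit.

Hierarchical scores extend gold and prediction sets with ancestors before
counting; set-based extension records presence, count-preserving
extension carries descendant counts. Micro pools over (document, node)
pairs and is the default and the reported form; an equal-node-weight
macro is available via `hierarchical_metrics(..., average="macro")`. Two worked identities pin the semantics: sibling confusion (gold
{A1,A2}, predicted {A1,A3}) scores 0.5 leaf-only, 2/3 set-based, 3/4
count-preserving; within-family over-prediction (gold {A1}, predicted
{A1,A2}) scores lower count-preserving than set-based.

WHCM rates classify each gold instance of a codeset label as TP,
within-family error (some same-family false positive exists in the
prediction — weak matching, no one-to-one assignment), or out-of-family
error. Per-label percentages are macro-averaged over codeset labels with
at least one gold instance; labels without gold instances are excluded
from this macro (they have no error mass to classify), unlike the flat
macro above. Per label TP% + IF% + OOF% = 100 by construction.

## Rater agreement

Fleiss' κ treats the five ordinal score levels as nominal categories
(the statistic's own assumption; the mean score μ is reported alongside
precisely because κ discards ordinality). κ is computed per criterion,
separately for real and synthetic documents, via the standard
(P̄ − P̄ₑ)/(1 − P̄ₑ) formula; a degenerate table (all raters always in one
category) is reported as NaN rather than aborting other criteria.

## Synthetic data: what it emulates, what it does not

The generator reproduces the structural conditions the study depends on:

* a code space of 12 designated families × 6 leaves plus 20 background
  codes. In each family, the leaf described "…, unspecified" is the
  frequent member, one leaf carries an "Other specified …" umbrella
  description, one leaf is zero-shot, and the rest are few-shot; variant
  leaves get globally unique pseudo-clinical terms so they are learnable
  in principle;
* label popularity: a truncated power law (exponent 1.5) over the
  frequent pool; few-shot strata planted with 1–5 training documents and
  at least one dev/test document each; zero-shot leaves planted only in
  test; frequent family leaves topped up past 120 training documents.
  Planting is deterministic so the study's preconditions hold exactly
  rather than probabilistically;
* per-document label counts share one distribution (1 + Poisson, mean 5,
  cap 12) across all splits;
* text: each label contributes tokens from its own description — the
  condition word and the variant word, each independently omitted with
  probability 0.3 but never both — plus Poisson(15) noise tokens. Token
  omission applies to the condition word too; with the family word always
  present, a baseline coder produces same-family false positives on about
  half its misses, whereas the study setting this package emulates has
  out-of-family errors dominating at baseline. Because generated
  documents paraphrase the same descriptions, synthetic and real text
  share exactly the vocabulary a real coder would exploit.

Default corpus scale is 3000/300/600 train/dev/test documents — large
enough for the frequent/few-shot contrast to be real, small enough that a
full 10-seed baseline-vs-augmented replication runs in about ten minutes
on one CPU. These sizes are the package's desk-scale choice.

What the generator does **not** emulate: clinical prose (documents are
token bags plus templated sections), label correlations beyond
co-occurrence by popularity, documentation habits, negation, or the
vocabulary size of real notes. Passing tests therefore demonstrate that
the pipeline's machinery is correct and that the augmentation mechanism
operates as designed under the assumed statistical structure — not that
any particular clinical corpus will enjoy the same gains.

## Determinism

Every stage draws from a named substream of one global seed
(`SeedSequence(seed, spawn_key=(stage_index,))`, reduced below 2³¹).
Reports serialize with sorted keys and no timestamps; an identical config
(hashed over everything except the output directory) reproduces
byte-identical reports. The separable learnability fixture
(`distinct_descriptions=True`, no planted strata, no token omission, low
noise, 800 training documents) is the configuration under which the coder
is expected to reach dev mAP ≥ 0.95 within 20 epochs.

## Known limitations

* The built-in generator's fluency is intentionally minimal; it validates
  plumbing and constraint compliance, not text quality.
* Generated documents (~110 tokens) are *longer* than the token-bag
  documents of the synthetic corpus (~25 tokens); a sectioned summary
  enumerating several conditions cannot be made shorter than a desk-scale
  token bag. In the real setting this direction is reversed (synthetic
  documents shorter than clinical sources); nothing in the pipeline
  depends on the direction.
* The mock coder and study scale are desk-sized; absolute metric values
  have no external meaning, only baseline-vs-augmented contrasts do.
* WHCM's weak matching lets one false positive license several
  within-family errors in the same document; this follows the weak
  construction and is not a bug.
* Fleiss' κ on ordinal data understates agreement; μ is reported
  alongside, and a linearly weighted variant is available behind
  `fleiss_kappa(..., weights="linear")` but is never the default.
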