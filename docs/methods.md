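# Methods

## The paradigm

`weaktext` implements a three-stage text-classification paradigm for
clinical snippets: a deterministic rule-based labeling function produces
weak labels for an unlabeled corpus; documents are mapped to dense
features (by default, mean-pooled word embeddings); and a standard
classifier is trained on the weak labels. The working hypothesis is that
a distributional representation lets the classifier generalize past the
literal rules — misspelled or morphologically-variant cue words occupy
the same neighborhood as their canonical forms in embedding space, so
documents the rules miss are still classified correctly.

## Rule matching semantics

A rule set is an ordered list of regular-expression rules, each mapped to
a category, with a precedence order over categories and a default
category assigned when nothing fires.

* **Case-insensitive matching.** Clinical text mixes "Fx", "fx", "No
  smoking", "no smoking"; the printed rules are lowercase.
* **Word-boundary anchoring.** Every top-level alternative of a pattern
  is wrapped in `\b…\b` at compile time. This prevents `smokers?` from
  firing inside "nonsmoker" while leaving multi-word patterns with
  explicit context (e.g. `denies\W*smoking`) intact.
* **Sentence segmentation** splits on `.`, `!`, `?`, `;` and newline.
  The semicolon matters: semi-structured report lines ("R hip
  inj/marc/steroid; fx femur neck nos closed") must segment so that a
  fracture modifier and an anatomical keyword can share one segment.
* **Precedence.** Negation categories are checked before affirmative
  ones (non-smoker before smoker; past smoker before current smoker
  before non-smoker in the multiclass task), because negation patterns
  contain the affirmative keywords as substrings: "No smoking" must
  resolve to non-smoker even though "smoking" alone is a smoker keyword.
  The default category may itself carry rules (non-smoker does), so
  precedence may include it; the default is additionally assigned
  whenever no rule fires at all.
* **Co-occurrence.** The hip-fracture labeler is sentence-scoped: a
  positive label requires at least one anatomical keyword and one
  fracture modifier within a single sentence. Consequently a modifier
  and keyword in different sentences ("Indications: femur fx. Cannulated
  screw fixation of the right femoral neck.") yield no-fracture — a
  deliberate, tested property of the labeler, and the exact failure mode
  an embedding-based classifier can repair.
* The entry `(inter|per|intra) trochanteric` is compiled by default to
  also accept the fused and hyphenated surface forms
  ("intertrochanteric", "inter-trochanteric"), which are the forms that
  occur in practice; a `strict_trochanteric_space` flag restores the
  literal reading.
* The unit of analysis is the provided snippet. Section extraction from
  full notes is assumed to have happened upstream.

Fixture snippets used in the test suite are limited to cases whose
expected label follows from the printed rules applied to the snippet
text alone; elliptical excerpts whose label depends on text outside the
excerpt are not usable as fixtures and are excluded.

## Document representations

* **Mean embedding** (the primary feature): the arithmetic mean of the
  embedding vectors of the document's in-vocabulary tokens.
  Out-of-vocabulary tokens are skipped and counted; a document with no
  in-vocabulary token gets the zero vector and a `degenerate` flag.
  Skipping (rather than zero-imputing) preserves the feature scale, and
  the zero vector is the natural neutral element for linear models.
* **Tokenizer**: lowercase, split on non-alphanumeric runs, punctuation
  dropped. Pattern matching lives entirely in the rule engine; features
  only need bag-level content.
* **tf-idf baseline**: smoothed idf, tf·(ln((1+N)/(1+df))+1), rows
  L2-normalized — the common default, which also avoids division by
  zero for unseen terms.
* **Topic baseline**: latent Dirichlet allocation with K=100 topics
  (matching the embedding dimension), symmetric priors α = min(1, 50/K)
  (the 50/K heuristic, clipped to the solver's admissible range) and
  η = 0.01, a fixed iteration budget and a mandatory seed. The document
  feature is the mean over in-vocabulary tokens of the per-word topic
  mixture p(topic | word), obtained by column-normalizing the fitted
  topic–word matrix; it lies on the K-simplex.

## Classifiers

Hyperparameters are fixed, not searched: linear SVM with C = 10; random
forest with 5 trees; single-hidden-layer MLP with 15 ReLU units. Seeds
are mandatory for the stochastic learners. The word-level CNN variant
(embedding layer initialized from a pre-trained table, one convolution
layer with 128 filters and window 3, global max pooling, softmax output,
sequences padded/truncated to 100 tokens) is specified as an optional
plugin: constructing it raises a clear `CapabilityError` when no
neural-network backend is available, and every evaluation in this
package is achievable with the three core models. Class imbalance is not
reweighted by default.

## Weak-label theory and its empirical check

For a binary task with labels in {+1, −1} and uniform marginals, an
m-rule labeling function whose i-th rule is correct with probability φ_i
agrees with the truth with probability q = Πφᵢ / (Πφᵢ + Π(1−φᵢ)) — the
normalized product of the per-rule agreement terms. When rules can
disagree on a document, this normalized-product reading is one
consistent way to reduce the per-rule accuracies to a single output
channel; it is the one implemented, and q is computed in log space.

The true-label empirical loss is the ridge-regularized logistic loss
L(w) = (1/|D|) Σ log(1+exp(−wᵀf(d)·Y_d)) + ρ‖w‖². The weak-label loss
L_φ(w) replaces each per-document term by its conditional expectation
given the observed weak label: q·log(1+exp(−wᵀf(d)Λ_d)) +
(1−q)·log(1+exp(+wᵀf(d)Λ_d)). This conditional expectation is evaluated
in closed form via q rather than by Monte-Carlo over Y given Λ — exact
and deterministic under the binary/uniform assumptions.

`verify_bound` checks the claim |L(w) − L_φ(w)| ≤ c‖w‖ε/2 with
ε = |D|^(−1/2) empirically. Its data-generating process follows the
weak-label model itself: features are standard Gaussian, the rule output
Λ is a logistic function of a fixed direction through the features, and
the truth Y is drawn from Λ through the accuracy channel P(Y=Λ) = q.
Under this process the empirical true loss is conditionally unbiased for
the weak loss given the fitting data, so the observed gap shrinks as
|D|^(−1/2) and the implied constant ĉ = 2·gap/(‖w‖ε) stays bounded.
This is a modeling choice worth stating plainly: if instead the truth
were a deterministic function of the features, the gap would contain a
systematic component ≈ 2q(1−q)·mean(wᵀf(d)·Y_d) that does not shrink
with |D| — the bound is a statement about data generated by the
weak-label model, not about arbitrary label noise.

The weak loss is convex in w; it is minimized by full-batch gradient
descent with Armijo backtracking, zero initialization, gradient-norm
tolerance 1e-8 and an iteration cap of 10⁴. A deterministic solver keeps
every report reproducible; non-convergence within the cap is flagged in
the report, never silently dropped. The constant c is treated purely as
an empirical output ĉ, never as an input. Default grid: |D| ∈ {400,
1600, 6400}, φ = 0.9, ρ = 0.1, 20 repetitions, 10 feature dimensions —
small enough to run in seconds, large enough to show the ε-scaling.

## Evaluation

Precision, recall and F1 are computed per class from the confusion
matrix, with micro and macro averages always reported; micro-F1 equals
accuracy for single-label tasks and is the default aggregate.
Zero-denominator cells are reported as 0 and flagged.

Two systems are compared with a paired bootstrap F1 test: the test set
is resampled with replacement n_boot times (default 1000), the F1
difference A−B is recorded per resample, and the statistic is the mean
difference divided by the bootstrap standard deviation (i.e. the
bootstrap standard error of the difference), referred to a t
distribution with n_boot−1 degrees of freedom. Note the denominator is
the bootstrap SD itself, not SD/√n_boot: the resampled differences
estimate the sampling distribution of one observed difference, so
treating them as n_boot independent observations would overstate the
evidence by a factor √n_boot. The implemented form has close to nominal
size: under exchangeable systems its rejection rate at the 5% level is
statistically indistinguishable from 5% (a property test enforces
this). Identical predictions and single-category gold sets are flagged
as degenerate rather than assigned a p-value.

## Synthetic data: what it emulates, and what it does not

The generator fabricates the mechanics the paradigm relies on, with gold
labels fixed by construction before any corruption:

* smoker documents carry affirmative cues (free-text "smokes N packs per
  day" or semi-structured "tobacco use: yes"); non-smoker documents
  carry negated cues ("no smoking", "denies smoking", "tobacco: no") or
  no cue at all (rate 0.3 — absence of documentation is itself the most
  common non-smoker presentation);
* fracture documents pair an anatomical keyword with a fracture
  modifier, co-located or split across two sentences with probability
  `p_cross`; no-fracture documents are cue-free, keyword-only, or
  mention a non-hip fracture;
* the multiclass smoking task defaults to the published class mix of the
  2006 shared task (9% current, 9% past, 17% non-smoker, 65% unknown),
  so its imbalance failure mode is reproducible;
* the misspelling operator perturbs one cue word per selected document
  (rate `p_miss`) by a single-character deletion or adjacent swap that
  never touches the first character and — checked against the rule set —
  no longer matches any pattern on its own, keeping variants
  human-plausible (tobacco → tobaco) and their rule-evasion guaranteed;
* filler text is pronounceable nonsense, screened so no filler word can
  fire any rule of any built-in rule set; snippets are short (one or two
  filler sentences of 3–6 words plus the cue sentences), like the
  section-level texts the tasks operate on.

Synthetic embeddings mirror the geometry that makes the paradigm work:
each base cue word gets a random cluster center (unit scale, k = 100 by
default); every surface form of it, including misspelled variants, gets
the center plus Gaussian noise of relative scale `cluster_sd` = 0.2;
numerals share one cluster (as they do in distributional spaces); all
other tokens get independent random vectors. The filler vocabulary
defaults to 50 words — deliberately smaller than the embedding
dimension, so filler words span a proper subspace and a linear separator
over cue directions exists. This is the generator's contract: it
produces data with the statistical structure the paradigm assumes. With
a filler vocabulary larger than the embedding dimension, filler noise
fills the whole space and even a fully supervised linear model degrades;
that regime is reachable through `filler_vocab_size` but is not the
default condition.

What the generator does **not** emulate: real clinical language (syntax,
abbreviation conventions, section headers), real embedding geometry
(trained vectors have anisotropic structure and polysemy), negation
scope beyond the printed patterns, or document-length effects (mean
pooling dilutes a single cue in long documents; real note-level
classification would need the section extraction assumed upstream).
Passing results on synthetic corpora therefore demonstrate that the
pipeline's mechanics are correct — rules miss exactly the corrupted
documents, embedding classifiers recover them, the loss bound scales as
predicted — not that any particular F1 level transfers to real
institutional data.

## Standard problem sizes

The packaged evaluations use 2,000 training and 400 test documents with
10 generator seeds for the recovery and misspelling studies, a 1,000 —
document corpus per task for the clean-agreement check, 10,000 draws for
the weak-channel calibration, and the bound grid above. These sizes give
binomial standard errors small enough for the 3-SE checks used
throughout while keeping any single run in the seconds range.

## Known limitations

* The CNN variant — the strongest model in the motivating setting — is
  declared but not runnable without a neural backend; conclusions here
  rest on the linear SVM, random forest and MLP.
* The loss-bound simulation is binary-only, as is the weak-label
  channel; the multiclass task is exercised by the labeler and
  classifiers but not by the theory harness.
* Rule evidence spans are reported for document-scope rule sets at the
  granularity of the sentence containing the match start; a pattern
  whose `\W*` gap crosses a sentence boundary is attributed to the
  sentence where it begins.
* The bootstrap F1 test conditions on the fixed test set; it does not
  account for training-set or seed variability (the multi-seed medians
  in the studies address that separately).
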