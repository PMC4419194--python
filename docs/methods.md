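# Methods

`supportdyn` analyses how members of online health support communities
elicit support, what support they receive, and how support exposure relates
to staying in the community.  The pipeline has three statistical stages —
construct measurement, path/mediation modelling, and retention (survival)
modelling — plus a synthetic-community generator that makes all three
testable without access to forum data.

## Construct measurement

Nine constructs are measured per message on a 1–7 Likert scale: four kinds
of self-disclosure (positive/negative × emotional/informational), question
asking, two support-elicitation judgments, and provision of emotional and
informational support.  Ground truth comes from crowd panels (k raters per
message, different subsets per message); per-message scores are panel
means.  Reliability uses the one-way random-effects intraclass correlation
— the message is the only random factor because rater subsets are not
crossed with messages.  For unbalanced panels the effective panel size is
`k0 = (N − Σk_i²/N)/(n − 1)`; the average-measure ICC is the Spearman–Brown
step-up of the single-measure ICC at `k0`.  Both are reported because the
two variants answer different questions (one rater vs the panel mean);
negative estimates are reported as computed to preserve the ANOVA
estimator's semantics.

Machine measurement is an epsilon-insensitive **linear** SVR per construct
over three feature families:

* category-dictionary counts (literal words and trailing-`*` stems; raw
  counts, not rates, so features are additive over concatenation — a
  per-100-words view is available via `normalize="per100"`);
* LDA topic-dictionary counts: scikit-learn's variational LDA with 20
  topics, top-500 words per topic, symmetric priors (document–topic prior
  `min(1, 50/n_topics)` — the classic heuristic capped at the variational
  implementation's bound — and topic–word prior 0.01), fixed seed;
* syntactic/pattern/sentiment features: sentence counts, negation,
  POS-based counts (proper nouns, adjectives, cardinal numbers), advice
  patterns (`<Please+VERB>`, `<If+you>`, `<You+MODAL>`, advice verbs),
  question patterns (question marks, indefinite pronouns, verb-subject
  inversion, indirect-question templates), state features (be/stative
  verbs, sentences opening with "I", optionally with positive/negative
  adjectives), subjectivity and drug-term counts, and a binary story flag
  from a logistic classifier.

Sentences split on `.!?` with a small abbreviation guard (dr., mr., mrs.,
e.g., i.e., etc.); tokens are lowercase word characters with internal
apostrophes.  POS tags come from a deterministic lexicon+suffix rule
tagger (Penn Treebank tagset).  It resolves closed classes exactly and
open classes by word lists and suffix heuristics, which is sufficient for
the tag distinctions the features use; it is not a general-purpose tagger,
and users with heavier needs can substitute tags upstream.

A token may match several dictionaries but counts at most once per
dictionary.  Overlap between topic and category dictionaries is handled by
an explicit exclusion list in configuration rather than automatic
detection.  The shipped dictionary/lexicon pack is a small, synthetic,
non-canonical stand-in; production analyses supply their own files
(two-column TSV or the `%`-header `.dic` convention).

Model fitting standardizes features and reports weights on the
standardized scale so magnitudes are comparable across features.  C and
epsilon are tuned on the 10% development split of the 80/10/10 partition
over a small fixed grid ({0.1, 1, 10} × {0.01, 0.1, 0.3}); the 10% test
split is used exactly once, for the reported Pearson accuracy.  Corpus
scoring clips predictions to the 1–7 construct range.

## Path and mediation models

The exchange models are recursive (acyclic) path models over observed,
standardized variables.  For such models, equation-wise least squares is
the maximum-likelihood estimator, so each endogenous regression is solved
directly from the correlation matrix.  The model-implied covariance
`Σ̂ = (I−B)⁻¹ Ω (I−B)⁻ᵀ` (Ω = free exogenous covariances plus diagonal
residual variances) yields

    χ² = (n−1)[ln|Σ̂| − ln|S| + tr(S Σ̂⁻¹) − p],

CFI against the mutual-independence baseline (diagonal S), and
`RMSEA = sqrt(max(χ²−df,0)/(df(n−1)))`.  Degrees of freedom are
`p(p+1)/2` minus free parameters (edges + free exogenous covariances +
exogenous variances + residual variances).  Standard errors are
normal-theory OLS Wald errors; no robust correction is applied.

The *direct* specification regresses reply emotional support on all five
starter strategies and reply informational support on question asking and
the two informational disclosures only — the emotional-disclosure →
informational-support paths are omitted (they are not significant and
omitting them improves fit), leaving df = 3.  The *mediated* variant adds
the two perceived-support-need constructs as mediators between every
strategy and the matching support outcome.

Mediation is decomposed as products of standardized path coefficients:
indirect = β(exposure→mediator)·β(mediator→outcome), total = direct +
indirect, proportion mediated = indirect/total.  The proportion is
sign-aware and can exceed 100% when direct and indirect effects have
opposite signs.  Worked-example arithmetic rounds effects to 2 decimals
and proportions to integer percents (half away from zero), matching the
convention used when such decompositions are reported.

## Retention (survival) model

Each member's clock starts at their first post; a "week" is a 7-day window
anchored there.  For every week with ≥1 post, the exposure set is all
messages posted during that window in the threads the member posted to that
window (reading is unobserved; thread-week co-presence stands in for it,
and the member's own posts are included since the definition does not
exclude them).  Weekly covariates: exposure post count, mean machine-coded
emotional and informational support over the exposure set, the member's
starter share that week, and the has-a-profile flag.

A member drops out on failing to post again within 12 weeks of their last
post; members whose last post is within 12 weeks of the end of data are
right censored.  Members can drop out and rejoin: silences longer than the
gap split participation into episodes, and the episode clock restarts at
each rejoin (a no-reset variant is a configuration choice).  Episodes are
expanded into counting-process intervals — one per active week, covariates
carried forward over short silences — and the final interval of an episode
spans one further week with the event flag.

The hazard is Weibull proportional hazards, `h(t|x) = p t^(p−1) exp(x'β)`
with the baseline log-rate absorbed into an intercept.  An interval
(start, stop, event, x) contributes
`−exp(x'β)(stop^p − start^p) + event·[ln p + (p−1)ln stop + x'β]` to the
log likelihood, which makes the likelihood invariant to interval splitting
(asserted numerically in the tests).  Optimization is L-BFGS-B on
`(ln p, β)` with an analytic gradient (convergence at gradient max-norm
1e-6 scale); standard errors come from the observed information, obtained
by central differences of the analytic gradient.  With the shape fixed at
1 the fit coincides with exponential regression, which the tests verify
against an independent Poisson-offset GLM oracle.  Continuous covariates
are z-scored over interval records (not over users — a documented choice),
and the post-count × support interactions are formed after standardizing
the mains.  Hazard ratios are `exp(β)`; the percent-change reading is
`100(1−HR)` ("more likely to stay") or `100(HR−1)` ("more likely to
leave"), rounded to integers.

## Synthetic community generator

The generator emulates the statistical structure each stage assumes, with
ground truth emitted alongside.

**Latents.**  Starter constructs are drawn from a correlated Gaussian with
means/SDs on the 1–7 scale typical of hand-coded community data (e.g.
question asking high, positive emotional disclosure low), then clipped to
[1, 7].  The default 7×7 correlation matrix copies the *sign structure* of
published descriptive correlations with magnitudes rounded to 0.05 (so no
inaccessible dataset is implied to be replicated); it is verified positive
semi-definite at configuration time.  Reply support latents are a
configured linear map of the starter Gaussians plus residual noise sized
to keep unit variance (with a floor), so the path models have a known
standardized-coefficient target; the default map uses the canonical sign
pattern (disclosure → emotional support positive, question asking →
informational support positive / emotional support negative).  Clipping to
the Likert range attenuates observable correlations slightly relative to
the Gaussian targets; correlation checks therefore compare the Gaussian
scale.

**Text.**  Message bodies are assembled from disjoint per-construct
vocabulary pools: the number of pool tokens is Poisson with rate 3 per
latent unit above 1, plus Poisson(6) filler tokens from a pool that matches
no dictionary.  Sentence templates plant exact counts for the pattern
detectors (question marks and indirect questions driven by the question
latent, "I am glad/scared" sentences by the emotional-disclosure latents,
advice patterns by reply informational support, negation at a constant
rate); every planted count is recorded per message, so featurization can
be checked for exact equality.  Text generation is template-based, not a
language model: the downstream features are counts, so controllable counts
matter more than fluency.  Passing tests therefore show that the pipeline
recovers planted count structure, not that it handles the full variability
of natural prose.

**Ratings.**  Ratings are `clip(round(latent + rater effect + noise), 1, 7)`
with rater effects drawn once per rater from a shared pool (σ_rater = 0.3,
σ_err = 1.0, k = 10 by default).  Integer rounding and boundary clipping
bias ICC estimates downward by roughly 0.02–0.04 relative to the
continuous-scale closed form; tolerance bands in the tests account for
this.

**Community and exchange defaults.**  1,000 threads (the scale of a
hand-codable exchange sample), 11.4% of threads never replied, exponential
first-reply delays with a 12 h mean, Poisson(1) additional replies, and a
25% story rate.

**Survival community.**  Per user: four latent z-covariates and a Bernoulli
profile flag (p = 0.3119); an event time drawn from the Weibull PH model
with configured log-hazard-ratios (defaults: shape 0.85 — hazard declining
with tenure — baseline rate 0.06/week, profile/starter/post/emotional
exposures protective, informational exposure hazardous, interactions
null); weekly posting (3 posts, 1–3 of them starters by stable tertiles of
the starter latent — a deterministic propensity, so the computed weekly
starter share measures its latent faithfully) until the event or the end
of data at week 52; supporter accounts inject replies whose support scores
encode the user's exposure latents.  Exact counting-process spells are
also derivable directly from the truth record for likelihood-level
recovery checks, while the corpus route exercises exposure construction
and dropout bookkeeping end to end.

## Problem sizes used in the test suite

Oracle-equivalence checks run on ≥1,000 generator tokens/sentences.
Parameter-recovery checks use n = 5,000 (path betas within ±0.05; Weibull
hazard ratios within ±15%, shape within ±0.1).  The pipeline property runs
50 seeded replicates of the 1,000-thread default community with fixed SVR
hyperparameters (C = 1, ε = 0.1); the survival direction property runs 50
replicates at 400 users; the null-coverage check uses 20 replicates of 250
users (100 interval-level confidence intervals).  These sizes were chosen
so each suite runs comfortably on one CPU while keeping Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

* The rule tagger approximates POS tags; rare suffixes are mis-tagged, and
  the proper-noun rule relies on capitalization.
* The generator's vocabulary-pool texts contain none of the noise of real
  forum prose (typos, quoting, markup); measurement accuracies on
  synthetic text are optimistic relative to real data.
* Exposure assumes members read everything in thread-weeks they posted to;
  lurking and partial reading are not modelled.
* The path models are observed-variable only; no latent measurement model
  or ordinal estimator is provided.
* Negative residual variances (Heywood-like cases) are clamped at zero
  when assembling the implied covariance and reported as such.
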