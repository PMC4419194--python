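# supportdyn

Analysis pipeline for **support exchange in online health communities**:
how members elicit emotional and informational support in threaded forums,
what support they actually receive, and how support exposure relates to
staying in or leaving the community.  It is aimed at computational social
science / health communication researchers who have (or can export) a
threaded message corpus and want the full measurement-to-model chain in
one tested package.

## What it computes

1. **Construct measurement.**  Nine support-related constructs per message
   on a 1–7 scale (four kinds of self-disclosure, question asking, two
   support-elicitation judgments, provision of emotional/informational
   support).  Crowd-rater panels are aggregated to per-message means with
   one-way random-effects ICC reliability; machine measurement uses linear
   epsilon-insensitive SVR over dictionary counts, LDA topic-dictionary
   counts and syntactic/pattern features, trained on an 80/10/10 split.
2. **Path and mediation models.**  Recursive path models over standardized
   observed variables link the thread starter's elicitation strategies to
   the support in the first reply, with χ²/CFI/RMSEA fit indices and
   product-of-coefficients mediation through perceived support needs
   (proportion mediated = indirect/total, which may exceed 100%).
3. **Retention.**  Weekly support-exposure covariates per member (exposure
   post count, mean emotional/informational support in thread-weeks the
   member posted to, starter share, profile flag), 12-week-gap dropout
   spells in counting-process form, and a Weibull proportional-hazards fit
   `h(t|x) = p t^(p-1) exp(x'β)` with hazard ratios and percent-change
   interpretation (HR 0.665 → "34% more likely to stay").
4. **Synthetic community.**  A generator that plants latent construct
   intensities, vocabulary-pool message text with exactly bookkept feature
   counts, rater panels with known variance components, reply support with
   known path coefficients, and Weibull dropout with known hazard ratios —
   so every stage above is testable against ground truth.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import pandas as pd
from supportdyn import (SimConfig, simulate_corpus, simulate_ratings,
    aggregate_ratings, icc_oneway, fixture_dictionaries, featurize_corpus,
    extract_exchange_pairs, split_dataset, train_construct_model,
    evaluate_model, score_corpus, fit_elicitation_models,
    percent_change_from_hr)

cfg = SimConfig(seed=7)                       # default synthetic community
threads, truth = simulate_corpus(cfg)
pairs = extract_exchange_pairs(threads)

ratings = simulate_ratings(truth.latents, cfg)          # 10-rater panels
rep = icc_oneway(ratings, "question_asking")
scores = {(s.message_id, s.construct): s.value
          for s in aggregate_ratings(ratings)}

starters = [p.starter for p in pairs]
replies = [p.first_reply for p in pairs if p.first_reply is not None]
X = featurize_corpus(starters + replies, fixture_dictionaries())

construct = "provide_informational"
ids = [m.message_id for m in replies]
split = split_dataset(ids, seed=7)            # 80/10/10
y = {i: scores[(i, construct)] for i in ids}
model = train_construct_model(
    X.loc[split.train], [y[i] for i in split.train], construct=construct,
    dev_features=X.loc[split.dev], dev_targets=[y[i] for i in split.dev])
acc = evaluate_model(model, X.loc[split.test], [y[i] for i in split.test])
```

Running the full chain (train all seven models, score the corpus, fit the
direct path model) prints:

```
1000 threads, 2803 messages, 893 exchange pairs
question_asking ICC(single)=0.76 ICC(average)=0.97
provide_informational: held-out Pearson r = 0.86 (n=89)
chi2(3) = 4.98, CFI = 0.999, RMSEA = 0.027
question -> informational support: beta = +0.29
question -> emotional support:     beta = -0.18
neg. emotional disclosure -> emotional support: beta = +0.21
HR 0.665 -> 34% more likely to stay
```

Reading it: the 10-rater panels judge question asking very reliably
(average-measure ICC 0.97); the trained model's scores track the held-out
human scores at r = 0.86; the path model fits well (CFI ≈ 1, RMSEA 0.03)
and shows the planted exchange structure — asking questions raises the
informational support in the first reply (β = +0.29) while *depressing*
emotional support (β = −0.18), and disclosing negative emotions raises
emotional support (β = +0.21).  The last line converts a survival-model
hazard ratio into its everyday reading.

A CLI mirrors the library (`supportdyn corpus-stats`, `annotate`,
`featurize`, `train`, `score`, `pathfit`, `survive`, `simulate`); run
`supportdyn --help`.

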