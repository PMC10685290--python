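# Methods

## The measurement model

The package treats media attention as a proxy for policy uncertainty:
when the health-policy environment becomes hard to predict, newspapers
discuss health policy in uncertain terms more often, and the share of
such articles in a paper's output rises. The index is therefore built
from counts, not content models: `A_it` target articles out of `B_it`
total articles for newspaper *i* in month *t*, with a target article
defined by joint presence of at least one *health*, one *policy* and one
*uncertainty* term.

The construction assumes:

* the scaled frequency `X_it = A_it / B_it` is comparable across months
  within a paper once volume is divided out;
* papers differ in level and variance of `X` for editorial reasons that
  carry no signal, which unit-SD standardization (`Y_it = X_it / σ_i`)
  removes;
* the common movement of the standardized series across papers is the
  uncertainty signal, so the cross-paper mean `Z_t` estimates it and
  averaging over ~11 papers suppresses house noise;
* the overall scale is arbitrary, fixed by normalizing the series mean
  to 100 over the study window.

Standardization divides by the SD without centering, so index values are
nonnegative and a month with no target articles anywhere maps to 0.

## Conventions and numerical choices

* **σ_i is the sample SD (ddof = 1)**, computed over each newspaper's
  *observed* months in the exact window of the build. Rebuilding on a
  subset of papers or months therefore recomputes every σ_i.
* **Missing is declared, never inferred.** A coverage gap (the source
  database simply has no data for a newspaper-month) is declared
  metadata; a covered month with zero articles is a legitimate
  `B_it = 0`. Gap cells are excluded from σ_i and from the monthly mean,
  whose denominator is the count of papers observed that month.
* **`B_it = 0` in a covered month** cannot form a ratio; the cell is
  dropped from that month's average with a warning. (With `A ≤ B` this
  also forces `A_it = 0`, so no signal is discarded.)
* **Degeneracy**: a paper whose `X` series is constant has no
  standardization; the build fails with an error naming the paper. A
  series is treated as constant when its spread is zero or its SD is at
  the level of float round-off relative to the values (≤ 1e-13 × max).
* **Determinism**: newspapers are processed in sorted order and all
  reductions run in fixed array order, so a build is bit-reproducible
  for a fixed corpus.
* Matching is **plain substring containment on NFKC-normalized text**,
  with no word segmentation — the counts are meant to replicate what a
  keyword query against a news database returns, and NFKC harmonizes
  full-width/half-width variants in mixed exports. Each article counts
  at most once however many terms hit; per-term hit lists are kept for
  audit transparency.

## Splicing across coverage gaps

When several papers lack a year of coverage, three indexes exist: the
*donor* built from the fully covered papers over all months, the
*ex-gap* index built from all papers with the gap year excluded for
everyone (`build_index(..., exclude_months=...)`, which also removes
those months from every σ_i), and the *spliced* index that takes non-gap
months from the ex-gap series and gap months from the donor.
`splice_indexes` inserts donor values unrescaled and then re-normalizes
the union to mean 100 — re-normalization restores the only scale
constraint the construction states. The correlation between donor and
ex-gap series on their overlapping months is always computed and
reported, so the user can apply a no-systematic-bias judgment before
trusting the splice; the spliced series' metadata records that it was
re-normalized.

## Robustness battery

Subgroup indexes are rebuilt end-to-end per newspaper group and compared
pairwise by Pearson correlation (exact two-sided p from the t transform
with n−2 df). The default pass criterion is **r ≥ 0.74**, the
conventional threshold for split-sample robustness of newspaper-count
uncertainty indexes; it is a configurable parameter, not a constant.
Group presets (ALL / NNI / PNI / MNI — full roster, national papers,
party organs, metropolitan papers) are data and can be overridden.

Audit sampling draws, per newspaper, a simple random half
(`ceil(fraction · n_i)`, without replacement) of the machine-retrieved
target articles. Each stratum has its own seeded stream keyed on
(seed, newspaper), so a paper's sample is independent of which other
papers are present and bit-reproducible. Two label rounds are stored;
where the rounds disagree the second (post-discussion) round stands.
Audit outcomes never feed back into the counts: the index is built from
machine-retrieved counts, and the pass rate quantifies their semantic
precision.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* totals: `B_it ~ Poisson(λ_i)` per covered newspaper-month;
* relevance: each article is relevant with probability
  `p_t = p0 · m_t · exp(ε_shared,t + ε_i,t)`, where `m_t` is an event
  multiplier and the ε are Gaussian log-rate perturbations — the shared
  one creates the cross-paper correlation that the robustness tests
  presuppose, the idiosyncratic one models house effects;
* texts: relevant articles receive one term from each category, decoys
  (a `decoy_rate` fraction of non-relevant articles) receive terms from
  exactly two randomly chosen categories, the rest are pure filler.

Default parameters (the simulation used throughout the tests):
11 newspapers at λ = 100 articles/month, 60 months, baseline rate
p0 = 0.03, one event month with m = 8, decoy rate 0.1,
shared SD 0.25, idiosyncratic SD 0.15. The SDs were chosen so that the
documented worst-case rate bound `p0 · max(m) · exp(3·(σ_s + σ_i))`
stays below 1 (0.80 at the defaults) while leaving visible cross-paper
correlation; rates that still exceed 1 in extreme draws are clamped with
a warning. Problem sizes in the validation battery (e.g. 100 seeds for
spike recovery, 50 for the matcher and split-half checks, 200 random
panels for the oracle comparison) keep each check to a couple of minutes
while leaving Monte-Carlo error far smaller than the margins being
tested.

**Exactness by construction.** Ground-truth agreement of the keyword
screen is exact, not approximate, because unintended matches are
impossible: the default filler vocabulary shares no character with any
lexicon term, planted terms are never adjacent, and the spec validates
that no term of one category occurs inside a term of another (the
builtin lexicon satisfies this). A custom lexicon violating these
conditions is rejected at spec construction.

**Randomness** is one hierarchical stream: sub-streams are keyed
(seed, newspaper-hash, month-index), with a reserved key for the shared
monthly perturbation. Adding or removing a newspaper never perturbs
another newspaper's draws — useful for ablation tests.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: real Chinese newspaper language
(filler text is a small word list, so matcher performance on real prose,
e.g. false positives from short tokens like 人大 inside unrelated
compounds, is untested); duplicate or syndicated articles; within-month
burst dynamics; editorial shifts in total volume correlated with events
(λ_i is constant); and any semantic notion of relevance beyond keyword
co-occurrence. The audit pass-rate machinery tabulates human judgments;
it cannot generate them.

## The noise-free target

`expected_index` runs steps 2–5 on the deterministic scaled frequencies
`X_it = p0 · m_t`, identical across papers. Because the rows are
identical, the result is simply the multiplier path rescaled to mean 100
— the target the full pipeline should recover up to sampling noise. A
flat path (no events, no shocks) is degenerate for standardization and
raises, mirroring the constant-series behavior of the real pipeline.

## Open design points resolved

* Whether the historical construction re-normalized after splicing is
  not documented; this implementation always re-normalizes and flags it
  in metadata (rationale above).
* Whether σ_i was computed before or after excluding the gap year for
  fully covered papers is likewise not documented; here σ_i is always
  recomputed over exactly the months entering the build.
* `B_it` counts every record in the supplied corpus; curation (ads,
  listings, deduplication) is the caller's responsibility.
* The matcher operates on whatever text field is supplied (title, body,
  or both concatenated) with no separate title weighting.

## Limitations

The package validates the *construction*, not the *measurement*: it can
show that the pipeline recovers a planted uncertainty signal from
synthetic counts, but whether keyword co-occurrence frequencies track
real policy uncertainty is an empirical question that requires human
audit (supported here) and external comparisons (supported here) on real
corpora. Reconstructing any published index series requires access to
the underlying proprietary news archive.
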