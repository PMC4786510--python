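# Methods

## Model and procedure

`ontoapriori` mines association rules A → B over itemized categorical
records. An item is one `feature=value` pair; an itemset never holds two
values of one feature (such a candidate has support zero by construction,
so the invariant is enforced rather than counted). Support of an itemset
is the fraction of records containing all of its items; support of the
empty set is 1 by vacuous containment. A rule's support is
supp(A ∪ B) and its confidence is supp(A ∪ B)/supp(A) — the standard
reading; rule support as supp(A) alone is a plausible alternative
convention but is not used anywhere here.

Mining is the level-wise Apriori loop. The ontology-constrained variant
differs from the classic algorithm in exactly one step: at every level
k ≥ 2, candidates are filtered by semantic admissibility *before* support
counting. This ordering matters twice over — it is where the claimed
runtime saving comes from (inadmissible candidates never touch the data),
and it changes which itemsets are ever evaluated, because the default
candidate generator may propose an itemset whose sub-itemsets were never
frequent (see below).

### Semantic relatedness

Two features are related when any enabled meta-rule fires on their mapped
concepts:

* **direct** — an IS-A or cause edge joins the concepts, in either
  direction. Edge direction is deliberately ignored: cause edges are
  drawn one-way in the ontology, but pruning treats feature pairs
  symmetrically.
* **indirect** — an undirected path of at most `indirect_max_intermediates`
  intermediate concepts joins them. The default is one intermediate
  (a diet item and the disease linked through a shared risk-factor
  category is the motivating case). The path uses the same edge types as
  the direct rule (IS-A, cause) so that zero intermediates is *exactly*
  the direct rule; attribute-of and part-of edges can be enabled
  explicitly.
* **cohort** — the concepts share an immediate IS-A parent, i.e. the
  features sit in the same category. With multiple inheritance (IS-A is a
  DAG, not a tree), any shared immediate parent suffices.

Relatedness is reflexive by definition (it never arises inside a valid
itemset, but totality avoids edge cases) and symmetric for every policy.
Explicit per-pair overrides take precedence over the graph: policy-level
overrides first, then overrides carried by the ontology file. A policy
with every meta-rule disabled is legal — relatedness then comes only from
overrides, and with none at all no pair is related, which is the
degenerate configuration used to verify that constrained mining collapses
to singletons.

A candidate is admissible under the default `all-pairs-related` rule when
every unordered pair of its features is related; this predicate is
anti-monotone, so pruning can never reject a sub-itemset of an accepted
candidate. The `any-pair-related` alternative (one related pair suffices)
is provided but is not anti-monotone and is not the default.

### Candidate generation

`extend-by-item` (default) unions each frequent (k)-itemset with every
frequent single item it does not contain. This mirrors the constrained
procedure's worked example, which evaluates a 3-candidate one of whose
2-subsets is infrequent — textbook subset pruning would never have
generated it. `classic-join` is the standard Apriori self-join (sorted
itemsets agreeing on their first k−1 items) followed by the
all-k-subsets-frequent prune; it is used for the classic baseline and the
oracle equivalence tests. Both skip unions that would place two values of
one feature in a candidate. For classic (unconstrained) mining the two
methods provably return the same frequent sets, and the suite checks both
against exhaustive subset enumeration.

### Thresholds and numerics

Both thresholds are inclusive (≥): the worked example keeps itemsets
sitting exactly on the 30 % support boundary. Support comparisons are
done on integer counts against `min_support·n − 1e-9` so that floating
point representation of thresholds like 0.3 cannot drop a boundary
itemset; confidence uses a 1e-12 slack for the same reason. Internally
supports are exact ratios of integers; text output rounds to five decimal
places. Rule ordering is support descending, then confidence descending,
then lexicographic canonical item ids — a total order, so output files
are byte-stable.

## Bundled fixtures

`data/gastric_risk_factors.onto` covers the full 29-feature schema: a
root risk-factor class, four category subclasses (stomach condition,
personal feature, systemic condition, diet food), one feature-attribute
concept per feature under its category, cause edges from each category to
the disease concept, and additional feature-level cause edges for the
individually established causal factors (surgery history, gastritis,
stomach infection, reflux, smoking, salt intake, family history of the
disease). The category membership of each feature and the feature-level
cause edges are this package's own modelling choices where the source
material groups features only coarsely.

`data/example5.onto` reproduces the worked example's relatedness by
explicit overrides only: every feature related to the disease outcome,
plus surgery history related to smoking, milk consumption, and family
history; all other pairs unrelated. This is the minimal assignment
consistent with the example's level-3 outcome (exactly 3 surviving
3-candidates, with the milk/surgery/cancer triple then removed at 20 %
support). The example's own level-2 narrative is internally inconsistent
— it lists a 2-itemset in L2 whose support in its own data table is 0.2,
below the stated 0.3 threshold, and removes as unrelated a pair that any
single pairwise assignment consistent with the level-3 outcome must mark
related — so end-to-end mining reproduces the level-1 counts, the level-3
pruning outcome, and the support-based removal, but not the printed L2
membership. The audit log exposes every removal with its reason and
offending pair so either reading can be inspected.

## Synthetic data generator

The generator emulates the study schema — 29 categorical features with
the published value ranges, continuous quantities (BMI, age) arriving
pre-binned — not the study cohort, whose joint distribution is unknown.
Features are drawn independently from per-feature marginals (uniform
unless specified), then planted rules rewrite the consequent feature to
the planted value with probability `lift` whenever all antecedent items
are present, in list order (later rules may overwrite earlier ones).
With `lift = 1.0` the Bernoulli draw is skipped entirely, so the planted
rule holds with confidence exactly 1. All draws flow through one
`numpy` generator seeded from the spec, record-major, features in schema
order — equal specs give byte-identical tables.

Because generated features are independent apart from planted rules,
passing tests demonstrate correctness of the mining machinery and the
qualitative reduction behaviour, not anything about real patient data:
real cohorts have correlated features, missing values, and unknown
effect sizes. The published rule counts from the clinical dataset
(thousands of classic rules, ~92 % reduction) are not reproducible
because that dataset is not deposited; the evaluation module reproduces
the report *format* and the monotone behaviour (frequent-set counts
non-increasing in the support threshold, reduction percentage in
[0, 100]) on synthetic tables.

## Problem sizes used in the test suite

The worked example runs on the bundled 10-record table. Oracle and
equivalence checks use 200 random datasets of at most 12 items and 64
transactions with random thresholds — small enough for exhaustive
enumeration to serve as an independent oracle. Containment and monotone
pruning use 60 random datasets with random override-defined relatedness.
Planted-rule recovery uses 1000-record synthetic cohorts at three fixed
seeds with a lift-1.0 rule on a 0.4-marginal antecedent, mined at
support 0.2 / confidence 0.8.

## Known limitations

* No FP-growth/Eclat, no lift/leverage/conviction measures, no
  incremental mining; `any-pair-related` pruning is not anti-monotone and
  gives no containment guarantee.
* The ontology format is the package's own YAML dialect; OBO/OWL import
  is out of scope, as is any description-logic reasoning.
* Wall-clock comparison between the two miners is available
  (`--time-runs`) but hardware-dependent and never asserted.
* Missing values are simply absent items; no imputation.
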