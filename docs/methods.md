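# Methods and design notes

## Scope and model of the world

`fairfed` simulates, in one process, a consortium of hospitals ("data
stations") joined to a trusted aggregation hub. Each station holds one
patient-level clinical table and optionally a radiomics feature table; the
hub may only ever see aggregate payloads. The package's two scientific
cores are (a) the schema-on-read semantic layer that makes one query run
against five structurally different databases, and (b) the federated Cox
proportional-hazards engine whose result is provably identical to the
centralized fit.

## Triplification

Each table row becomes an RDF subject `<node-ns>/patient/<id>` with one
`rdf:type` assertion into the table class and one triple per non-missing
cell; predicates are minted per column. Design choices the RDF standardises
poorly were fixed as follows:

- **Missing cells produce no triple.** Open-world semantics: absence of a
  triple is exactly "not recorded". Missing counts at query time are
  computed as cohort size minus subjects carrying the predicate.
- **Numeric literals are `xsd:decimal` carrying the source's textual
  value**, so round-trips cannot introduce float drift; categorical codes
  stay plain strings even when they look numeric (a node that codes sex as
  1/2 keeps "1"/"2").
- **URI minting is deterministic** (url-encoded identifier and column
  names), so the same source yields byte-identical canonical N-Triples.

The extracted OWL schema holds one class per column plus one per table with
the user-confirmed column metadata (kind, description, unit label) attached
as annotations. It contains no cell values by construction — the test suite
includes a property test fuzzing this.

## Annotation and materialized closure

The consortium vocabulary ships as a small curated Turtle file: NCIt-style
value terms (OBO PURL URIs; published codes where confidently known, a
reserved synthetic block otherwise), ROO-style P-coded variable predicates,
per-variable ordered category lists, and a value-term hierarchy (T4a, T4b ⊑
T4). The per-node mapping layer is three kinds of assertion: column-class
equivalences (`owl:equivalentClass`), value mappings via minted mapping
nodes `(mapsColumn, localCode, targetTerm)`, and unit/hierarchy extras.

Instead of running an OWL reasoner at query time, the entailment is
**materialized once**: for every data triple under a mapped column the
closure adds the consortium-predicate triple for the mapped term *and all
its hierarchy ancestors*. Querying T4 therefore matches T4a/T4b-coded
subjects with plain SPARQL 1.1 and no entailment regime — deterministic,
engine-portable, idempotent (re-running the closure adds nothing), and
cheap at consortium scale (tens of thousands of triples). Explicit
"Unknown"-type codes map to their own terms rather than being dropped,
because consortium tables report them as categories; a wholly unmapped term
at a node is *flagged* in the result ("absent at node"), never silently
reported as zero — the distinction between "–" and 0 in a per-node table is
semantic, and the renderer preserves it.

## Federation contract

The hub is an in-process stand-in for a networked Personal Health Train
stack with the same message discipline: JSON-serialisable task and result
payloads, two audit-log entries per addressed node, failure isolation (a
raising node yields a marked-failed result), and no execution path from one
station to another. Because every payload is JSON-round-tripped at the
boundary, the privacy invariant — no subject URI or identifier in any
message — is a scannable property of the log rather than a promise.
Replacing `FederationHub.dispatch`'s inner call with a transport client is
the intended extension point.

Disclosure control is cell suppression: category counts 0 < c < k_min are
masked, continuous summaries with n < k_min are withheld wholesale, and
suppression propagates through pooling (never imputed as zero). The default
k_min is 5. Exploration runs that must reproduce a table with singleton
cells set `k_min=1` explicitly; model-fitting payloads (risk-set sums) are
sufficient statistics under the federation contract and bypass the guard.

## Federated Breslow Cox

Breslow tie handling is the design keystone: its risk-set sums are additive
across nodes, so each station ships, per pooled event time, the quintuple
(d, Σx over deaths, S0, S1, S2) — a payload of size O(|grid|·p²)
independent of the node's sample size. The hub's Newton–Raphson uses

- ll(β) = Σ_t [β'·xsum_t − d_t log S0_t],
- score g = Σ_t [xsum_t − d_t S1_t/S0_t],
- Hessian H = −Σ_t d_t [S2_t/S0_t − (S1_t/S0_t)(S1_t/S0_t)'],

starting at β = 0, with at most 10 step-halvings per iteration whenever a
proposed update lowers the likelihood, convergence at |Δll| < 1e-9 or
‖g‖∞ < 1e-6, a 50-iteration cap, and SEs from √diag((−H)⁻¹). Efron tie
handling would be marginally less biased with heavy ties but does not
decompose additively; the tests therefore configure their centralized
oracles to Breslow (scikit-survival) and use an Efron-based oracle only on
tie-free data, where the two coincide.

Other engine choices:

- **Event-time grid.** The union of node-local *event* times (censoring
  times excluded) with global death counts. Sharing this list is the
  standard, accepted disclosure of distributed Cox fitting — the same
  information is readable off any published Kaplan–Meier curve. For
  small-cohort settings an optional coarsening rounds times up to a
  configurable bin width; it is off by default.
- **Design matrices.** Categorical covariates are reference-coded against
  the vocabulary-ordered first *observed* level; levels unobserved anywhere
  in the training federation are pruned (a federated level-count round
  precedes planning) so no node emits an all-zero indicator. Missing
  covariate values are handled complete-case within the requested covariate
  set, with per-node dropped counts reported in the fit record; explicit
  "Unknown" categories are levels, not missing.
- **Transforms.** Box-Cox exponents for the strictly positive radiomics
  features are chosen on the grid λ ∈ {−2.0, −1.9, …, 2.0} by maximising
  the pooled profile log-likelihood −(n/2)·log σ̂²(λ) + (λ−1)·Σ log x, with
  grid ties broken toward λ = 1; centring/scale constants are pooled
  population moments of the transformed feature. Clinical covariates are
  not transformed. All constants derive from the training nodes of the
  current fold only.
- **Backward elimination** drops whole model terms by group Wald chi-square
  (identical to the scalar two-sided Wald test for single-column terms),
  largest p first while p > α (default 0.05). Eliminating everything is a
  valid outcome and returns the null model with its trace.
- **Model composition.** Stations compute linear predictors locally and
  store them under a name; only completion counts return. The combined
  clinical+radiomics model is an ordinary two-covariate federated fit over
  the stored columns.
- **Harrell concordance** is computed entirely node-locally over ordered
  pairs (i, j) comparable when t_i < t_j with subject i deceased, or
  t_i = t_j with exactly subject i deceased; prediction ties count ½. The
  implementation is vectorised O(n²); the tests check it against a plain
  pair-enumeration oracle.
- **Leave-one-dataset-out validation** tags every message with fold and
  phase, so "the held-out node contributed nothing to training" is an audit
  query, not an assumption.

## Synthetic consortium fixtures

The generator emulates a five-node head-and-neck-cancer collaboration whose
published case-mix table is the ground truth: per-variable category counts
are reproduced *exactly* (labels laid out to count and shuffled), mean age
to one decimal with the exact printed range (truncated-normal draw, SD 10
years — the per-node SDs are unpublished — followed by integer
adjustment), deceased counts exactly (continuous Weibull event times with
a case-mix-linked linear predictor, uniform censoring, and an
administrative cutoff placed at the order statistic that yields the target
event count, then rounded to integer days), and the radiomics linkage
counts exactly among eligible subjects. Joint structure beyond the
published marginals is sampled freely subject to two constraints: M1/Mx
subjects sit outside the oropharynx subgroup (making the printed cohort
sizes arithmetically consistent with the oropharynx row), and "non-
metastatic" is interpreted as "not M1" (Mx allowed). Each node uses a
different schema dialect — different column names, codings (M/F vs 1/2 vs
m/f vs V/M), a node that splits T4 into T4a/T4b, a node with an absent
overall-stage column, a node with genuinely missing tumour-location cells —
so the annotation layer is load-bearing, not decorative. A post-generation
audit re-tabulates the written CSVs against the profile and fails loudly.

What the fixtures deliberately do **not** emulate: realistic joint
dependence between case-mix variables beyond the constraints above,
realistic radiomics distributions (five lognormal-skewed features partially
correlated with the prognostic linear predictor, enough to exercise Box-Cox
and the C/R/CR composition), or the outcome associations of any real
cohort. Passing tests therefore demonstrate pipeline correctness — exact
marginal reproduction, federated/centralized equivalence, privacy
invariants — not clinical validity of any fitted model, and the
discrimination indices obtained on fixtures are not comparable to values
reported for real cohorts.

The parametric simulator used by the estimation tests is standard: T from a
Weibull baseline with hazard h₀(t)·exp(β'x) by inverse transform,
independent exponential censoring, optional time rounding to induce ties.

## Problem sizes

The shipped consortium is 1,698 subjects across five nodes (~25k data
triples at the largest node); a full pipeline build plus the consortium
table takes a few seconds, a federated Cox fit on the 1,452-subject cohort
about a second. The estimation test-bed uses cohorts of 300–1,000 subjects
and 100-replicate recovery studies, sizes at which Wald coverage and
federated/centralized agreement are already sharp.

## Known limitations

No time-varying covariates, stratification, penalisation or competing
risks; no calibration assessment beyond the CR calibration-slope check; no
SHACL-style data-quality constraints on graph shape; SQL sources must be
exported to CSV first; the in-process hub does not implement
authentication, encryption or containerised deployment — those belong to
the transport layer it stands in for.
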