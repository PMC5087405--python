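# Methods

## The model

`hlcontext` implements a two-level symbolic model of human context.
*Low-level contexts* (LLCs) are primitives a recognizer can emit directly:
an **activity** (16 types: lying_down, standing, sitting, riding_escalator,
riding_elevator, walking, running, jumping, hiking, climbing_stairs,
descending_stairs, cycling, stretching, dancing, sweeping, eating), a
**location** (8 types: home, office, yard, gym, mall, restaurant, outdoors,
transport) or an **emotion** (8 types: anger, happiness, neutral, sadness,
fear, disgust, surprise, boredom).  Each LLC belongs to one user and is valid
over a half-open interval `[start, end)`; an absent end means it is still
ongoing.  A *high-level context* (HLC) is an abstract behavioral situation —
office work, sleeping, exercising, … — composed of at most one concurrent LLC
per category.

Each HLC class is defined, per category, by a *required* flag (an existential
restriction: some component of this category must exist) and an *allowed* set
(a universal restriction: if a component exists, its type must be in the
set).  An absent optional category satisfies its universal restriction
vacuously, which is what lets office work be recognized with or without an
emotion reading.  Classification of an instance is pure set logic over its
component types; because class definitions are not mutually exclusive (lying
down at home with a neutral mood is both Sleeping and Inactivity), the full
match set is kept and a priority order — specific before general, default
`[Sleeping, Amusement, OfficeWork, HavingMeal, HouseWork, Gardening,
Commuting, Exercising, Inactivity, NoHLC]` — resolves it to the single label
that is stored and notified.  An instance matching no enabled class is
labeled `unidentified`.

## The description-logic reading and its closure

The same definitions are exported as an OWL 2 terminology
(`hlcontext.owl.export_terminology`): each class an equivalent intersection
of `some`/`only` restrictions over unions of the allowed term classes.
Because OWL reasoning assumes an open world, exported instances carry closure
axioms: for every present category the type `hasX only ({component})` (a
universal restriction over the nominal class of the component) and for every
absent category `not (hasX some Category)`.  Without these, no universal
restriction would be provable and no instance would ever classify.

`hlcontext.owl.infer_labels` evaluates memberships directly from the
serialized graphs: it parses the restrictions and closure axioms back out of
the RDF and decides each restriction exactly as a tableau reasoner would on
this fragment (existential → an asserted value of a type inside the filler;
universal → the property is closed and every closed value's type lies inside
the filler).  It shares no code or objects with the in-memory classifier,
which is why the test suite can use it as an independent second route: the
two must agree instance by instance, and do on 500 randomized instances plus
the exhaustive 1,024-triple sweep for a single-class terminology.

## The event pipeline

Incoming events are processed per user, strictly in arrival order, through
six stages: **map** (turn a label + metadata into a stored LLC, closing the
previously open LLC of the same category), **synchronize** (find the user's
LLCs valid at the event instant), **instantiate** (compose a new pending HLC
starting at that instant), **verify** (reject instances missing a start time,
holding duplicate categories, mixing users, or referencing components not
valid at the start), **classify**, and **notify** (store the instance,
finalize its predecessor at the new start, and emit a notification only when
the resolved label changed).  Every accepted event therefore yields exactly
one new HLC record, and per user the HLC intervals form a non-overlapping,
gapless chain.

Decisions taken where the behavior was genuinely open:

- **Half-open intervals.** A context is valid at its start and invalid at its
  end instant, so back-to-back contexts meet without overlap and an emotion
  ending at 11:06:40 is already absent from the context starting at 11:06:40.
- **Explicit end events.** Recognizers only announce starts, but "no emotion
  detected anymore" must reach the pipeline somehow; an end event closes the
  open LLC of its category and triggers re-derivation of the HLC without it.
  An end event that leaves no LLC valid closes the current HLC and creates
  nothing (there is no context to describe).
- **First notification.** A user's first HLC is announced only if it carries
  an actual class label; a first `unidentified` context is silent (nothing
  identifiable has happened yet).  Later transitions into `unidentified` do
  notify, unless suppressed via the pipeline flag.
- **Out-of-order arrivals.** An LLC or HLC arriving with a start earlier than
  an already-stored posterior record is spliced in: it is finalized at the
  next posterior start of its kind (and an overlapped predecessor is
  truncated), keeping chains disjoint; late HLCs emit no notification.
- **Equal start times.** Zero-length intervals are forbidden, so a new
  context starting exactly when the currently valid one of the same kind
  started *replaces* it.  This cannot occur in the synthetic streams (gaps
  are ≥ 1 s) but keeps replays of adversarial orderings consistent.
- **Timestamps** are timezone-naive at second precision (XSD dateTime lexical
  forms without zone); sub-second events are ordered by arrival.

The store is an in-memory index (per user and category, sorted by start).
RDF persistence is available through the export functions, and the
previous-valid query's SPARQL parity is a test: the native query result must
match a SPARQL engine run over the exported graph.

## The robustness experiment

The ground truth is the exhaustive enumeration of low-level combinations
classified clean — by default the 1,024 full activity×location×emotion
triples (the enumeration with absent categories, 1,376 non-empty
combinations, is available via `include_partial`).  Error injection at rate
*r* selects `round(r·N)` instances uniformly without replacement and replaces
in each, for every affected category, the term with a uniformly random
*different* term of the same category.  Accuracy is the fraction of instances
whose resolved label equals the clean label, `unidentified` counting as an
ordinary label.  The default grid crosses rates {5, 10, 20, 50}% with the
seven non-empty category subsets at 100 replicates per cell; per-replicate
generators are spawned deterministically from the experiment seed
(`SeedSequence(seed, spawn_key=(cell, replicate))`), so every cell is
independently reproducible.  A nested mode fixes one corruption order and one
replacement per instance, making the corrupted set at a lower rate a subset
of that at a higher rate — accuracy is then monotonically non-increasing in
the rate within a replicate, which the property tests exploit.

Because classification is deterministic, clean instances always score 100%
and every accuracy loss is attributable to the injected errors; analytically,
the expected drop in a cell is the rate times the probability that a random
replacement flips the label, so the high-level error can never exceed the
injected low-level error.  On a toy ruleset small enough to enumerate every
replacement outcome, the Monte-Carlo mean is checked against the exact
expectation to within three standard errors.

## The stream generator

`generate_stream` emulates recognizer output: each event draws its category
uniformly, then a type uniformly within the category and a user uniformly
among the requested population; consecutive events along the single stream
are 1–10 s apart (uniform integers), so 250,000 events for 100 users span
roughly 16 days.  What it does *not* emulate: realistic dwell times and
diurnal structure, correlated categories (people sit *in* offices), per-user
streams with independent clocks, recognizer confidence or systematic
(non-uniform) confusion patterns, and delivery delays (tests construct those
orderings explicitly).  Passing tests therefore demonstrate the pipeline's
bookkeeping and the classifier's logic under the stated noise model, not
recognition performance on real sensor data.

## The default ruleset is a reconstruction

The class definitions shipped in `data/default_rules.yaml` reconstruct a
published class diagram that is only partially recoverable from text; the
file marks which cells are anchored and which are documented defaults, and
every cell can be overridden by user configuration.  Consequences worth
knowing: `NoHLC` ships disabled (its membership conditions are nowhere
stated, and `unidentified` already covers "no known class"); the ten classes
are not declared pairwise disjoint (match sets may hold several names); and
quantitative robustness results depend on the reconstructed cells — the
qualitative structure (activity most damaging, emotion least, joint
corruption worst, high-level error below injected error) is stable, while
individual cell accuracies shift with the exact allowed sets.

## Problem sizes

Tests run the full 28-cell, 100-replicate experiment at the 1,024-instance
scale (a few seconds, thanks to memoized classification), 500-instance
dual-route equivalence, 1,000 randomized-store query checks, and replays of
a few hundred events; the acceptance script uses the same 1,024-instance,
100-replicate conditions.  Larger streams (10⁵–10⁶ events) run fine but are
not exercised in the default suite.
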