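# Methods

## Model and assumptions

The package treats each character family (gene family, cognate set) as an
independent binary trait on a fixed rooted reference tree.  Character
history is modelled as a pure gain–loss process: a family can be gained on a
branch (innovation, or arrival by lateral transfer) and lost on a branch
(deletion, lexical replacement).  The reference tree is taken as the true
vertical backbone; its quality bounds everything downstream.  Polytomies are
allowed throughout — classification trees of language families are rarely
binary — and no stage assumes bifurcation or branch lengths (lengths are
used only where stated below).

Lateral transfer is inferred purely from topological conflict: a character
needing two or more gains under the selected reconstruction is a transfer
(or parallel-innovation) candidate.  Consequences the user should keep in
mind:

* **Singletons** (one present taxon) and **tree-compatible** patterns
  (present set = one clade) are invisible: a single gain explains them on
  any tree.  `classify_detectability` reports these classes so that recall
  statements can be conditioned on the detectable (patchy) subset.
* Direction and donor are unidentifiable.  A borrowed word that entered
  English from some Romance language conflicts with the tree the same way
  whichever Romance language donated it; lateral edges therefore attach to
  the inferred origin nodes (possibly internal), never to a guessed donor
  tip.
* Transfers between lineages ancestral to the sample, and transfers from
  outside the sampled family, cannot be recovered.

## Gain–loss mapping

Reconstruction is the two-state Sankoff dynamic program with asymmetric
penalties: loss fixed at 1 (the unit of the scale), gain at `g > 0`.
Presence at the root costs one gain — the character must originate
somewhere, and scoring the root stem keeps the gain count equal to the
origin count.  A post-order pass accumulates per-node, per-state cost
tables, vectorized over all characters; a pre-order backtrace fixes states.

Tie-breaking is fully deterministic, chosen to maximize the vertical
component (the "minimal lateral" reading of ambiguous data):

1. among equal-cost assignments, fewer gains win (the DP minimizes the pair
   `(cost, gains)` lexicographically);
2. remaining ties are resolved in pre-order by preferring presence at the
   shallowest admissible node, which pushes gains toward the root.

Numerics: cost comparisons use an absolute tolerance of 1e-9; unresolvable
states carry a large finite sentinel (1e18) rather than IEEE infinities so
sums stay ordered.  `gain_cost = ∞` is accepted in the grid and substituted
by the finite bound `loss_cost · (n_leaves + 1)`, which provably forces
single origins (a root gain plus a loss per leaf is always cheaper than a
second gain).  Missing leaf states cost nothing in either state; the
backtrace imputes them and reports the imputation, so sample gaps never
manufacture losses.

The default penalty ladder is 1, 1.5, 2, 2.5, 3, 4, 6, ∞.  It brackets the
all-lateral extreme (at `g = loss = 1` a second origin is never dearer than
a loss) and the all-vertical one, with steps fine near 1–3 where selection
usually lands.  The ladder is configuration, not dogma; any strictly
increasing grid works.

## Scenario selection: the ancestral size criterion

For each penalty, the package builds per-node inventory sizes: counts of
characters inferred present at each internal node, and observed counts at
the leaves (leaf entries never vary across penalties; missing data are not
counted).  Forcing single origins inflates ancestral inventories; forcing
transfers everywhere deflates them.  The selected penalty is the one whose
ancestral distribution sits closest to the contemporary one — measured by
the two-sample Kolmogorov–Smirnov statistic (Mann–Whitney optional) — with
ties broken by **fewest total lateral events**, then by the larger penalty.
This makes the inferred network minimal twice over: minimal per character
(parsimony) and minimal across the penalty grid.

Pooling differs by mode, deliberately:

* **Genome mode** pools per-node family totals, zeros included.  Genome
  size is a physical quantity; an ancestor with zero families would be
  meaningful (and damning for a scenario).
* **Language mode** pools per-(node, concept) synonym counts and drops
  zeros from both the ancestral and the leaf pool.  Wordlists are samples
  from meaning lists: a language without a sampled word for a concept still
  expressed the concept — its word simply lies outside the sample.  An
  internal node reconstructed with zero sampled words for a concept is the
  ancestral analog of leaf missing data, not a real zero.  (In the
  six-language worked example the root carries no sampled word for
  "to count" under the preferred mapping; counting that zero would wrongly
  penalize the correct scenario.)

Candidate penalties are those at the exact minimum distance (tolerance
1e-9).  A p-value–based relaxation is available (`tolerance="pvalue"`:
every penalty whose KS test does not reject agreement at `alpha`, default
0.05, is a candidate).  It is not the default because on small instances —
few internal nodes — KS p-values are so permissive that every penalty
qualifies and the fewest-events rule would collapse the analysis to the
vertical extreme even when a strictly better-fitting penalty exists.  The
per-scheme p-values are always reported.  If all penalties produce
identical ancestral pools the selection is flagged degenerate and the
largest penalty returned.  The penalty is selected globally — one value for
all characters — since per-character selection is unidentifiable (every
character would happily pick whatever explains it with one gain).

## Parallel-evolution allowance

Some patchy characters reflect independent parallel innovation rather than
transfer.  Absent any signal in the data to separate the two, the allowance
is an explicit, conservative knob: a fraction `f` (default 0) of multi-origin
characters is excluded from edge construction.  Ranking is by *increasing*
minimal pairwise patristic distance between a character's gain nodes
(branch lengths where present, else unit branches): near-identical
innovations in adjacent lineages are the most plausible parallel
developments, while origins far apart on the tree are better explained by
contact.  Exactly `⌊f · #multi-origin⌋` characters are flagged, ties broken
by character id for determinism.

## Network construction

A character with `k ≥ 2` gains implies `k − 1` transfer events.  Because
order and direction among the origins are unknowable, the package draws all
`C(k,2)` unordered gain-node pairs and gives each weight `(k−1)/C(k,2)` — a
symmetric allocation that conserves the event count exactly (the sum of all
lateral edge weights equals the summed `k − 1` over borrowing candidates).
A star or chain allocation would assert an ordering the data cannot
support.  Edges coinciding across characters are merged by weight addition.
Node sizes record the number of characters inferred present per node under
the selected penalty — inferred ancestral genome sizes / lexicon sizes.
Exports: GML and DOT with a `kind` attribute separating vertical from
lateral edges, and a 5-column lateral edge list that round-trips weights
via `repr`.

## The simulator

`simulate` runs a continuous-time forward process down an ultrametric tree
(ultrametricity is required only when borrowing is on, since a donor must be
contemporaneous; it is checked at 1e-6 relative tolerance).  Each of the
`n_concepts` meaning slots in each alive lineage evolves independently:

* replacement at rate λ per concept per lineage per unit time — the
  resident word dies, a fresh character takes the slot.  This is the
  standard lexical-clock convention (per-slot rates), and it matters: rates
  interpreted per lineage in total would leave vocabularies essentially
  static at workable values, and a "borrowing" of a form the recipient
  already shares with the donor — which is then almost always the case —
  changes nothing observable and is undetectable in principle.
* borrowing at rate β per concept per lineage — the recipient takes the
  donor's current word for the slot, the donor drawn uniformly from the
  other lineages alive at that instant; with probability `p_syn`
  (default 0.5) the loan enters as a synonym, otherwise it replaces a
  resident word.

Implementation: one global exponential clock per inter-speciation segment
(total rate `#lineages · n_concepts · (λ+β)`), with the lineage, event type
and concept drawn at each firing — equivalent to independent per-slot
processes.  At speciations children copy the parent inventory.  Defaults
λ = 0.3, β = 0.1 on a depth-1 tree turn over roughly a quarter of slots and
borrow into a tenth — dynamic but tree-dominated vocabularies; these
defaults are for software validation, not estimates for any real family.

Ground truth records every character's originating node, every borrowing
event, and a per-word borrowed flag that survives transmission to the
leaves.  A character counts as truth-borrowed if at least one borrowed copy
reaches a leaf, mirroring real datasets in which borrowing status is
annotated on attested words.  Note that the truth's event list can include
events that left no surviving trace; scoring uses the surviving labels.

What the simulator does **not** emulate: phonological change and cognate
misjudgment (forms are opaque tokens; cognate coding is error-free), dialect
chains and gradual diffusion (transfer is instantaneous between discrete
lineages), rate heterogeneity across concepts, and borrowing from outside
the sampled family.  Passing the validation suite therefore shows the
inference machinery is correct and well-calibrated under the stated
process, not that real wordlists satisfy that process.

## Detection scoring

`evaluate_detection` cross-tabulates truth-borrowed characters with the
multi-origin borrowing candidates at the selected penalty.  Singleton and
tree-compatible borrowings are reported as technically undetectable rather
than as misses; recall is given both conditioned on the detectable subset
and unconditionally, alongside precision and the false-flag rate on
non-borrowed characters.  Undefined ratios (empty denominators) are
reported as not-applicable rather than as zeros.

On the validation conditions used by the test suite and the acceptance
script — a fixed 12-leaf depth-1 ultrametric tree, 300 concepts, λ = 0.3,
20 replicates per β ∈ {0, 0.05, 0.2} — the pipeline shows a strictly
increasing mean lateral weight in β, a false-flag rate of essentially zero
at β = 0, and recall on detectable borrowings around 20 %.  The modest
recall is the price of the double minimality above: borrowings whose
patterns a single loss can absorb are deliberately explained vertically.
These sizes keep the whole validation under a minute; they are stated here
so results can be reproduced exactly, and scale linearly if enlarged.

## Known limitations

* Everything is conditional on the reference tree; topological errors
  surface as spurious lateral edges.
* The KS statistic on small trees (few internal nodes) has little power;
  the selection then leans on the fewest-events tie-break, i.e. toward the
  vertical extreme.
* The clique weighting for `k > 2` origins is a convention; only the total
  per-character weight `k − 1` is identified by the model.
* Recall on true borrowings is intentionally conservative (see above); the
  method is built to bound lateral transfer from below, not to enumerate
  every loan.
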