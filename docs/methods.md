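# Methods

## The problem being modeled

A carbon atom-mapping model assigns every reaction of a metabolic
network a bijection between substrate and product carbons, written in
the ABC letter notation. Composing these per-reaction bijections lets
one follow any carbon through the network, which is the structural input
to ¹³C metabolic flux analysis. Two failure modes dominate in practice:
inconsistent atom numbering across reactions (computed mappings renumber
the same metabolite arbitrarily), and chemically wrong but syntactically
valid mappings. The package addresses the first with canonical
numbering and makes the second observable through label tracing.

## Canonical atom ordering

`canonical.canonical_order` is a pure function of the labeled molecular
graph (element, formal charge, bond orders). It proceeds in three
stages:

1. **Seed invariants.** Each atom gets the tuple
   *(element class, charge, −hetero, −degree, neighbor profile)* where
   element classes put carbon first, then other elements alphabetically,
   then hydrogen (Hill convention); *hetero* is the summed bond order to
   non-C/non-H neighbors, so more oxidized carbons rank earlier (a
   carboxyl carbon before a keto carbon before a methyl); the neighbor
   profile is the sorted multiset of (−atomic number, −bond order).
   These seeds were chosen so that for the common acids and sugars the
   canonical order coincides with the conventional "most oxidized chain
   end first" numbering — glucose comes out C1(aldehyde)…C6, pyruvate as
   carboxyl/keto/methyl — which keeps positions human-interpretable.
2. **Refinement.** Ranks are iterated on *(rank, sorted neighbor-rank
   profile)* to a stable partition (Morgan-style).
3. **Individualization.** If tied cells remain, each member of the
   first tied cell is individualized in turn, refinement re-run, and the
   branch with the lexicographically smallest graph certificate (node
   labels + relabeled edge list) wins. Branches that tie are automorphic
   images of each other; the first (smallest original index) is kept.
   Symmetry is never silently erased — it is reported separately.

The ordering is therefore invariant under any permutation of the input
atom numbering, up to exchanges of genuinely automorphic atoms; this is
enforced by exhaustive permutation tests (all *n*! relabelings for
fixtures with ≤ 8 atoms, seeded samples above that) and frozen golden
orders for every fixture structure. Stereochemistry is deliberately
ignored: wedge/hash information does not affect carbon connectivity and
the tracing semantics never consult it.

Symmetry orbits are computed by enumerating graph automorphisms
(element/charge/bond-order preserving self-isomorphisms, via VF2) and
taking the orbit partition. Tests check this against a brute-force
enumeration of all vertex bijections (≤ 8 atoms) and against RDKit's
canonical symmetry classes on larger structures (ATP, G6P).

## Validation semantics

`carbon_balance` compares total substrate and product carbon counts;
imbalance in other elements is informational only, because carbon models
legitimately drop protons, water, and phosphate bookkeeping.
`validate_mapping` additionally flags element-mismatched pairs,
duplicated endpoints, and — for balanced reactions — carbons absent from
the map. Mappings are accepted when carbon-complete even if heteroatoms
are unmapped: the ABC model is carbon-only. Both operations report
rather than raise; dirty data is a filtering decision, not an exception.
Note the deliberate blind spot, demonstrated in the tests: a *swapped*
but complete mapping passes every check. That is the class of error the
tracer's injection facility exists to expose.

## Model assembly

Stored reactions are canonicalized on load (atoms reordered so file
order equals canonical order, maps re-expressed) and must validate
cleanly unless the store is opened leniently. Assembly walks the user
model reaction by reaction:

* identifiers in square brackets are resolved against the store's
  BRENDA/KEGG/MetaCyc index (bare identifiers are searched across all
  namespaces; cross-namespace collisions are errors listing candidates);
* model metabolites are matched to stored instances by external id,
  then alias table, then exact name, in order, with coefficients
  expanding to repeated instances;
* stored participants missing from the model row are omitted
  automatically when they carry no carbon (water, ammonia); otherwise
  they must be named in the omit option or the build fails — silent
  dropping of carbon would corrupt letter conservation;
* substrate carbons receive letters `a…z` then `A…Z` (52 per side) in
  substrate order and canonical carbon order; product carbons inherit
  letters through the atom map; orphans created by omission receive the
  next unused letters;
* for balanced reactions the letter multisets of the two sides must
  match exactly once per letter — violations indicate an incomplete
  stored mapping and abort the build.

Custom reactions carry user ABC strings in the model CSV
(`glutamate (abcde)`); they are accepted only if each string's length
equals the canonical carbon count of the (known) structure and the
letters form a per-reaction bijection. A carbon-count annotation
(`acetyl-CoA {C:2}`) asserts a moiety restriction and is validated
against the store structure; the fixture store ships acetyl-CoA as its
2-carbon acetyl moiety with C1 = carbonyl, C2 = methyl, the convention
under which methyl-labeled pyruvate yields C2-labeled acetyl-CoA.

Symmetry handling is per entry: `ignore` emits the entry as built;
`expand` emits one additional entry per distinct relabeling induced by
the automorphism groups of participating metabolites (the unmodified
entry first, then variants in lexicographic order); `canonical` keeps
only the lexicographically smallest relabeling. Under this package's
canonical ordering, symmetric partners occupy adjacent positions (both
fumarate carboxyls rank 1–2), so fumarate's variant is the position swap
`badc` rather than the chain-order reversal `dcba` that conventional
numbering would suggest; the invariant is the automorphism itself, not
the string shape.

## Tracing

A label state is a set of *(metabolite, instance tag, canonical carbon
position)* triples. Each path step moves every engaged label to the
product position(s) carrying the same letter; reversible entries are
traversed backwards when the label sits on their product side, and
symmetry-expanded variants contribute the union of their fates. Labels
on metabolites untouched by a step (CO2 released earlier) ride along; a
step engaging no label at all is an error naming the gap. A letter with
no surviving partner (after cofactor omission) is reported as a
terminal `<lost>` fate rather than dropped.

Instance tags are caller-defined and preserved verbatim; they exist
because pooled metabolites (the two glucose-derived triose lineages
reaching pyruvate) need distinguishing in merged views. The fixture
convention tags the C1–C3 lineage (which passes the isomerase) "1" and
the C4–C6 lineage "2". The tracer is purely positional: no fractional
enrichments, no flux weighting, no isotopomer distributions — those
belong to flux-analysis software consuming the model.

`inject_error` swaps two product-side letters of one reaction, producing
a model that is well-formed (letter-conserving, validation-clean) but
chemically wrong; `diff_models` verifies the change is confined to that
reaction. The shipped swap for the aldolase entry (`b`/`e`) exchanges
the fates of the two termini of the dihydroxyacetone-phosphate half of
fructose 1,6-bisphosphate, rerouting a glucose-C1 label from the
pyruvate methyl carbon to the carboxyl carbon and onward into CO2.

## The fixture generator

Fixtures emulate a curated store for a toy central-carbon network.
Structures are hydrogen-free heavy-atom connection tables embedded in
source, written in conventional chain numbering and hand-checked against
standard structures; sugars are open-chain (ring/anomeric chemistry is
irrelevant to carbon fates and would add symmetry-free complexity).
Glycolysis is condensed to single-compartment skeleton reactions that
carry phosphate groups on the carbon skeletons but no ATP/NAD partners;
a separate hexokinase fixture with full, programmatically assembled
ATP/ADP structures (31/27 heavy atoms) exercises cofactor omission.
Atom maps are carbon-complete and encode textbook mechanisms (aldol
split C1–C3/C4–C6, isomerase chain flip, decarboxylation fates).

What the fixtures do *not* emulate: database-scale identifier
harmonization, protonation-state merging, mapping computation itself
(the store consumes pre-mapped RXN files), and real mapper error
statistics. Passing tests therefore demonstrate correctness of the
numbering/assembly/tracing machinery, not robustness to noisy
third-party mappings.

`random_molecule(seed, n_heavy)` grows a random spanning tree over ≤ 8
heavy atoms from {C, N, O} with valence caps, occasional double bonds
and at most one ring closure — enough variety to exercise the canonical
ordering's invariance without generating chemically absurd graphs.
Generation is seed-deterministic; the emitted store is byte-identical
across runs and pinned by checksum.

## Numerical and interface choices

* MDL V2000 only; V3000 is rejected with a clear error. Atom-atom map
  numbers live in atom-block columns 61–63 and are regenerated
  deterministically on write. Stoichiometry > 1 is represented by
  repeated MOL blocks.
* CSV dialect: comma-delimited, standard quoting, `+` separating
  metabolites within a column, reversibility tokens
  `reversible|irreversible|r|ir|1|0` (case-insensitive), optional header
  detected by a literal `reaction` first cell. This dialect is
  self-defined and documented here, not claimed byte-compatible with any
  particular web upload format.
* Letter capacity is 52 per reaction side; exceeding it is a hard
  capacity error, as is > 999 atoms per V2000 block.
* Automorphism enumeration is capped (10⁵ isomorphisms, 10³ symmetry
  variants per entry) to fail loudly on pathological inputs instead of
  hanging.

## Problem sizes

The exhaustive oracles run at deliberately small scale: all *n*!
permutations for fixtures up to 8 heavy atoms (40 320 canonicalizations
for fumarate), brute-force automorphism enumeration up to 8 atoms, and
seeded sampling beyond. The toy network has 17 reactions and 24
structures; the full suite (234 tests) completes in well under a
minute, and the acceptance script in seconds.

## Known limitations

* Canonical ordering ignores stereochemistry; enantiotopic carbons
  (e.g. the two arms of citrate, which enzymes distinguish) fall into
  one orbit. Prochirality-aware tracing would need stereo-aware
  automorphism filtering.
* Cross-molecule consistency of numbering (glutamine vs glutamate
  agreeing position-by-position) is an empirical property of the seed
  invariants on closely related structures, not a theorem; it holds on
  the fixture set and is pinned by tests.
* The tracer follows single positional labels; mixtures and enrichment
  fractions are out of scope.
* The mapping store is filesystem-only and assumes pre-computed,
  curated RXN mappings; no mapping algorithm is bundled.
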