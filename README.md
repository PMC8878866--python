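# atomtrail

Carbon atom-mapping models for metabolic networks: canonical atom
numbering, atom-mapping validation, automatic assembly of ABC-format
carbon transition models, and positional isotope-label tracing.

## Why

¹³C metabolic flux analysis infers fluxes from isotopic enrichment
patterns, but it needs an *atom mapping model*: a metabolic network in
which every reaction records the one-to-one correspondence between
substrate and product atoms. These models are traditionally written by
hand in the **ABC format** — one case-sensitive letter per carbon, e.g.

```
glutamine (abcde) -> glutamate (abcde)
```

for glutaminase, meaning carbon *a* of glutamine becomes carbon *a* of
glutamate. The format is human-readable but dangerous: the letter *a*
could be any of glutamine's five carbons unless every metabolite carries
a reproducible atom numbering. Computed per-reaction mappings (RXN files
from tools such as the Reaction Decoder Tool) make things worse by
renumbering the same metabolite differently in every reaction.

`atomtrail` solves both problems at desk scale:

* **Canonical numbering** — every molecule gets a deterministic,
  isomorphism-invariant atom order (Morgan-style neighborhood refinement
  with individualization; carbons first), so "glutamate carbon 3" means
  the same structural atom everywhere. Molecular symmetry is reported as
  automorphism orbits (e.g. fumarate's two interchangeable carboxyls).
* **Validation** — carbon balance and mapping-integrity filters for
  per-reaction mappings (element-matched pairs, no duplicated endpoints,
  carbon-complete).
* **Model assembly** — given a user network in a 4-column CSV format and
  a store of curated RXN mappings keyed by BRENDA/KEGG/MetaCyc
  identifiers, builds the network-wide ABC model automatically, with
  cofactor omission, user-supplied custom reactions, moiety restriction
  (acetyl-CoA as its 2-carbon acetyl group), and three symmetry modes.
* **Label tracing** — follows a labeled carbon position through reaction
  paths, and can inject a single well-formed-but-wrong letter swap into
  one reaction to demonstrate how a local mapping error corrupts label
  fates network-wide.

## Worked example

Everything below runs offline against the generated fixture store (a toy
central-carbon network: condensed glycolysis, pyruvate dehydrogenase,
glutaminase, GABA, fumarase, a cofactor-bearing hexokinase, ...).

```
$ atomtrail fixtures build store/
$ atomtrail build-model store/toy_glycolysis.csv --store store/ -o glyc.abc
$ cat glyc.abc
HK: glucose (abcdef) -> G6P (abcdef)  # source=KEGG:R00299
PGI: G6P (abcdef) <-> F6P (bcdeaf)  # source=KEGG:R00771
PFK: F6P (abcdef) -> F16BP (abcdef)  # source=KEGG:R00756
ALDO: F16BP (abcdef) <-> DHAP (aeb) + GAP (cdf)  # source=KEGG:R01068
TPI: DHAP (abc) <-> GAP (cab)  # source=KEGG:R01015
GAPDH: GAP (abc) <-> BPG13 (abc)  # source=KEGG:R01061
PGK: BPG13 (abc) <-> PG3 (abc)  # source=KEGG:R01512
PGM: PG3 (abc) <-> PG2 (abc)  # source=KEGG:R01518
ENO: PG2 (abc) <-> PEP (abc)  # source=KEGG:R00658
PK: PEP (abc) -> pyruvate (abc)  # source=KEGG:R00200
PDH: pyruvate (abc) -> acetyl-CoA (bc) + CO2 (a)  # source=KEGG:R00209
```

Letters are per reaction: substrate carbons are lettered `a, b, c, ...`
in substrate order and canonical carbon order, and each product carbon
inherits the letter of the substrate carbon it comes from. In `PGI` the
string `bcdeaf` reflects that glucose and fructose phosphates have
different canonical carbon orders (the keto carbon ranks first in the
ketose) while the chemical mapping is the identity.

Tracing a `[1-13C1]glucose` label (glucose C1 is the aldehyde carbon):

```
$ atomtrail trace glyc.abc --start glucose:1 \
      --path HK,PGI,PFK,ALDO,TPI,GAPDH,PGK,PGM,ENO,PK,PDH
acetyl-CoA C2 (instance 1)
```

The label lands on the methyl carbon of pyruvate (C3) and then on C2 of
the acetyl moiety — the textbook fate. Injecting a single letter swap
into the aldolase entry (still a perfectly well-formed model):

```
$ atomtrail trace glyc.abc --start glucose:1 --inject ALDO:b/e \
      --path HK,PGI,PFK,ALDO,TPI,GAPDH,PGK,PGM,ENO,PK,PDH
CO2 C1 (instance 1)
```

One local error reroutes the label from acetyl-CoA into the CO2 released
by pyruvate dehydrogenase — the reason atom-mapping curation matters.

Symmetry, for a fumarate-consuming reaction:

```
$ atomtrail build-model store/fumarase.csv --store store/ --symmetry expand
FUM: fumarate (abcd) <-> malate (abcd)  # source=KEGG:R01082
FUM: fumarate (badc) <-> malate (abcd)  # source=KEGG:R01082
```

Tracing fumarate C1 through both variants yields malate C1 *and* C2 —
the ambiguity a symmetric metabolite really introduces.

## Layout

```
src/atomtrail/
  chem_io.py        MDL MOL/RXN (V2000) reading/writing, map numbers
  canonical.py      canonical atom ordering, symmetry orbits
  validation.py     carbon balance + mapping integrity reports
  model_format.py   4-column model CSV and ABC text formats
  mapping_store.py  filesystem store of curated mappings, id lookup
  abc_builder.py    network-wide ABC model assembly
  tracer.py         label tracing, error injection, model diffing
  fixtures/         embedded toy network + random molecule generator
  cli.py            the `atomtrail` command
```

See `docs/methods.md` for the algorithmic details and design decisions.
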