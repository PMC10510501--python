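# Methods

## Enumeration model

The library is the closure, up to two steps, of a priced building-block
catalog under seven named transforms grouped into four reaction
families: amide (acid + amine) and ester (acid + alcohol/phenol)
formation, SNAr (electron-poor aryl halide + amine/aliphatic
alcohol/thiol) and Buchwald–Hartwig amination (aryl Cl/Br/I + amine),
and the Pd-catalyzed C–C couplings Suzuki (aryl halide + aryl/vinyl
boronic acid), Sonogashira (aryl halide + terminal alkyne) and Heck
(aryl halide + terminal olefin). Each rule carries SMARTS role patterns
for its two reagents, a SMIRKS transform, a condition class and a
leaving-group formula; the shipped set lives in
`src/diylib/data/rules.yaml` and is user-replaceable.

Step 1 reacts all unordered block pairs, including a block with itself
(two physical copies of one reagent; `allow_self_pairing=False`
disables it). Step 2 reacts each step-1 intermediate with the original
blocks only — never intermediate × intermediate — so every two-step
route consumes exactly three catalog blocks. Products are standardized
(largest organic fragment, normalization, charge neutralization — but
no tautomer canonicalization; identity is the standard InChI, whose own
mobile-H conventions govern tautomers) and deduplicated with route
merging. A molecule reachable in one step keeps its one-step route and
is not re-recorded at step 2. Products identical to a catalog block are
not recorded. Enumeration is embarrassingly parallel over pairs; the
`n_partitions` argument chunks the work and the merged result is
contractually independent of the partitioning.

### Compatibility semantics

A pairing is allowed for a rule iff

1. one molecule matches the rule's role A and the other role B (both
   assignments are tried);
2. no side pattern present on either molecule lists the rule's
   condition class among its blocking classes; and
3. no *other* main reaction with the same condition class is possible
   across the pair (ambiguity veto). Main reactions requiring a
   different additive/catalyst regime never veto: a boronic acid does
   not block an amide coupling because Suzuki chemistry needs a Pd
   catalyst that is absent under amidation conditions, whereas an
   aliphatic halide blocks everywhere it can alkylate.

Condition classes: amide/ester → coupling agent; SNAr → base only;
Buchwald/Suzuki/Sonogashira/Heck → Pd catalyst. The shipped side-pattern
set (24 patterns: aliphatic halides, acyl halides, anhydrides, sulfonyl
halides, free thiols, aldehydes under Pd, N–H azoles under base, labile
aryl esters, isocyanates, epoxides, aziridines, azides, Michael
acceptors, …) is an open, documented starting point, not a claim of
completeness; industrial pattern sets are substantially larger, and the
config format is deliberately extensible. The ambiguity veto is
re-applied to intermediates at step 2 (same code path), which may
undercount polyfunctional chemistry relative to more permissive
schedulers.

Design choices where the chemistry is underdetermined: the SNAr
"electron-poor" requirement is encoded as halogen on a six-membered
azine ring or ortho/para to a nitro group; Buchwald scope is aryl
halide + amine only; Sonogashira/Heck accept aromatic sp2 halides
(vinyl halides are rare in low-cost catalogs); Heck products are
generated E-configured (the dominant outcome); a per-pair cap of 8
distinct products guards against combinatorial blowup on
polyfunctional reagents.

### Mass balance

Every product must satisfy `formula(product) = formula(A) + formula(B)
− leaving`, where the leaving formula may contain the placeholder X
expanded over the halogens (HX for the substitutions and couplings,
H2O for acylations, X·B(OH)2 for Suzuki). Violating products are
dropped and counted; the test suite asserts zero violations across
≥1000 seeded pairings per rule.

## Greedy selection

The reaction score of a block is the number of distinct surviving
products whose routes involve it, divided by its price per gram (a
block used twice within one route counts that product once). Scores
are recomputed every iteration on the current surviving product set;
the single lowest-scoring block is removed and all products depending
on it are dropped. Ties are broken by removing the higher-priced block,
then the lexicographically greatest id, so cheaper reagents are kept
and the trace is deterministic. The implementation keeps an inverted
product↔block index with incremental deletion; its contract — identical
to from-scratch recomputation at every iteration — is enforced against
a naive oracle in the tests. This is exact bookkeeping of the stated
greedy loop, not an optimizer; no look-ahead, and no claim of global
set-cover optimality.

The budget curve emits one (blocks, products, budget) point per
iteration plus the initial state. The knee is the point of maximum
discrete curvature of products vs. budget after min-max normalization
of both axes; curvature is estimated as the turning angle between
secant slopes over a window of one tenth of the curve (pointwise second
differences would amplify sampling noise by 1/h²). A near-straight
curve is degenerate and returns the initial block count with a flag.

## Descriptor panel and gates

Nineteen descriptors per molecule, computed with RDKit: molar mass,
Crippen logP, topological PSA *including the S/P contributions* (the
convention of OpenBabel, against which the continuous descriptors are
cross-validated), H-bond acceptors (acceptor perception; the Lipinski
N+O variant is exposed alongside), H-bond donors (N/O/S bearing H),
rotatable bonds (non-strict definition: acyclic single bonds between
non-terminal heavy atoms, excluding triple-bond-adjacent bonds — chosen
because it is implementation-independent and exactly reproducible),
heavy atoms, rings, fraction of sp3 carbons, Crippen molar
refractivity, aromatic and aliphatic rings, chiral centers (assigned +
unassigned), acidic and basic group counts by configurable SMARTS
lists (carboxylic/sulfonic/phosphonic acids, tetrazoles; aliphatic
amines, amidines, guanidines), their sum, noncyclic amide count, O+N
count, and heteroatom ratio (non-C,H heavy atoms over heavy atoms).

Gates are pure threshold logic with configurable bounds. Defaults:
rule of five (mass ≤ 500, logP ≤ 5, donors ≤ 5, acceptors ≤ 10); rule
of three (mass **strictly** < 300, logP ≤ 3, donors ≤ 3, acceptors ≤ 3,
rotatable bonds ≤ 3, PSA ≤ 60); lead-like (200 ≤ mass ≤ 450, −3.5 ≤
logP ≤ 4.5, rings ≤ 4, rotatable bonds ≤ 10). All other bounds are
inclusive. Under the defaults rule-of-three compliance implies
rule-of-five compliance.

## Focused subsets

Labels are non-exclusive except the general screening set. DEL
building-block labels count main-reaction handles (amine, carboxylic
acid, aryl halide, aliphatic alcohol, thiol, boronic acid, terminal
alkyne, terminal olefin; every occurrence counts, symmetric duplicates
collapse): exactly 2 handles → `del_2site`, exactly 3 → `del_3site`;
single-handle capping blocks are computed but not labeled. Covalent
warheads (nitrile, carbamate, boronic acid, acrylamide,
chloroacetamide, vinyl sulfone, epoxide, aldehyde) split into
fragment-sized (rule of three) and drug-like (rule of five) subsets.
Amino-acid derivatives require an α-amino-acid backbone whose α-carbon
carries a side chain; bare glycine backbones are excluded because their
trivial substructure would swamp the subset. Nucleotide derivatives
match purine/pyrimidinone/cytosine-type nucleobase cores. Bioactives
are assigned only by exact InChI match against a user-supplied
annotated reference. The general screening set requires passing the
PAINS screen (published families A/B/C via RDKit's filter catalog; a
custom SMARTS mapping may substitute) and carrying none of the
unwanted reactive sites (default: the electrophile subset of the side
patterns). All pattern lists are configurable.

## Chemical space and novelty

Products are fingerprinted with Morgan/ECFP4 (radius 2) fingerprints
folded to 2048 bits (configurable) and embedded with t-SNE
(scikit-learn, Barnes–Hut, Euclidean metric on the binary matrix,
random initialization, default perplexity 70 and 1000 iterations,
seeded). The perplexity is reduced with a warning when fewer than
3× perplexity molecules are supplied; a seeded subsampling helper
supports large libraries. Novelty is a byte-exact InChI membership
test; the fraction is |novel| / |products|.

## Synthetic catalogs

The fixture generator decorates a fixed pool of simple ring/chain
cores (13 aryl, 14 alkyl, 6 halogenated azine, 5 two-slot bifunctional
cores) with requested handles; cores are chosen to introduce no side-
pattern hits unless a handle does. Handle-type counts follow largest-
remainder allocation of the requested mix; exactly
`round(bifunctional_fraction × n)` blocks carry a second handle. The
default mix (25% amines, 20% acids, 12% alcohols, 12% aryl halides, 8%
heteroaryl halides, 8% boronic acids, 5% alkynes, 5% olefins, 2%
thiols, remainder inert) mirrors a reagent catalog dominated by amino,
hydroxy, halide and carboxylic-acid functionality; prices are uniform
on [4.5, 10.0] USD/g, emulating a sub-10-USD catalog whose cheapest
member costs 4.5. What the fixtures do **not** emulate: real catalogs'
structural diversity and price clustering, salt forms, stereochemistry,
or supplier-specific error modes — so green tests demonstrate correct
mechanics, not field performance on commercial data.

A frozen 8-block micro-world (2 acids, 4 amines, aryl bromide,
phenylboronic acid) serves as the regression anchor: its full two-step
library (13 + 18 products), per-reaction counts and greedy elimination
trace were computed once by an independent naive enumerator/eliminator
and are stored in package data.

## Problem sizes and numerical notes

The shipped tests and the acceptance script run at desk scale by
design: the known-answer world has 8 blocks, the oracle-equivalence
sweeps use ≤10-block catalogs, the end-to-end run uses 60–100 blocks
(10³–10⁴ products), and embeddings use up to 3000 fingerprints. Scores
and costs are exact rational/float bookkeeping; the only stochastic
components (catalog generation, subsampling, t-SNE) are seeded and
reproducible. Degenerate inputs are defined behavior: empty libraries
tabulate to zero, an all-inert catalog enumerates to an empty library,
a straight budget curve returns a flagged degenerate knee, an empty
PAINS set passes everything with a warning, and novelty of an empty
product set is an error rather than a convention.

## Known limitations

- The side-pattern set is a documented core, far smaller than
  industrial collections; enumeration on real catalogs will be more
  permissive than a production scheduler.
- Reagent roles are matched structurally; reactivity nuances
  (sterics, electronics beyond the SNAr gate, protecting-group needs)
  are out of scope, as are yields and conditions.
- Acceptor-perception H-bond-acceptor counts have no second independent
  implementation available, so cross-validation of that single
  descriptor is by bounds (≤ N+O) and by its exactly-checked Lipinski
  variant.
- Two-step products record routes through each intermediate's preferred
  (first-recorded) one-step route; alternative first steps of the same
  intermediate are implied by the intermediate's own record rather than
  duplicated per product.
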