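# diylib

Build, select and mine **do-it-yourself virtual chemical libraries**:
large collections of synthetically accessible molecules enumerated in
one or two robust reaction steps from a small set of cheap, purchasable
building blocks. The package is aimed at medicinal-chemistry and
cheminformatics groups who want an in-house virtual screening library —
novel, low-cost and quickly synthesizable on demand — instead of relying
on external make-on-demand catalogs.

## What it does

Given a priced building-block catalog (CSV/SDF/SMILES with price per
gram), `diylib`:

1. **Enumerates** all one-step products over block pairs, and all
   two-step products of the intermediates with the *original* blocks,
   under four robust reaction families — amide and ester bond formation,
   SNAr / Buchwald–Hartwig amination of (hetero)aryl halides, and the
   Pd-catalyzed C–C couplings (Suzuki, Sonogashira, Heck). A pairing is
   allowed only if the reagent roles match, no *side-reaction* pattern is
   active under the reaction's condition class (coupling agent, base
   only, Pd catalyst), and no other main reaction of the *same* condition
   class is simultaneously possible. Products are deduplicated by
   standard InChI with full route provenance, and every product obeys the
   mass balance `formula(product) = formula(A) + formula(B) − leaving group`.
2. **Selects** the most cost-efficient block subset by iterative
   elimination on the *reaction score*

   ```
   score(b) = |{products derived from block b}| / price(b)
   ```

   removing the lowest-scoring block each iteration, and reports the
   products-vs-budget curve with its knee (the point past which extra
   budget buys few extra products).
3. **Profiles** every product with a 19-descriptor physicochemical panel
   (molar mass, logP, PSA, H-bond donors/acceptors, rotatable bonds,
   rings, Fsp3, refractivity, acidic/basic group counts, …) and flags
   rule-of-five, rule-of-three and lead-like compliance.
4. **Classifies** products into focused subsets: DNA-encoded-library
   building blocks (2 or 3 reactive handles), covalent warheads
   (fragment-sized / drug-like), nucleotide and amino-acid derivatives
   (glycine backbones excluded), user-annotated bioactives, and a
   PAINS-screened general screening set.
5. **Maps and checks novelty**: ECFP4 fingerprints, t-SNE embedding
   (perplexity 70, seeded), and byte-exact InChI novelty against
   reference sets.

A deterministic synthetic-catalog generator (`diylib.fixtures`) builds
priced catalogs with controlled reactive-group mixes so the whole
pipeline runs and is tested without any external data.

## Worked example

Enumerate and select over the bundled 8-block known-answer catalog
(2 acids, 4 amines, an aryl bromide, a boronic acid):

```sh
$ python -c "from diylib import generate_known_answer_set; \
from diylib.chem_io import write_catalog; \
write_catalog(generate_known_answer_set()[0], 'demo_catalog.csv')"

$ diy catalog validate demo_catalog.csv
8 valid blocks; price min 2.50 median 6.00 max 9.00

$ diy enumerate --catalog demo_catalog.csv --steps 2 --out demo_lib.csv
31 unique products written to demo_lib.csv (31 rows)
  amide step 1: 13
  amide step 2: 13
  buchwald step 1: 19
  buchwald step 2: 7
  suzuki step 1: 1

$ diy select --library demo_lib.csv --catalog demo_catalog.csv --keep 5 --trace demo_trace.csv
retained 5 blocks; 15 products; budget 22.50
```

The enumeration summary counts each product once per (reaction, step)
cell of its routes: the 13 step-1 amides are the 8 one-step amides plus
5 two-step products whose first step was an amide coupling. The trace
CSV logs one row per elimination — removed block, its reaction score,
products and budget remaining:

```
iteration,removed_id,score,products_remaining,budget_remaining
1,boronic_phenyl,0.111111,30,35.50
2,amine_benzyl,0.857143,24,28.50
3,acid_benzoic,1.5,15,22.50
```

The phenylboronic acid goes first: at 9 USD/g it contributes only one
product (the Suzuki biphenyl), scoring 1/9 ≈ 0.11.

The same pipeline is available as a library API
(`enumerate_step1/enumerate_step2`, `eliminate`, `compute_profile`,
`classify`, `fingerprint`/`embed`, `novelty_check`).

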