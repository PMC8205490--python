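# aragsl

Seed glucosinolate (GSL) chemotype analysis for *Arabidopsis thaliana*
accession collections.

Aliphatic GSLs are methionine-derived defense metabolites whose structure
is controlled by three epistatically interacting loci: **GS-Elong** (the
MAM side-chain elongation enzymes: MAM2 → 3-carbon, MAM1 → 4-carbon
GSLs), **GS-AOP** (AOP2 → alkenyl, AOP3 → hydroxyalkyl side chains, null
alleles → methylsulfinyl GSLs) and **GS-OH** (hydroxylation of 3-Butenyl
to 2-OH-3-Butenyl, phenotypically visible only in MAM1/AOP2
backgrounds).  Each accession's replicated seed GSL profile therefore
encodes a discrete **chemotype** — one of 3MSO, 4MSO, 3OHP, 4OHB, Allyl,
3-Butenyl, 2-OH-3-Butenyl — that geneticists, chemical ecologists and
population biologists use to map enzyme functional states across
collections without sequencing the (structurally messy) causal loci.

`aragsl` turns a long-format table of replicated seed measurements into
that full analysis:

* **profiles** — per-compound linear model `amount ~ accession +
  replicate + plate`; broad-sense heritability H² = SS_accession /
  SS_total; estimated marginal (adjusted) means per accession; PCA of
  the accession × compound matrix.
* **chemotype** — enzyme-state calls from the profile: MAM from the
  C3-vs-C4 majority (C3 = 3MT + 3MSO + 3OHP + Allyl, C4 = 4MT + 4MSO +
  4OHB + 3-Butenyl + 2-OH-3-Butenyl); AOP from the strict argmax of
  alkenyl / alkyl / MSO fractions of the short-chain pool; GS-OH from
  the 2-OH-3-Butenyl : 3-Butenyl ratio where the substrate exists; then
  the seven-way chemotype lookup.
* **envmodels** — north/south assignment against a configurable
  Pyrenees–Alps–Carpathians boundary, and OLS models of chemotype (or
  chain length) on genomic group, five climate covariates and
  geography × covariate interactions, with Type-II partial F-tests.
* **phylo** — p-distance matrices (pairwise deletion), Saitou–Nei
  neighbor joining with the Studier–Keppler criterion, outgroup rooting,
  column-resampling bootstrap, k-clade cutting and clade↔chemotype
  concordance.
* **lof** — the epistasis-conditioned loss-of-function analysis: GS-OH
  LOF carrier fractions among phenotypically informative (C4-alkenyl)
  vs masked accessions, with exact-rational arithmetic and one-sided
  Fisher enrichment tests.
* **simulate** — a synthetic cohort generator (accessions, replicated
  profiles, clade-structured sequences, environmental covariates) with
  known ground truth, so the entire pipeline is testable end to end.

## Worked example

```python
import aragsl as ag

config = ag.SimulationConfig(n_accessions=250, seed=3)
truth = ag.simulate_accessions(config)
emmeans = ag.compute_emmeans(ag.simulate_profiles(truth, config))
calls, freq = ag.classify_all(emmeans)
print(freq)
```

```
     chemotype  count  pct_classified  pct_total
          3MSO     13             5.2        5.2
          4MSO     16             6.4        6.4
          3OHP     13             5.2        5.2
          4OHB     17             6.8        6.8
         Allyl    128            51.2       51.2
     3-Butenyl      9             3.6        3.6
2-OH-3-Butenyl     54            21.6       21.6
```

Each accession is called from its adjusted means; for instance the first
accession prints as

```
acc0000: C3=26.23, C4=3.05 umol/g -> MAM2; ratios alkenyl=0.86
alkyl=0.05 MSO=0.03 -> AOP2; GS-OH masked -> chemotype Allyl
```

i.e. its short-chain pool is dominated by 3-carbon alkenyl GSL (Allyl),
so MAM2 and AOP2 are the expressed enzymes and GS-OH is unreadable
(masked) because the accession makes no 3-Butenyl substrate.  Against
the generator's ground truth the recovery is 100.0% at the default
dominance (0.85) and heritability (0.83).

The `examples/` directory holds one short script per capability
(simulation, heritability/PCA, chemotype calling, environment models,
haplotype trees, LOF frequencies); each prints the numbers it computes
and a line on what they mean.

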