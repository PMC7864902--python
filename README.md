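# protract

Poly-proline tract (PPT) profiling of protein sequences, gene-set
enrichment statistics, and quantification of the standard translation
assays used to characterise eIF5A function: western-blot densitometry
normalization, qPCR relative expression, and polysome-profile area
ratios.

## The scientific problem

Runs of three or more consecutive prolines stall the ribosome during
elongation; the stall is resolved by the hypusinated translation factor
eIF5A. When eIF5A function is reduced, proteins rich in poly-proline
tracts are synthesised less efficiently. Two quantitative questions
follow:

1. **Is a disease gene set enriched for PPT-containing proteins?**
   Given per-protein PPT profiles, the gene set (e.g. the
   microcephaly-associated genes, MAGs) and the proteome background
   form a 2×2 table of ≥1-PPT carrier status. Association is tested
   with the uncorrected Pearson chi-square (df = 1),

   χ² = n(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)],   p = erfc(√(χ²/2)),

   and effect size is the cross-product odds ratio with its Wald
   (Woolf) 95 % interval, exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d)),
   z = 1.959964. Gene-set members are additionally ranked by their
   proline content in PPTs (total prolines in tracts, ties broken by
   longest tract, then tract count, then identifier).

2. **Do the wet-lab readouts show an elongation defect?** The package
   implements the blot normalization

   ab ratio = (Tab / mean Tab) / (Cab / mean Cab),

   where Tab is the test-antibody and Cab the control-antibody signal
   and means run over all lanes of one blot (for hypusination, total
   eIF5A is the control of the hypusine signal); Student's unpaired
   t-test for group comparison; 2^−ΔCT relative expression against a
   reference gene; and segmentation of A254 sucrose-gradient traces
   into 40S/60S/80S/polysome regions with baseline-corrected areas,
   reporting the polysome-to-monosome ratio P/M = Σ polysome areas /
   80S area and the 60S/80S ratio.

Because the curated catalogues and instrument traces behind such
studies are rarely deposited, the package ships seeded synthetic-data
generators (`protract.synthetic`) that plant known ground truth —
tracts at recorded positions, true peak areas, true group effects — so
every stage is tested by recovery against truth.

## Worked example

The enrichment stage applied to the published MAG carrier counts
(198/685 gene-set vs 4366/17981 background carriers):

```sh
$ protract enrich --counts "198,487,4366,13615" --out enrichment.json
INFO protract: chi2=7.6375 p=0.005717 OR=1.2679
```

`enrichment.json` then contains

```json
{
  "table": {"a": 198, "b": 487, "c": 4366, "d": 13615},
  "chi2": 7.637490158818464,
  "p_value": 0.005716740728972475,
  "odds_ratio": 1.2678566221530758,
  "ci_low": 1.0710640400728138,
  "ci_high": 1.5008070051797535,
  "fraction_set": 0.28905109489051095,
  "fraction_background": 0.24281185696012458
}
```

i.e. 28.9 % of the gene set versus 24.3 % of the background carry at
least one PPT — a modest but significant enrichment (χ² = 7.64,
OR = 1.27, 95 % CI 1.07–1.50, P = 0.0057).

A fully synthetic round trip — generate a 1000-protein proteome whose
gene-set class carries tracts at twice the background rate, scan it,
and test the planted enrichment:

```sh
$ cat spec.yaml
n_set: 250
n_background: 750
p_ppt_set: 0.5
p_ppt_background: 0.25
seq_len_range: [80, 200]

$ protract simulate proteome --spec spec.yaml --seed 5 --out-dir sim
$ protract scan --fasta sim/proteome.fasta --out profiles.tsv
INFO protract.ppt_scan: scanned 1000 records (min_tract_len=3): 305 with >=1 PPT
$ protract enrich --profiles profiles.tsv --gene-set sim/gene_set.txt --out enr.json
INFO protract: chi2=54.9892 p=1.212e-13 OR=3.0226
```

The recovered odds ratio (≈3.0) matches the planted rate ratio
(0.5 vs 0.25 carrier probability corresponds to a true OR of 3), and
`sim/truth_tracts.tsv` records every planted tract so the scan output
can be checked exactly. `protract rank`, `protract blot`,
`protract qpcr` and `protract polysome` drive the remaining stages;
every command writes a `*.provenance.json` with its parameters and the
package version.

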