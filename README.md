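# scdscan

Census of **S/T-Q cluster domains (SCDs)** in protein sequences.

The DNA-damage-response kinases Tel1/Mec1 (yeast) and ATM/ATR (human)
phosphorylate substrates at S/T-Q motifs — a serine or threonine
immediately followed by glutamine.  In many substrates these motifs are
concentrated in short stretches, the SCD: at least *k* S/T-Q motifs
within a span of at most *W* residues (default *k* = 3, *W* = 50).
`scdscan` detects such clusters in any protein FASTA, asks how many
cluster-containing proteins a proteome would yield *by chance*, and
provides the downstream statistics used to interpret a census:
overlap tests against experimental protein lists, term enrichment,
a log-normal fit of census protein lengths, and frequency profiles of
residues flanking phosphorylated S/T-Q sites.

## The model at the core

Motif occurrences along a protein of length *L<sub>i</sub>* are treated
as a point process with per-residue rate λ<sub>i</sub> (estimated as
*m<sub>i</sub>* / *L<sub>i</sub>*, or from pooled counts).  The chance
event "protein *i* contains an SCD" is the scan-statistic event that
some window of ≤ *W* residues holds ≥ *k* motif events; its probability
*p<sub>i</sub>* is computed by seeded Monte Carlo (with exhaustive
enumeration and a closed-form scan approximation as cross-checks).
Each protein is then a Bernoulli trial, so

* expected census size = Σ<sub>i</sub> *p<sub>i</sub>*, and
* the observed census size is Poisson-binomial distributed; its exact
  upper tail P(X ≥ observed) is the census significance.

Two event models are provided: the classic independent-indicator
idealization, and a sequence-faithful *dipeptide* model (default) that
accounts for the two-residue motif footprint — adjacent S/T-Q motifs
are impossible, and given λ alone that law is exact (see
`docs/methods.md`).

Overlaps with external lists use the exact hypergeometric upper tail
P(X ≥ x) with expected overlap *nK/N*; term enrichment applies
Bonferroni and Benjamini–Hochberg corrections over the tested terms;
the length distribution is tested with Pearson's chi-square against a
log-normal fit by maximum likelihood (df = bins − 3).

## Worked example

Everything below runs on synthetic data generated by the package itself
(no downloads).  Generate a 500-protein proteome with 25 planted SCDs,
scan it, and test the census against the chance model:

```sh
scdscan synth --out-dir fixtures --n-proteins 500 --planted 25 \
              --n-sites 200 --n-terms 15 --seed 42
scdscan scan --fasta fixtures/proteome.fasta --out census.tsv --bed census.bed
scdscan null --fasta fixtures/proteome.fasta --lambda-mode global_per_residue \
             --n-sims 50000 --seed 17 --out null.tsv
```

which prints

```
census_size     61
n_regions       62
expected_census 36.32248
observed_census 61
p_value         4.61131e-05
tail_method     exact_dp
```

Reading: 61 of the 500 proteins contain an SCD.  Under the chance model
only ~36 were expected — the 25 planted clusters sit on top of the
background, and the Poisson-binomial tail (p ≈ 5 × 10⁻⁵) flags the
excess.  The census TSV lists each maximal region with 1-based
inclusive coordinates, span and member motif positions:

```
protein_id  start  end  span  n_motifs  motif_positions
SYN00005    77     119  43    3         77,86,118
SYN00010    99     127  29    3         99,123,126
```

Downstream commands operate on these outputs: `scdscan sweep` scans a
(k, W) definition grid, `scdscan overlap` tests the census against an
external id list, `scdscan enrich` computes term enrichment from a GAF
or two-column TSV, `scdscan goffit` fits the census length
distribution, and `scdscan flank` builds the ±5-residue profile around
phosphosites (optionally restricted to sites inside or outside SCDs).
The same commands apply unchanged to a real proteome FASTA (e.g. a
UniProt download): census counts on real data depend on the database
release used, so they are reported, not asserted.

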