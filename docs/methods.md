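# Methods

This note records the models the package implements, the defaults and
why, the numerical choices, and what the synthetic cohort can and
cannot demonstrate.

## Variant taxonomy

Small variants pass quality filters (QUAL > 50, read depth > 8, allele
balance in [0.25, 0.75] or > 0.9 for homozygotes), a quality-depth
filter, rarity filters (gnomAD AF ≤ 0.001 and presence in fewer than 10
in-house panel samples), and a CADD Phred ≥ 10 cutoff from which
loss-of-function and splice-site variants are exempt. Two conventions
deserve flagging:

- **Quality-depth direction.** The source pipelines list "quality depth
  (QUAL / reads with alternate allele) < 1.5" among the filters without
  stating keep-or-remove. We *remove* variants with QD < 1.5, matching
  the conventional low-QD exclusion. `FilterConfig.min_quality_depth`
  makes the threshold (and hence the behaviour) configurable.
- **CADD boundary.** The cutoff is inclusive (≥ 10): a CADD 10.0
  missense passes, a 9.9 one does not.

Classification is per (variant, gene) pair, so one variant can label
several genes and carry several labels. Genic labels come from the
annotation (stopgain/frameshift → LOF, missense → missense, a
splice-disruption flag → splice_site — the flag is an *input* column, no
effect prediction happens in-repo) or from position: UTRs, intronic,
and strand-aware 1-kbp windows upstream of the TSS / downstream of the
TES, measured from the boundary base inclusive. Regulatory labels
(promoter = ChromHMM states 1–3, enhancer = 4–7, silencer = 12) apply
when the position falls in a matching segment within 50 kbp of any
gene's TSS. Coordinates are 0-based half-open internally; VCF and GTF
are converted at the I/O boundary.

The 25-class set is 11 SNV + 8 SV + 6 STR classes. The exact membership
is a reconstruction (the source enumerates locations without printing
the partition); intronic SNVs are included and are CADD-filtered like
the other non-coding classes. The list lives in one place
(`twohit.variants.ALL_CLASSES`) so it can be re-aligned if needed.

CNV calls of the same type merge transitively when they overlap or when
the gap is both < 20% of the larger call's length and < 50 kbp. SV gene
labels are geometric: encapsulating (SV ⊇ gene), interstitial
(SV ⊆ gene), or a strand-aware 5′/3′ overhang. STR expansions require a
locus called in > 95% of samples with nonzero variance; the threshold
is the locus mean plus three *sample* (n−1) standard deviations over
one call per individual, and the flagged call must exceed it strictly.

Inheritance: an SNV is inherited from whichever parent carries the
alternate allele (genotype matching, not phase; both parents →
unresolved, neither → de novo); an SV needs > 50% reciprocal overlap
(strict — exactly 50% is not inherited) with a same-type parental call;
an STR needs an exact parental repeat-length match (tolerance
configurable). Individuals without two genotyped parents stay
unresolved.

## Differential expression

The DE engine is an in-house negative-binomial log-linear model, fitted
by Fisher scoring vectorised across genes (all genes share the design
matrix, so the normal equations batch into einsums). Counts have
variance μ + αμ²; the offset is the log library size. Dispersions are
method-of-moments estimates pooled *within design cells* (so real group
differences do not inflate α), shrunk 50/50 on the log scale toward a
fitted α(m) = a₀ + a₁/m mean–dispersion trend. The group coefficient is
tested by a 1-df likelihood-ratio chi-square with the dispersion held
fixed between the nested fits. This is a deliberate re-implementation
of the edgeR-style quasi-likelihood workflow, validated by properties —
type-I error within 3 binomial SEs of nominal on 1000-gene null
simulations, ≥ 0.9 power on planted 4-fold changes — and cross-checked
in the test suite against edgeR itself (run via Rscript as an
independent oracle; fold changes correlate > 0.98, p-value ranks > 0.8,
which is the expected level of agreement between an LRT and a QL
F-test, not numerical identity).

The global comparison (19 carriers vs 13 noncarriers, family as a
categorical covariate, replicate-level columns) is run once per
leave-one-sample-out subset — all replicates of one individual removed
at a time — and the reported set is the intersection of the 32
per-iteration FDR < 0.05 sets. The intersection is the robustness
mechanism; kinship-model corrections are out of scope. Trio comparisons
(offspring vs one parent, 3 vs 3 replicates, no covariates) threshold
at |log2FC| > 0.5 and BH FDR < 0.05, after removing genes expressed
(nonzero count) in under 25% of replicates. The default low-expression
rule for the global test is ≥ 10 counts in ≥ 70% of the smaller group's
columns.

## Outlier expression

Per individual: median TPM over the three replicates → log2(x + 1) →
per-gene z across individuals. Population (ddof = 0) standard
deviations are used, so for values (1,1,1,1,9) the maximum sits at
exactly z = 2 and the strict |z| > 2 rule excludes it — all printed
thresholds (0.2 TPM, |z| > 2, 25%, FDR 0.05) are strict as printed.
The latent-factor correction replaces a PEER fit with the top singular
component of the z matrix, subtracted as a rank-1 term; with one factor
and no covariates the two are near-equivalent, and this keeps the
package dependency-free. Rows are re-standardised afterwards —
otherwise the |z| > 2 rule would no longer be calibrated. Zero-variance
genes are dropped with a warning.

## Family patterns, splicing, ASE

Pattern semantics: *unique* = changed against both parents; *shared
with the carrier parent* = changed only against the noncarrier parent;
*shared with the noncarrier parent* = the mirror image. The three sets
partition the union of the two per-parent sets by construction. The
"paired Mann-Whitney" cohort contrast is implemented as the Wilcoxon
signed-rank test (its standard paired analogue), exact for n ≤ 25
without ties; it runs on per-offspring proportions by default, counts
by flag, since the source is ambiguous. For ASE the per-parent sets are
presence sets (the parent has ASE for the gene), not DE sets.

Splicing calls are isoforms with FDR < 0.05 whose gene shows no
gene-level DE in the same comparison — separating usage shifts from
dosage — using the same NB engine at both levels (the original used
DESeq2; same substitution rationale as above). Single-isoform genes are
excluded (their isoform test is identical to the gene test); genes need
more than 2 total counts.

ASE uses the exact two-sided binomial test at p = 0.5 (minimum-
likelihood two-sided convention) on haplotype read counts, testing
genes with total > 10 reads, BH-corrected within each individual and
called at FDR < 0.05. The source text prints "FDR > 0.05" at one point;
we treat that as a typo for < 0.05 — the stated Benjamini-Hochberg
usage and every other threshold in the text point the same way. An ASE
call is flagged when a phased coding-class variant (LOF, missense,
splice-site) lies on the overexpressed haplotype; unphased variants
warn and never flag. Haplotype counts and phase are input tables —
read-backed phasing is out of scope.

## Enrichment, burden, synergy

The unit of analysis is the (gene, individual) pair pooled within a
stratum; the background is expressed protein-coding genes × the
stratum's individuals. For each (class, change type, stratum): a = units
with variant and change, b = variant only, c = change only, d = neither;
two-sided Fisher exact p; odds ratio with a 95% Wald CI on the log OR
using a Haldane–Anscombe 0.5 correction when any cell is zero (the p is
always exact); BH across the 25 classes within each (change type,
stratum), mirroring per-forest-plot reporting. A gene with several
variants of one class counts once per (gene, individual, class) but in
every class it hits. Default strata: all individuals, carrier children,
carrier parents, noncarrier parents, and carrier children restricted to
carrier-parent- or noncarrier-parent-inherited variants. A per-gene
(rather than per-unit) mode was considered and set aside: per-person
outlier and variant data make the unit pooling the natural reading.

Burden: one-tailed (greater) Welch t-tests of per-unit variant counts,
outlier vs non-outlier units, aggregate and per class (BH across
classes), with restricted aggregates for configured gene sets
(intolerant = pLI > 0.9 or RVIS percentile < 20; brain-preferential =
expression > 2 SD above the cross-tissue median, both strict).

Synergy genes are the triple intersection — global-DE gene, outlier in
a specific deletion carrier, second-hit variant in that carrier
inherited from the noncarrier parent — emitted per (gene, carrier) with
the supporting variant, global log2FC, and outlier z.

## Brain network

Edges with probability weight > 2.0 (strict) are kept, duplicates
collapse to the maximum, self-loops drop; path weight is 1/probability.
The observed statistic is the mean Dijkstra distance over all pairs
(second-hit coding gene, expression-change gene), a ≠ b, disconnected
and absent pairs excluded from the mean but counted and reported rather
than assigned a sentinel. Second-hit coding classes default to {LOF,
missense, splice_site, STR_exonic, DEL/DUP encapsulating}. Permutations
relabel *all* network nodes uniformly (topology fixed); the wording
supports relabelling only the tagged nodes too, and the seed-driven
generator makes the two equivalent in distribution here. z =
(permuted mean − observed)/permuted SD, so z > 0 means the observed
sets are closer; the one-tailed p is Φ(−z) for the observed-smaller
alternative, with an add-one empirical p reported alongside (the
empirical p is the calibration-tested quantity). BH across offspring;
the cohort-level contrast is the paired signed-rank test of observed vs
permuted means.

## Synthetic cohort: what it emulates and what it does not

The pedigree is a fixed template reproducing the studied cohort's
structure: five families, 32 individuals, 19 carriers/13 noncarriers,
10 carrier children, six discordant parent couples (one family with
two), three grandparent couples, four noncarrier siblings; 13 trios
with carrier offspring (9 carrier children + 4 carrier parents against
grandparents) and 4 noncarrier-child trios. One carrier child has an
ungenotyped father so that exactly 9 of the 10 carrier children form
complete trios, as in the cohort. The seed drives everything stochastic
downstream; the structure itself is deterministic.

Defaults and rationale (chosen once; effect sizes are placeholders for
power studies, not anchored to any measured value):

| parameter | default | rationale |
|---|---|---|
| genes | 220 (7 deletion + 13 flanking + 100 variant-pool + 100 effect-pool) | small enough for minutes-scale runs, large enough for 25 disjoint planted classes plus null genes |
| baseline mean | log-uniform 50–1000 counts | mid-expressed genes; keeps NB noise realistic at 3 replicates |
| dispersion | uniform 0.02–0.1 | replicate-level LCL RNA-seq is technically tight |
| family effect | N(0, 0.2²) log2 shift per (family, gene), shared within family | reproduces family clustering that the latent factor must handle |
| deletion effect | −1 log2 on region genes in carriers | pure 0.5× dosage; chromatin-contact effects on flanking genes are not modelled mechanistically (they can be planted as cis effects) |
| downstream genes | 24 genes, ±0.6 log2 in all carriers | deletion-responsive genes outside the region, so the synergy triple is realisable; placed on non-coding-variant host genes so coding-class outlier signals stay clean (synergy hits are then mostly non-coding, as observed) |
| cis effects | per class, e.g. LOF −1, regulatory ±0.6 | placeholders; applied to every carrier of the planted variant |
| outlier shift | 4 × the realised cross-individual SD | injected post-simulation against the measured SD so the planted z is what it claims |
| isoform usage | (0.7, 0.3) baseline, shift to 0.9 | two isoforms per gene, binomial split conserving gene totals |
| ASE | fraction 0.85 at ~200 reads | comfortably detectable at the > 10-read rule |
| network | 1500 supra- + 300 sub-threshold random edges; planted mode wires 80% of (second-hit, changed) pairs at probability 3.2–4.0 | null mode is label-independent (calibration); planted mode gives unambiguous proximity |

Planted variants carry up the pedigree (child → parent → grandparent
chain) so no planted allele is an accidental de novo; transmission
alternates noncarrier/carrier parent per class instance. Decoys fail
exactly one filter each (CADD 9, AF 0.01, QUAL 40, depth 5, allele
balance 0.1, panel count 15, QD 1.0, an invariant STR locus, an
under-called STR locus).

What passing tests therefore show: the *machinery* is correct — filters
and labels exact, statistics calibrated on their own assumptions,
planted effects recovered at the configured strengths, byte-level
determinism. What they do not show: performance on real data, where
expression is not NB with per-gene independence, family effects are not
rank-1, variant effect sizes are unknown and heterogeneous, annotations
are noisy, and the interaction network is far larger and scale-free.
The planted-effect recovery studies use a strong LOF cis effect
(−2 log2) by design; at the placeholder −1 default the per-gene outlier
z sits near the threshold, which is a statement about power at 32
individuals, not about the code.

## Numerical choices

- BH step-up implemented directly (q = min over j ≥ i of p·m/rank,
  capped at 1, monotone); verified against its definition by property
  tests.
- NB fits: ridge 1e-8 on the normal equations, η clipped to ±30,
  convergence at 1e-8 max coefficient change, 50 iterations;
  non-converged genes are marked untested rather than reported.
- Fisher p from `scipy.stats.fisher_exact`; exactness is verified
  against a rational-arithmetic hypergeometric enumeration for every
  table with total ≤ 20.
- Dijkstra from networkx; verified against exhaustive simple-path
  enumeration on random graphs with ≤ 8 nodes.
- Exact binomial from `scipy.stats.binomtest`; verified against direct
  tail enumeration for n ≤ 20.
- Ties in the signed-rank test fall back from the exact to the
  tie-corrected normal method automatically.
- All randomness flows from one integer seed per stage
  (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs, which the test suite asserts on file hashes.

## Known limitations

- No read-level data anywhere: variant calling, alignment,
  quantification, phasing, and annotation (CADD, MutationTaster,
  gnomAD) are consumed as inputs, never computed.
- The DE engine is not edgeR: p-values agree in rank, not in value.
- Kinship-corrected DE, GO/pathway enrichment, WGCNA, eQTL discovery,
  and Hi-C analyses are out of scope.
- The enrichment background is configurable but defaults to expressed
  protein-coding genes; with other backgrounds the odds ratios shift.
- Grandparent-trio offspring have second-hit sets derived from their
  children's planted variants, so their network proximity signal is
  weaker than carrier children's in planted mode.
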