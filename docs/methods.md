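# Methods

`orthodiv` re-creates, as a tested library, the comparative-transcriptomics
workflow used to contrast two closely related transcriptomes — the motivating
system being the two invasive whitefly cryptic species MEAM1 and MED of the
*Bemisia tabaci* complex, whose coding sequences differ at well under 1% of
positions. The pipeline has four analytical stages (orthology, region
annotation, context-stratified divergence, Ka/Ks selection scan) and one
generative stage (a ground-truthed transcriptome-pair simulator) that makes
every estimator testable without any external data.

## The simulator and what it emulates

Each simulated gene is a transcript with 5'UTR + CDS + 3'UTR structure. The
ancestor sequence is drawn from a first-order Markov chain over nucleotides
whose conditional C→G probability is scaled by the `cpg_enrichment` factor
and whose base distribution is re-calibrated (fixed-point on the chain's
stationary distribution) so the realized GC content matches `gc_content`
despite the CpG skew. The CDS starts with ATG, ends with a uniform stop
codon, and internal stop codons are redrawn during construction; the
reference protein attached to each gene is the exact translation of the
ancestral CDS.

Two descendant lineages then accumulate substitutions independently. The
process is a per-site, single-draw approximation rather than a
continuous-time Markov chain: per lineage, site *i* substitutes with
probability

    p_i = (d/2) · m^[CpG] · Σ_b w(b),   w(b) = κ/(κ+2) or 1/(κ+2) (ts / each tv)
                                               · ω^[nonsynonymous, CDS]
                                               · 0 if the change creates a stop

where `d = branch_divergence` is the expected number of substitutions per
non-CpG site summed over both lineages, `m = cpg_rate_multiplier` applies
when the site currently lies in a CG dinucleotide (evaluated against the
mutating sequence at draw time, sweeping left to right), `κ` is the
transition/transversion **rate** ratio (so a transition is drawn with
probability κ/(κ+2) at a neutral site), and `ω` multiplies the rate of any
amino-acid-changing target. Changes that would create a premature stop codon
carry zero rate — the standard codon-model convention. (The alternative of
keeping the stop-target rate mass and redrawing the target redistributes
that mass unevenly onto stop-adjacent codon positions; a deterministic
expected-rate calculation shows it inflates recovered Ka/Ks by ~14% at
ω = 0.2, so it was not used.) The terminal stop codon evolves neutrally and
carries no synonymous/nonsynonymous label.

At the sub-5% divergences this targets, the probability of two hits at one
site within a lineage is ≲ (d/2)², i.e. a relative multiple-hit bias of
order d/4 — below every tolerance used here. The single draw keeps the truth
log exact: every substitution is recorded with position, region, draw-time
CpG status, transition status and synonymous status, and a master seed
spawns per-transcript child streams so fixtures are bit-reproducible.

Paralog confounders are spiked by duplicating a fraction of ancestors into
species A with extra divergence (`paralog_extra_divergence`, default 0.03
per site — a duplicate noticeably older than the speciation); each duplicate
carries its own reference protein (the translation of the duplicate's CDS),
which is what a shared-unique-protein screen must detect.

What the simulator deliberately does **not** model: indels and frameshifts
(the real workflow filters them; simulation is substitution-only),
among-gene rate heterogeneity beyond CpG/ω, codon-frequency evolution,
assembly artifacts (chimeras, fragmented transcripts) and sequencing error.
Passing tests therefore demonstrate correctness of the estimators under the
stated substitution model, not robustness to assembly noise.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| `gc_content` | 0.42 | coding GC of the whitefly ortholog set (~42.8%) |
| `cpg_enrichment` | 0.7 | observed %CpG ≈ 6.5 vs ≈ 9 expected at that GC |
| `branch_divergence` | 0.01 | non-CpG coding divergence 0.6–1%, identity 98–99% |
| `cpg_rate_multiplier` | 6.5 | measured CpG/non-CpG fold in noncoding regions |
| `kappa` | 3.0 | noncoding ts/tv counts ~1.4 ⇒ rate ratio ≈ 2·1.4 |
| `omega` | 0.225 | mean Ka/Ks of the ortholog set |
| `cds_length_range` | 300–900 bp | short assembled transcripts, mean CDS ≈ 0.5 kb |
| `paralog_fraction` | 0.1 | enough duplicates to exercise the screen |

## Orthology

All-vs-all candidate pairs are shortlisted by shared distinct 11-mers and
scored by exact affine-gap local alignment (Smith–Waterman/Gotoh via
Biopython's `PairwiseAligner`; match +1, mismatch −2, gap open −5, extend
−2, first gap residue pays the open cost). Because BLAST E-values depend on
database statistics this package does not reproduce, significance is a raw
score threshold (default 40 ≈ 40 net matched bases) documented here as the
stand-in for E < 1e-5-style cutoffs. N bases score as mismatches and are
excluded from identity denominators. Best hits break ties by score, then
aligned-span length, then lexicographic subject id, making the search
deterministic and symmetric.

Reciprocal best hits longer than 200 bp and above the 0.80 identity
reporting floor become putative orthologs; the paralog screen keeps a pair
only if both members' six-frame translated comparison against the reference
protein set yields the **same** protein as a **unique** best hit (score lead
over the runner-up ≥ `tie_margin`, default 5, BLOSUM62 with gap −11/−1,
minimum score 60 as the protein-level significance surrogate).

## Region annotation

The shared protein anchors the reading frame (best of six translated
frames; minus-strand hits reverse-complement the transcript once). The
start codon is the in-frame ATG within ±30 nucleotides of the aligned
protein start — nearest candidate wins, ties go upstream; if none is found
the CDS is anchored at the aligned protein start and the pair contributes
no 5'UTR. The stop codon is the nearest in-frame TAA/TAG/TGA within ±30
nucleotides of the position just past the last aligned codon, with the same
fallback and 3'UTR exclusion. The CDS interval includes the terminal stop
codon when found, so 5'UTR/CDS/3'UTR tile the annotated transcript.

Accepted pairs must have equal CDS lengths (the substitution-only analogue
of the indel/frameshift filter), CDS ≥ 150 bp, and no internal stop codon.
The aligned CDS is the positional codon-by-codon pairing (gap-free by
construction). UTR pairs are attached only when both members have the
region and their nucleotide alignment spans ≥ 40 gap-free, N-free columns
at ≥ 0.90 identity — the high-stringency surrogate for an E < 1e-30-style
UTR threshold; gap columns inside a UTR alignment are dropped from the
comparison.

## Divergence statistics

Divergence per stratum is substitutions divided by base pairs compared,
pooled over loci, with no multiple-hit correction (appropriate below ~5%).
The quoted SE is the standard error of per-locus divergence across loci;
the pooled point estimate is reported alongside the per-locus mean because
the two differ when loci vary in length. Columns containing N in either
member are excluded from all tallies.

Codon-position degeneracy (nondegenerate, twofold, threefold, fourfold)
comes from the universal genetic code, with changes to stop codons never
counted as synonymous; a column enters the nd/4d strata only when both
members' codons imply the same class, and stop-codon columns are excluded
from degeneracy strata while remaining in the "all" rows.

**CpG classification and its bias.** A column is CpG-context when its base
participates in a CG dinucleotide in *either* member (a both-members mode
exists behind `cpg_mode`). The either-member rule captures deamination at
ancestrally methylated sites after one lineage has mutated the CG away —
but it is intrinsically ambiguous: a CG present in exactly one member may
equally be a substitution that *created* a CG, and such columns enter the
CpG stratum as fully diverged sites. The inflation of the measured
CpG/non-CpG ratio is approximately `p_create · n_nonCpG / n_CpG`,
independent of divergence depth; under the default composition it turns a
true 4-fold rate elevation into a measured ratio near 6, and even a
multiplier of 1 measures near 2. Pairwise data cannot separate decay from
creation, so the package reports the measurement as the field defines it
and, for validation, recovers the configured multiplier from the truth
channel (`simulate.realized_context_divergence`: substitutions classified
by draw-time context, site totals from ancestral CpG content), where the
recovery is unbiased. Reported two-species CpG fold ratios should be read
with this ascertainment in mind.

Fold ratios divide stratum percent differences (CpG vs non-CpG per region,
fourfold vs nondegenerate overall); a zero or absent denominator yields an
undefined (NaN) ratio.

## Ka/Ks estimation

`ng86` implements Nei–Gojobori (1986) counting: per-codon synonymous-site
fractions among non-stop single-nucleotide changes (mutations toward stop
codons are excluded from the mutational opportunity and renormalized —
note that some implementations instead count them as nonsynonymous sites,
a legitimate convention difference of a few percent in Ks), multi-difference
codons averaged over all minimal pathways with equal weights, stop-passing
pathways excluded (falling back to the unrestricted set if every ordering
is blocked), and Jukes–Cantor correction applied separately to the
synonymous and nonsynonymous proportions. The correction is undefined at
proportions ≥ 0.75 and the result is flagged.

`yn` follows the approximate method of Yang & Nielsen (2000) in structure:

1. κ is estimated from columns whose position is fourfold-degenerate (or
   nondegenerate) in both codons, by the K80 formulas, the two class
   estimates combined weighted by site counts, clamped to [0.05, 99], with
   κ = 1 as the fallback when no class yields a valid estimate.
2. Codon frequencies are F3x4 (positional nucleotide frequencies of the
   pair), uniform, or user-supplied.
3. Site counting weights each single-nucleotide change by
   κ^[ts] · π(target codon); synonymous + nonsynonymous sites sum exactly
   to 3 per codon.
4. Pathway weights additionally carry ω on nonsynonymous steps, so
   multi-hit codons are resolved in favor of the currently estimated
   selection regime; ω iterates from 0.5 until its relative change falls
   below 1e-6 (cap 100 iterations; non-convergence is flagged and the last
   iterate returned).
5. Distances are corrected per site class with K80 on the
   transition/transversion split of the proportions — a simplification of
   the original F84-style correction that differs negligibly below ~5%
   divergence, which is the regime this package targets.

Both estimators are symmetric under argument swap, strip a terminal stop
codon pair, and refuse internal stops or ambiguous codons (enforced
upstream by annotation). Ks = 0 leaves Ka/Ks undefined; such pairs are
reported with whichever rate is defined but excluded from ratio-based
lists, mirroring the usual both-rates-defined reduction. Selection bands
are Ka/Ks > 1 (positive), 0.5 ≤ Ka/Ks ≤ 1 (relaxed) and < 0.5
(constrained): a ratio of exactly 1 is *not* counted as positive selection.
The per-pair κ̂ is itself ratio-distributed and overshoots mildly (mean
≈ 2.4–2.5 at a true κ of 2 for 500-codon genes); its effect on Ka/Ks is
about +1% and is left uncorrected.

A caution for users comparing against published per-gene tables of this
kind: synonymous- and nonsynonymous-substitution count columns are
sometimes transposed relative to the Ka > Ks rates they accompany; this
package's `s_sub`/`n_sub` always match its own `ks`/`ka` definitions.

## Validation experiments and problem sizes

`orthodiv.experiments` packages the self-validation studies, run at sizes
chosen to keep the whole suite interactive on one core: CpG-multiplier
recovery over 200 loci at m = 4 (recovered 4.0 ± sampling, measured
either-member ratio ≈ 6 as derived above); mean Ka/Ks over 200 replicate
500-codon pairs at ω = 0.2, κ = 2 under neutral composition (GC 0.5, no
CpG structure — isolating the selection parameters; recovered ≈ 0.20);
neutral ts/tv over 100 loci at κ = 1 (expected 0.5: one transition vs two
transversion targets per site); and a filter-funnel check on a 100-gene,
10%-paralog fixture (recall ≥ 0.95 at precision 1.0, with the annotation
funnel count matched exactly against the same rules applied to the truth
table). Simulation uses 8% divergence in the Ka/Ks study so each replicate
carries enough substitutions for a stable ratio; the slight Jensen
(mean-of-ratios) excess this leaves is ≈ +3%.

## Numerical and degenerate-input choices

All coordinates are 0-based half-open internally. TSV reports use `%.6g`
formatting and fixed column schemas (`pipeline.REPORT_SCHEMAS`); reruns
with the same seed are byte-identical. Empty strata are omitted from the
divergence table with a warning rather than emitted as 0/0; zero
denominators in fold ratios and Ka/Ks give NaN/undefined rather than
raising. Alignment tie-breaks, stop-codon fallbacks and κ clamps are
described above at their point of use.

## Known limitations

Direct positional CDS pairing presumes the substitution-only regime;
transcript pairs whose located CDSs differ in length are rejected rather
than gap-aligned, so on real data with indels the funnel would discard more
pairs than a codon-aware gapped aligner. The protein k-mer shortlist (4-mers,
top 6) can in principle miss a remote runner-up hit when judging uniqueness,
slightly relaxing the paralog screen for very divergent duplicates. The
divergence SE treats loci as independent and ignores shared ancestral
polymorphism. The CpG measurement bias discussed above applies to any
two-sequence analysis of this design, including published tables of the
same shape.
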