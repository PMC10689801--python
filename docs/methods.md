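# Methods

This note records the models, rules and numerical choices behind each
stage, what the synthetic communities do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Sequence primitives

Coordinates are 0-based half-open; strands are `+`/`-`.

**Exact search.** `find_exact_matches` reports every (possibly
overlapping) occurrence of a pattern and, optionally, of its reverse
complement; `N` never matches. Palindromic patterns are reported once on
the forward strand.

**Local alignment.** `local_align` is seed-and-extend: exact k-mer
anchors (default k = 13; k ≥ 11 enforced) are grouped into banded
diagonals (band 25 bp, adjacent bands merged) so that chains tolerate
small indels, chains are split at query gaps > 200 bp, each chain is
extended outward ungapped with an X-drop rule (match +1, mismatch −2,
drop 30), and the spanned region is scored by unit-cost edit distance
(edlib). Identity is matches over the query span, and `aln_len` is the
query span, so a reported alignment's identity/length thresholds are
per-alignment, never summed over fragments (the BLAST-HSP convention).
Overlapping candidates are resolved greedily by identity × length. No
E-value is computed: at the linkage thresholds (≥ 2.5 kb at ≥ 70 %
identity) any alignment is overwhelmingly significant, so the length and
identity cuts subsume a significance test.

**Terminal repeats.** The direct terminal repeat (DTR) of a scaffold is
its longest prefix that recurs as its suffix, found with the KMP failure
function (and cross-checked in tests against a brute-force scan).
`occurrences` counts all exact, possibly overlapping copies;
`covered_fraction` is the union of copy intervals over the scaffold
length — i.e. the "repeat region" is all copies, not a single copy
(the alternative reading was noted and rejected as weaker). A repeat is
low-complexity when one base exceeds 75 % of it or it is a perfect
1–3-mer tandem; this operational definition is ours.

## Viral triage

A scaffold is a provirus iff an upstream provirus caller flagged it AND
it belongs to a prokaryotic bin with completeness ≥ 50 and contamination
≤ 10 — both verdicts are consumed as tables; the callers themselves are
out of scope. A scaffold is a closed genome iff all six rules hold: DTR
present (min length 20, configurable), not a provirus, repeat not
low-complexity, no `N` in the repeat, fewer than six occurrences
(`>= 6` fails) and repeat region under 20 % of the scaffold (`>= 20 %`
fails). Taxonomy is a strict bit-score majority: phylum P wins iff its
summed bit-score exceeds half the total (ties are unclassified). A
candidate bin is discarded — its scaffolds returned to the fragment
pool — when its scaffolds resolve (per-scaffold majority) to more than
one phylum or it carries two or more terminase-large-subunit genes.
Units are restricted by default to the six phyla known to infect
prokaryotes (Dividoviricota, Duplornaviricota, Hofneiviricota,
Phixviricota, Preplasmiviricota, Uroviricota); the allow-list is a
parameter.

## Host linkage

Four channels, integrated by logical OR; every evidence link stores the
statistic that fired so it can be re-verified from the raw sequences.

* CRISPR arrays are found CRT-style with exact repeat copies: at each
  candidate start (prescreened by requiring the leading 19-mer to recur
  within one array period), repeat lengths 19–48 are tried and the one
  chaining the most copies wins, ties to the longest repeat; spacers are
  the literal inter-repeat substrings and must be 19–48 bp, so tandems
  (0 bp spacers) are not arrays. Exact copies are conservative relative
  to fuzzy-repeat CRT. Spacer-to-virus matching is exact, both strands,
  spacers > 6 bp.
* Homology uses `local_align` at identity ≥ 0.70 and length ≥ 2500 bp.
* tRNA linkage requires a full-length identical sequence, either strand;
  orientation on assembled scaffolds is arbitrary, so strand symmetry is
  deliberate (for spacers too).
* The k-mer channel counts distinct canonical 25-mers shared between the
  virus unit and the host bin; the acceptance threshold is 10 by
  default. The alignment-free tool it emulates publishes no explicit
  cutoff ("default parameters"), so 10 is our stand-in: far above chance
  (two random 10 kb sequences share none) and below any planted signal.
* A provirus scaffold is never linked against the bin that contains it.

Pairs are projected to populations and grouped as connected components
of the bipartite virus-population × host-population graph (networkx);
the union-find oracle test pins the semantics.

## Populations and shared pairs

Fragment ANI cuts the query into consecutive 500 bp windows, aligns each
to the target and accepts a window when its best alignment covers ≥ 80 %
of it; ANI is the mean window identity × 100, reported only when the
aligned fraction reaches 0.8 (viruses) or 0.5 (hosts). Because local
alignment trims mismatching ends, measured ANI at 2 % planted divergence
sits at ~98.0–98.1 rather than exactly 98. ANI is not symmetric, so
clustering uses max(ani(a,b), ani(b,a)); populations are single-linkage
components at ANI ≥ 95 with ids ordered by smallest member, making the
partition input-order invariant. A (virus-population, host-population)
combination is shared when at least two samples contain a pair in it;
one row lists all such samples.

## Quantification and expression

Unit depth is the length-weighted mean over member scaffolds, taken from
a depth TSV (a SAM adapter computes the same table from alignments when
they exist; the TSV is canonical for desk-scale testability). VPR sums
the depths of a host's paired viral bins and closed genomes — fragments
are excluded as unreliable population proxies — and divides by the host
depth; a zero-depth host yields an undefined (flagged) row, and VPR is
invariant to uniform depth scaling. RPKM = count / (kb × million mapped
reads); relative abundance divides by the summed RPKM of the (location,
sample-type) group, so each group block sums to one. TPM normalises
count/length rates to 10⁶ per replicate (exact to 1e-6 relative). A gene
is expressed iff ≥ 1 transcript maps to it in any replicate (transcript
identity ≥ 95 %, the transcript aligned over 100 % of its own length —
the gene need not be fully covered; the other reading would make short
transcripts uninformative) or it receives reads in all replicates.

## Defensome calling

All calls are re-verifiable threshold conjunctions over hit tables; the
search engines are not run. Defence: PADS hit (identity ≥ 30, E < 1e-10)
AND a PFAM domain (E < 1e-3, bit ≥ 30) listed as conserved for that
system in `data/defence_systems.yaml`. Counter-defence: the same rule on
viral genes restricted to RM accessions. AMG: KEGG hit (E < 1e-5, score
above the per-family threshold carried in the table) AND PFAM hit AND
accession on the curated list in `data/amg_accessions.yaml`; genes first
or last on their scaffold are flagged `edge_gene` rather than dropped —
a mechanised form of positional screening that would otherwise be
manual. A system is complete when every required component has at least
one called gene in the contig or bin. Both YAML maps are small
illustrative defaults (nrdA, psbA, RM pairs, cas1/cas2, TA pairs, one
marker per additional system); completeness of the curation is
explicitly not a goal, and both files are meant to be extended. Calls
are monotone in the thresholds (tested).

## Differential abundance and meta-analysis

Counts are modelled per location as NB(μ = s_j q_g, α_g): size factors
s_j by median-of-ratios over genes positive in all samples; dispersion
α_g by method of moments within groups, α = (var − μ)/μ², floored at
1e-6 and pooled as the max over the two groups; the group effect is fit
by a log-link NB GLM (statsmodels) with offset log s_j, and the Wald
statistic is referred to a t distribution with n − 2 degrees of freedom
— a small-sample guard for the plug-in dispersion that keeps the null
type-I error at or below nominal (measured ≈ 0.03 at nominal 0.05 with
n = 8 + 8). BH adjustment is applied within a location. This is a plain
NB-Wald approximation of DESeq2 — no shrinkage, no independent
filtering; the contract is parameter recovery on synthetic truth, and
one test cross-checks effect sizes against pydeseq2 (rank correlation
> 0.95, planted effects within 0.5). All-zero genes are excluded.

Genes with padj < 0.05 in the per-location stage enter a classical
DerSimonian–Laird random-effects pool: w_i = 1/se_i², Q = Σw_i(y_i−ȳ_w)²,
τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)), re-weight w*_i = 1/(se_i²+τ²),
pooled effect Σw*y/Σw*, se = (Σw*)^(−1/2), normal z test and 95 % CI.
k = 1 returns the input effect exactly. The estimator is cross-checked
against R metafor's `rma(method="DL")` in a test. Positive effects mean
seawater-enriched (configurable flip); directions are rolled up per
defence system. REML would be the modern alternative; DL was chosen as
the classical moment estimator and the closed-form test anchor.

## Synthetic communities

The generator emulates exactly the inputs the pipeline consumes:
uniform-i.i.d. ACGT scaffolds (no GC bias, no repeats beyond what is
planted), host bins of two 15 kb scaffolds, 10 kb phages (the 5 kb
scaffold floor of the analysis is enforced), and per channel: a 3 kb
homology block copied at ≤ 20 % substitution (default 10 %); a CRISPR
array with a 25–35 bp repeat and 3–8 spacers of 25–40 bp, at least one
copied exactly from the phage; an identical 75 bp tRNA inserted in both
genomes and annotated (tRNA prediction itself is out of scope); a 300 bp
exact block for the k-mer channel. DTR phages, integrated proviruses
(flagged in the provirus and bin tables), ANI population mates at a
chosen within-population divergence, log-normal per-sample depths,
defence/counter-defence/AMG hit tables with sub-threshold decoys, and
NB count tables (gene-wise dispersion, log-normal library sizes) with
planted biofilm/seawater shifts complete the picture.

Because a copied tRNA or a low-divergence homology block *is* exact
sequence sharing, the generator measures shared canonical 25-mers
between every phage and host bin in the final sequences and records the
implied k-mer links in the ground truth — truth is defined by the
emitted sequences, not by intent. Same seed, byte-identical outputs.

What passing tests on these communities shows: the decision rules,
thresholds and statistics behave exactly as specified on clean planted
signal with realistic noise in the statistical stages. What they do not
show: robustness to assembly artefacts, strain microdiversity, chimeric
scaffolds, GC/coverage biases or annotation error in real metagenomes.

Problem sizes used in the checked-in tests and acceptance script (20
phages × 10 hosts with 30 links; a 50-scaffold DTR panel; 1000 random
taxonomy tables; 8 genomes for clustering; 2000 null and 150 planted DA
genes at n = 8 per group and two locations) were chosen as the smallest
communities that exercise every rule and keep Monte-Carlo error well
inside the stated tolerances.

## Orchestration

`bioflink all` runs simulate → triage → link → populations → abundance →
defensome → meta into one directory; stages are re-runnable
individually from the files already present. Every threshold is a named
YAML config key with the study default. The manifest records the config
hash, seed, package version and SHA-256 of every output; wall-clock
timestamps go only to the stderr log, never into outputs or the
manifest, so identical seed + config reproduce a byte-identical
directory. Exit codes: 0 success, 1 runtime failure, 2 config error.

## Known limitations

* The alignment engine reports ungapped-anchored, edit-distance-scored
  regions; long indel-rich homologies may fragment.
* The k-mer channel threshold stands in for an unstated upstream
  default.
* The AMG/defence configuration is a seed list, not a curated database.
* DA is per-gene with a system-level rollup; gene-family aggregation
  before testing is not implemented.
* No read-level simulation: depth tables stand in for alignments, and
  the SAM adapter is exercised only on toy inputs.
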