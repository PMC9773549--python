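# Methods

## The probe-net model

probenet screens RNA-seq read sets for non-host sequences with a fixed
collection of 64-nt probes drawn from small-subunit rRNA (16S/18S) across all
cellular taxonomic domains (Archaea A; Bacteria B0–B6; Chloroplastida C1–C4;
Amoebozoa D; basal Eukaryota E0; Fungi F0–F6; Holozoa/Metazoa H0–H3; plus
retroelement probes, class R). The collection is a retrieval net, not a
classifier: a probe entraps reads from a cluster of related organisms, and
species identification is downstream work (contig assembly against reference
databases, confirmation with large-subunit rRNA), which this package
deliberately leaves to external tools.

The 64-nt probe length reflects the shortest sequence that is expected to be
unique, at a biologically meaningful identity level, against a background the
size of a mammalian genome; it is taken here as a fixed constant of the
method. Probes are drawn without any selection for hypervariable or conserved
rRNA regions: hypervariable-only probes would miss divergent relatives, and
conserved-only probes would sacrifice resolution, so the design samples the
source uniformly and handles the resulting within-collection similarity
("redundancy") explicitly instead.

## Alignment and statistics

All similarity decisions go through one seed-and-extend local aligner with
megablast-style defaults: contiguous 28-nt exact seed words, match +1,
mismatch −2, linear gap cost 2.5 per gap character, both strands. Raw scores
map to bit scores via the Karlin–Altschul transformation
`bits = (λ·S − ln K) / ln 2` with λ = 1.28 and K = 0.46, the constants the
NCBI blastn program applies to this scoring scheme (a perfect 64-nt alignment
is 119.3 bits). Because the constants match, bit-score cutoffs quoted in
blastn units can be used directly in configuration.

Extension is an exact Smith–Waterman confined to windows around seed
clusters. For pairs up to a few hundred nt the window covers every alignment
that can pass through a seed, so the reported raw score equals the optimal
local-alignment score whenever the optimum contains an exact seed word (this
is the property the test suite checks against an independent full-matrix
dynamic-programming oracle on hundreds of pairs). For long pairs the window
starts narrow and is regrown fourfold whenever the optimal path touches a
window edge — the usual X-drop-style locality compromise, except that the
alignment inside the final window is still exact rather than greedy.

Consequences of contiguous 28-nt seeding worth knowing:

* a 64-mer with 4 substitutions is detected whenever the substitutions leave
  one exact 28-window (94% identity, the standard detection anchor), and a
  28-mer exact match is detected;
* a 38-mer with a single *central* mismatch has no exact 28-word and is
  missed, although the same 38-mer with the mismatch within ~10 nt of an end
  is found. Detection of near-threshold short matches is position-dependent
  in seeded aligners generally; this divergence is documented rather than
  papered over.
* N bases never seed and never match (scored as mismatch), so N-runs cannot
  inflate hits.

The reporting floor defaults to 50 bits (any seeded hit clears it, since a
bare 28-match is 52.8 bits); the E-value column of the tabular output is
reported as "NA" because all cutoffs in this toolkit are bit-score based.
Ties among equal-scoring extensions resolve to the leftmost, then longest,
subject interval; ties between strands resolve to '+'. Output order is
deterministic (subjects in input order, then queries).

## Probe design, host filtering, redundancy

`generate_probes` partitions a source into windows of
`stride = floor(1000 / density)` nt (default density 10/kb, stride 100) and
draws one uniformly random admissible probe start per window, confined to the
window, so probes are structurally non-overlapping, a clean source of length
L yields exactly `floor(L / stride)` probes, and a fixed seed reproduces the
set exactly. Windows containing ambiguous bases are skipped.

Host filtering discards any probe with at least one hit against the host
database at the reporting floor. Because discard is exhaustive at the same
floor used for screening, re-screening the kept probes against the same host
database finds nothing (a fixed point the tests assert).

Redundancy is the all-vs-all statistic: the number of probes (self included)
each probe hits. Unique probes have redundancy 1; summaries bin the
collection into {1, 2, 3–5, 6–19, ≥20}. `redundancy_normalize` divides probe
readcounts by redundancy as an optional display correction; the uncorrected
values are kept alongside because the correction degrades retrieval of
conserved-region signals.

A full-scale synthetic reference collection
(`simulate.synthetic_reference_collection`) stands in for a deposited probe
list that is not redistributed here: 1017 random 64-mers with planted
conserved 32-nt blocks shared within groups, composing to 634 unique probes,
100 in pairs, 122 in groups of 3–5, and 161 in larger groups. On this
stand-in the internal aligner and an external blastn (megablast defaults)
agree exactly on the unique/non-unique classification of every probe.

## Screening, refiltering, deduplication

A screen counts, per probe, the reads with a reportable hit (both strands).
Sequence similarity is not transitive: a read can match a host-filtered probe
and still be of host origin via an intermediate sequence, and reference host
databases under-represent population polymorphism. Every matched read is
therefore re-aligned against the host database and discarded when its best
host bit score strictly exceeds a per-sample cutoff. The default cutoff is
150 bits; because retrieved reads are longer than probes, the appropriate
cutoff grows with read length, and `suggest_host_cutoff` documents (without
claiming) the heuristic of taking the bit score of a perfect alignment over
80% of the mean read length. Reads matched by several probes are allocated to
the single probe with the highest bit score (ties to the lexicographically
smallest name), so deduplicated counts partition the retained reads — the
conservation law `sum(dedup) = #retained reads` is asserted throughout.

## Normalization

Libraries differ in RNA amount and conversion efficiency, so counts are
expressed per host cell. The host-cell equivalent of a library is
`mean(per-gene mean housekeeping probe count) / 50`, with PGK1 and NSE (two
probes each) as the default "brain" panel at 50 transcripts per cell
(measured range 46–64). HMGCR ships but is excluded from the default mean
(expression ~fivefold lower). Other tissues need their own panels; the panel
is a config object.

Microbial cells per host cell divide reads per host cell by a
ribosomes-per-cell (RBPC) constant: 2000 for prokaryote classes (A, B — a
compromise for slow growth in tissue), 10000 for eukaryotic microbe classes
(C, D, E, F, H). Closed forms follow directly: one read in a 10-cell library
at 2000 RBPC is 0.0005 microbial cells per 10 host cells; one latency
transcript at 50 transcripts per infected cell is 0.02 infected cells per 10
host cells regardless of denominator. No corrections are applied for rRNA
depletion (incomplete and kit-dependent) or read/probe overlap loss — the
latter is common to housekeeping and microbial transcripts and cancels in
the ratio.

## Decontamination

Operations act on wide probe × sample batches of normalized values, each
returning a removal log that reconstructs the input exactly.
`drop_multipositive` zeroes probes positive in ≥ a fraction (default all) of
samples, the signature of reagent contamination — at the documented risk of
deleting genuine core community members. `subtract_reference` zeroes, in
every target sample, any probe positive in any sample of a reference batch
(tapwater, skin, blanks); it is monotone, binary (values drop to zero or stay),
and order-independent, so successive subtractions compose. `core_signals`
returns probes present in strictly more than a fraction (default 75%) of
samples. A name-keyed blocklist is supported, but no contaminant list ships
as authoritative, since common contaminants can themselves be disease-relevant.

## Genome stripping

Viral genomes share sequence with the host; stripping excises every
host-homologous region so residual matches are unambiguously viral. Round 0
removes low-complexity intervals (DUST-style triplet score over 64-nt
windows, threshold 2.0 — a homopolymer window scores ~30, random sequence
~0.5) and tandem arrays (≥3 copies) of curated motifs, by default the
telomeric repeat unit TAACCC that several herpesvirus genomes carry. Each
later round aligns residual segments against the host and deletes the whole
query span of every hit (deletion, not masking, so residual coordinates stay
explicit); fragments under 64 nt are dropped since they cannot anchor a
seeded read match with useful specificity. Rounds repeat until one removes
nothing — deletions create junctions and expose flanks that can themselves
match the host, which is why convergence typically takes more than one round.
Termination is guaranteed (residual length strictly decreases), the terminal
residual has zero host hits, and the per-round log records every removed
interval with its reason so alternative policies (e.g. merged envelopes,
different minimum segment lengths) can be compared on the same audit trail.

## Cost model

Costs are counted in blocks (BL): one BL compares two 100-nt units, so
aligning m units against n units costs m·n BL (1 GBL = 10^9 BL). Defaults: a
10^8-unit library against a 10^7-unit host costs 10^15 BL directly; the
probe-net first pass is 10^3 × 10^8 = 10^11 BL, and refiltering (10% of
probes positive at ~100 matches each → 10^4 units vs 10^7) another 10^11 BL;
total 2×10^11 BL, a 5000-fold reduction. These are rule-of-thumb unit counts,
not wall-clock claims.

## Synthetic data: what it emulates and what it does not

The generator realizes the statistical structure the normalization model
assumes: housekeeping transcripts at 50 copies per cell, microbial rRNA at
θ × host_cells × RBPC copies, reads sampled in proportion to copy number from
both strands with independent substitution errors, and ground-truth origins
recorded in a sidecar table. Housekeeping transcripts (230 nt, probes at
offsets 44 and 110) and rRNA sources (tiled at 10 probes/kb) are chosen so
that at the default 150-nt read length every read overlaps each housekeeping
probe window, and some rRNA probe window, by at least a seed length: the
read-capture factor is then equal (unity) for housekeeping and microbial
transcripts, which is exactly the cancellation assumption of the
normalization. Batch-wide contaminants are injected
identically into all samples, and contaminant organisms are part of the
probe-design universe, so decontamination can be validated end to end.

Sequences are i.i.d. uniform, so host and microbe share no seed words by
construction. Real data differ in ways the generator deliberately omits:
rRNA secondary-structure-dependent RT dropout (unpredictable; no allowance is
made), conserved blocks genuinely shared between microbe and host rRNA (the
reason the refilter exists at all; planted homology exercises it in tests),
population polymorphism in the host, quality-correlated error profiles, and
sparse probe coverage of long real housekeeping mRNAs (real per-probe capture
is lower than the simulated unity, but common to numerator and denominator).
Passing tests therefore demonstrate correctness of the computation and
calibration of the estimator under the model's own assumptions, not
field performance on real libraries.

Problem sizes in the shipped tests: single-organism studies of 1500–3000
reads over ~10 host-cell equivalents, 20-seed replication for recovery
checks (θ ∈ {0.01, 0.1, 1} recovered within twofold, geometric-mean bias
well inside that), stripping genomes of ~4–10 kb against ~6–8 kb host
databases, and the 1017-probe synthetic collection for the all-vs-all audit.

## Numerical and degenerate-input choices

Scores are float32 in the DP matrix (exact for half-integer scores in this
range); traceback prefers diagonal, then query-gap, then subject-gap moves.
Empty read sets screen to an empty table with a warning; an all-zero
housekeeping panel raises ("cannot normalize sample") because the library is
unusable; a genome fully consumed by stripping returns an empty residual
with a warning; sequences shorter than the word size simply produce no
seeds. Presence in decontamination means value > ε with ε = 0 by default
(an optional floor guards against numeric dust). The log2 display transform
is log2(x+1) so zeros are admissible.

## Known limitations

* Contiguous-word seeding misses short matches whose mismatches break every
  28-window (see above); discontiguous words are out of scope.
* E-value statistics are not computed; all thresholds are bit scores.
* The per-dataset host-refilter cutoff has no closed form; the per-sample
  override is the contract and the shipped heuristic is advisory.
* Redundancy counts depend on the reporting floor; near-threshold pairs can
  classify differently under other aligners' rounding (the audit trail keeps
  the underlying hits inspectable).
* The pipeline does not assemble contigs or assign taxonomy; it exports
  retained reads per probe for external tools.
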