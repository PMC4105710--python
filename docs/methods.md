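# Methods

This note documents the models and procedural choices behind pacall: what
each stage assumes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Scope and assumptions

pacall assumes a single-end 3′-tag library: each read is a genomic insert
whose 3′ end is the transcript's cleavage position, followed by a poly(A)
tail and possibly low-quality terminal bases. Read mapping is out of scope;
the pipeline consumes SAM/BAM of the clipped inserts (any aligner, or the
synthetic generator's truth alignments) and treats "uniquely mapped" as
primary, non-supplementary alignments at or above a mapping-quality floor
(default MAPQ ≥ 10), since uniqueness reporting is aligner-specific.
Paired-end handling, adapter trimming and PCR-duplicate removal are
deliberately absent.

All internal coordinates are 0-based half-open (BED convention); GFF3 and
SAM positions are converted at the I/O boundary. The cleavage coordinate of
a read is the last transcribed base in transcript orientation: the rightmost
aligned base on the plus strand, the leftmost on the minus strand.

## Stage parameters

| parameter | default | meaning |
|---|---|---|
| `min_q` | 16 | Phred threshold for terminal-segment trimming (Q2 convention) |
| `window`, `min_a`, `min_steps` | 5, 4, 7 | tail scan: window size, adenines per window, minimum completed steps |
| `min_remaining` | 20 nt | smallest clipped insert considered mappable |
| `astretch_k`, `max_mismatch` | 10, 2 | A-stretch seed: k-mer length and allowed non-A bases |
| `adjacency` | 10 nt | downstream window in which a stretch invalidates an event (an A₈ within 10 bp already primes) |
| `max_dist` | 25 bp | clustering distance to the rolling median (most sites cluster within ~24 bp; extreme wobble may exceed it, so spans are uncapped) |
| `min_mapq` | 10 | unique-alignment proxy |
| `hcs_threshold` | 5 reads | high-confidence-site flag |
| `max_ext` | 3000 nt | maximum 3′UTR extension length |
| `upstream_n` | 50 nt | signal-scan window upstream of the cleavage site |
| `motifs` | AWTAAA | IUPAC poly(A)-signal motif(s) scanned |
| `tol` | 25 bp | PA-set intersection tolerance (matches the clustering distance) |

## Numerical and procedural choices

**Quality trimming** removes only the *maximal terminal run* of sub-threshold
bases at each end; interior dips stay, because the Q2 indicator marks
terminal segments, not individual bases. The operation is idempotent.

**Tail detection.** The window starts on the 3′-terminal five bases (step 0)
and moves one base per step ("steps" count movements, not windows). Scanning
stops at the first failing window or at the 5′ end. The cut point is not
implied by the pass/fail rule alone: the last passing window may begin on a
genomic base (its one-mismatch margin). We therefore clip at the start of
the last passing window advanced past any leading non-A bases, which
guarantees the clipped read never ends in a long A run when the insert
itself was not A-rich. A read still passing at the 5′ end is
poly(A)-positive but unmappable and is rejected at the clipping step.

**A-stretch scan.** Implemented as a direct per-window count (equivalent to
exhaustively aligning a 10-A query with ≤ 2 mismatches and merging the
hits); book-ended intervals merge. Stretches are strand-oriented — A-runs
(+) and T-runs (−) — and only same-strand stretches invalidate an event,
because internal priming is strand-specific chemistry. The adjacency test is
symmetric on both strands: a stretch whose transcript-orientation start lies
0–9 bases past the cleavage position (or that contains it) discards the
event.

**Clustering.** Per (chromosome, strand), a greedy sweep admits the next
sorted coordinate iff its distance to the lower median of the cluster
*including that coordinate* is ≤ `max_dist`; the representative is thus
recomputed at every admission and is always an observed coordinate. This
tentative-admission reading is the one under which chained coordinate runs
(e.g. five coordinates 10 bp apart) remain a single cluster, which is the
intended behaviour for wobbling sites; testing against the pre-admission
median instead would split them. Mode ties break toward the smaller
coordinate for determinism; plus- and minus-strand events never co-cluster.

**Annotation.** UTRs derive from the coding span (BED12 thickStart/End, or
GFF3 CDS extent); introns are exon gaps; transcripts without CDS become
non-coding all-exon models. Extensions are blocked by features of *any* gene
on *either* strand, read literally from "overlapping no annotated feature".
Annotation itself is strand-matched, since PA sites are strand-specific by
construction. A single base of overlap with the cluster span suffices; per
gene only the highest-ranking class survives (isoform disagreements resolve
upward), and cross-gene ties at equal rank break by total overlap length,
then gene symbol.

**Lost sites** are anchored at the cluster median (the cluster's
representative); a binding site must start strictly downstream in transcript
orientation to count as lost, so sites straddling the cleavage position are
conservatively retained. Only sites within annotated 3′UTRs enter the loss
calculus.

**Upstream windows** exclude the cleavage base itself (minus-strand windows
start one base past the coordinate) and are returned 5′→3′ in transcript
orientation; truncation at contig boundaries is flagged. Motif scanning uses
IUPAC degeneracy with overlapping matches. PA-set intersection is one-to-one
and nearest-first at tolerance `tol`, making matched cardinality symmetric.

All output files are written atomically (temp file + rename), and identical
inputs yield byte-identical outputs at every stage.

## The synthetic generator

The generator emulates the features the pipeline must discriminate:
cleavage sites with ±2 nt wobble and 10–30 nt templated tails; optional
low-quality (Q2) terminal junk on 30% of reads; genes on both strands with
2–5 exon blocks, 100 nt 5′UTRs and 600–1000 nt 3′UTRs, separated by 10 kb;
1–4 PA sites per gene (always one at the distal 3′UTR end, others proximal
or up to ~900 nt into the extension zone, ≥ 130 nt apart); 5–15 miRNA
binding sites per 3′UTR placed > 10 nt from every cleavage position; and
decoy internal-priming reads at planted genomic A₁₀ runs, 10% of the
library by default. The default study fixture is 20 genes / 50 sites /
depth 50 on a 420 kb chromosome — small enough to run in about a second,
deep enough that every cluster clears the high-confidence threshold.

Three constructions make the planted truth exact rather than statistical:
the background genome is scrubbed of every A-stretch by rejection redrawing,
so decoys are the only priming templates; the eight transcript-orientation
bases ending at each cleavage position are forced to C/G, so the tail scan
clips every wobbled read exactly at its cleavage base; and poly(A) signals
are planted (with C/G guard flanks that cannot assemble an A-stretch)
upstream of an exact count of sites while the remaining upstream windows are
scrubbed motif-free, so the expected signal frequency is a rational number
the pipeline must hit exactly, not approximately.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequencer-specific error profiles (substitution
errors default to 0 because truth alignments bypass mapping; a nonzero rate
only perturbs tail detection), PCR duplicates, expression-level variation
between sites of one gene, non-templated tail additions, alignment errors
and multi-mapping, and annotation imperfections such as overlapping genes.
Real libraries will show partial rather than perfect recovery, and the
filter's false-discard rate depends on the true genome's A-richness.

## Degenerate inputs and edge behaviour

Empty reads survive trimming and are rejected at tail detection; reads
shorter than the window are negative with reason `no_tail`; whole-read tails
are rejected as `all_tail_too_short`. An empty post-filter event set
produces a complete (empty) output bundle and a distinct CLI exit code.
Malformed alignment or miRNA records are skipped with logged counts rather
than aborting the run. Cluster BED round-trips carry the summary columns
(span, count, median, mode) — member multisets are not representable in BED.

## Known limitations

The caller is single-sample; multi-sample unions are concatenation plus
re-clustering downstream. The greedy left-to-right sweep is order-dependent
by design (it matches the sorted-coordinate formulation) and is not a
probabilistic peak caller; two sites closer than ~25 bp merge. Extension
regions assume the annotation is locally complete — an unannotated gene
downstream of a 3′UTR will be absorbed into an extension. Motif discovery
is out of scope: the signal module scans user-supplied IUPAC motifs only.
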