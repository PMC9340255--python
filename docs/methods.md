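# Methods

## The measurement model

A TGIRT small-RNA library is a set of adapter-ligated inserts of roughly
15–40 nt. Each insert is a fragment of a parental small RNA: a full mature
miRNA (possibly with 1–2 non-templated 3′-added bases), an end-anchored tRNA
fragment, an rRNA fragment from a discrete cleavage region, a YRNA fragment
produced by cleavage in a single-stranded loop, or a fragment of another
small-RNA class. TGIRT reads through Watson-Crick-face base modifications and
records them as substitutions in the cDNA, so the library carries two signals
per read: where the fragment sits on its parent, and whether it passed over a
modified base.

The pipeline inverts this model read by read:

* **Alignment** is ungapped, forward-strand, with at most one substitution
  and no indels. Indels are excluded by design: RT misincorporation produces
  substitutions, and allowing gaps on 15–40-nt queries mostly manufactures
  false placements. The aligner is exact, not heuristic: the read's two
  non-overlapping half-seeds cannot both contain the single allowed
  substitution (pigeonhole), so exact-seed lookup followed by full Hamming
  verification enumerates *every* valid placement. The test suite holds this
  against a brute-force all-offsets scan on random fixtures.
* **Annotation** is hierarchical: miRNA references are probed first, then
  tRNA (with mitochondrial tRNAs and precursor trailers in the same tier),
  then rRNA (+ mitochondrial), YRNA, snoRNA, snRNA, lncRNA, mRNA. A read is
  attributed entirely to the first tier that accepts it; within a tier a
  multi-mapping read is split 1/k over the k references hit. Ties between
  genomic and mitochondrial members of a tier are resolved by this
  fractionation, not by priority.
* **The mismatch index** at position p is 100 × (weighted reads with a
  substitution at p) / (weighted reads covering p). Reads, not bases, are the
  numerator unit: a read contributes once at its (single) mismatch position.
  Non-templated miRNA tail bases are unaligned and contribute to neither
  numerator nor denominator.

## Coordinate conventions

All reported coordinates are 1-based inclusive on the reference. tRF group
profiles are aggregated per amino-acid group either 5′-anchored (members
co-add from position 1) or 3′-anchored (members co-add at the CCA-terminal
base). Canonical tRNA sites 9 and 26 are 5′-anchored offsets; the T-loop m¹A
site ("position 58" on a 76-nt tRNA) is resolved 18 bases upstream of the 3′
terminal base, because tRNA lengths vary while the T-loop sits at a fixed
distance from the (CCA-completed) 3′ end. The offset is configurable per
site. rRNA sites are absolute coordinates on their molecule (28S:1322,
28S:4530, 18S:1248).

## Parameter defaults

| parameter | default | rationale |
| --- | --- | --- |
| minimum read length | 15 nt | shorter inserts map ambiguously |
| 3′ trim `min_overlap` / `max_error_rate` | 3 / 0.1 | cutadapt-like semantics |
| 5′-adapter discard | full containment, read-within-adapter, or ≥ 8 nt read-start overlap | see below |
| alignment mismatches | ≤ 1 substitution, 0 indels | the misincorporation signal is substitutions |
| miRNA soft tail | ≤ 2 non-templated 3′ bases | known miRNA 3′-addition biology |
| seed length | 7 | ≤ floor(15/2), preserving the pigeonhole guarantee |
| tRF length cut-points | half ≥ 30; 5c ≥ 27; 5b ≥ 23; 3b ≥ 20 | placed between the observed peak sizes (32–34/27/19 and 37–38/22/18) |
| anchoring tolerance tol5/tol3 | 1 nt | ragged ends from RT/ligation edge effects |
| site report coverage floor | 10 reads | avoids 1-read 100 % artifacts; per-position tracks use floor 1 |
| cleavage `min_drop_fraction` | 0.5 of peak coverage | report only dominant steps |
| Argonaute filter | 18–24 nt, ≥ 10 samples, 500–15,000 RPM mean | the miRNA-like abundance window |

**Adapter trimming semantics.** A single pass removes everything from the
leftmost position where an adapter prefix (≥ 3 nt, ≤ 10 % Hamming error over
the full overlap) runs to or beyond the read 3′ end. Trimming is deliberately
*not* cascaded to a fixpoint: an insert whose own final bases coincide with
the adapter start by chance (probability 4⁻ᵏ for a k-base coincidence) would
otherwise lose genuine sequence, which measurably distorts fragment-subtype
boundaries. The trade-off is that re-running the trimmer on such an insert
can remove those coincident bases; the property tests document this
explicitly.

**5′-adapter discard.** A read is discarded when it contains the full 5′
adapter, when the whole trimmed read is a substring of the adapter (the
remnant of an adapter dimer — the configuration that lets adapter sequence
masquerade as a miRNA), or when the read starts with ≥ 8 nt of the adapter's
3′ end. The 8-nt floor is deliberately longer than the 3′-trimming overlap:
flagging every ≥ 3 nt coincidence would discard ~4⁻³ of genuine reads per
boundary and bias class fractions, while 4⁻⁸ ≈ 1.5 × 10⁻⁵ is negligible.

**miRNA tail tie-break.** When a placement can be read either as a terminal
substitution or as a non-templated addition, the interpretation with fewer
internal mismatches wins (the addition); on exact ties the smaller tail
(templated) is kept, so templated 3′ bases are not misreported as additions.

## The simulator: what it emulates, and what it does not

The patient FASTQs behind the published analysis are access-restricted, so
the generator stands in for them. Its defaults are the study conditions:

* class mixture miRNA 0.43 / tRF 0.20 / rRF 0.25 / YRF 0.05 / other 0.07
  (≈ 43 % miRNA vs 57 % nmsRNA);
* anchored fragment geometry — 5′ tRFs start at position 1 and 3′ tRFs end
  at the CCA end (each with a 10 % chance of a 1-nt ragged end), tRF-1s come
  from trailer records, rRF starts are drawn from discrete hotspot windows
  (placed so the canonical modification sites are covered), YRFs are the two
  sides of a fixed cleavage position in the preterminal loop;
* length peaks 22 (miRNA); 33/27/19 (tRF-5 series); 37–38/22/18 (tRF-3
  series); 20 (tRF-1); 39 (rRF); 37 (mt-rRF); 33/35/31 (YRF); 35/28 (snoRF);
* misincorporation injected per covered site with a per-site rate and
  substitution spectrum (defaults put signal at tRNA 9/26/58 and the three
  rRNA sites, including the published Glu-high / Gly-low contrast at
  position 9);
* 0/1/2 non-templated miRNA additions with probabilities 0.7/0.2/0.1;
  uniform 0.1 % per-base sequencing error; full 3′ adapter appended; small
  adapter-dimer (0.2 %) and short-insert (0.3 %) artifact fractions to
  exercise the filters.

Everything is drawn from one `numpy` Generator seeded by the config, so
output is byte-identical under a fixed seed, and every read has exactly one
truth record (source coordinates, injected events, added bases, sequencing
errors).

The bundled reference set is likewise synthetic (ids end in `_syn`): 76-nt
CCA-ended mature tRNAs with the landmark bases placed at the canonical
offsets, rRNA surrogates long enough to hold the absolute sites at their
literal coordinates, YRNA analogues whose sequences are forced to pair under
their dot-bracket structures, a trailer, ten 22-mer miRNA analogues and a few
members of the remaining classes. Real reference FASTAs (miRBase, gtRNAdb,
Ensembl exports) are drop-in replacements via the reference manifest.

What the simulator does **not** model — and hence what passing tests do not
establish about real data: RT hard stops and premature truncations, position-
dependent quality and error profiles, PCR duplication and ligation bias,
isodecoder families with near-identical sequences (real multi-mapping is far
heavier), partial/degraded fragments off the anchored geometry, and
modification heterogeneity across isodecoders within an amino-acid group.

## Validation experiments and problem sizes

`nmsrna.experiments` (shared by the test suite and `scripts/acceptance.py`)
runs: class-mixture recovery on a 100k-read default library (fractions within
±1 percentage point); modification-rate recovery at 5/20/40/80 % injected at
all six canonical sites on 30k-read calibration libraries restricted to one
tRNA per site-bearing group so every site accumulates ≥ 2,000 covering reads
(recovered index within 3 binomial SDs of the bookkept injected fraction —
the injection process is itself binomial, so the realized fraction, not the
nominal rate, is the oracle); exact subtype recovery on 10k anchored tRF
reads; length-mode recovery; mismatch-type asymmetry with G-type planted only
on 5′ tRFs and A-type only on 3′ tRFs; and YRF cleavage recovery within
±1 nt, annotated unpaired. These sizes give comfortable statistical margins
while keeping a full run in tens of seconds.

Known quantitative caveat: reads carrying an injected misincorporation *and*
a sequencing error exceed the 1-mismatch budget and drop out of the pileup,
biasing the recovered index low by roughly rate × P(error on read) ≈ 0.8
percentage points at a 40 % site — inherent to 1-mismatch mapping (the
published analysis shares it) and well inside the binomial bands at the
depths used.

## Degenerate inputs and numerical choices

Empty FASTA files load as empty lists with a warning; an empty alignment list
cannot be fractionated (error); RPM is undefined at zero mapped reads
(error); a zero-coverage YRNA normalizes to all-zeros rather than dividing by
zero; mismatch indices are null (not 0) wherever depth is below the floor;
site labels that do not resolve on a profile propagate nulls. All counting is
in float64; the conservation identities (Σ weights per read = 1, Σ RPM = 10⁶,
mismatch mass ≤ depth positionwise) are asserted in the tests at 10⁻⁹–10⁻⁶
relative tolerance. Alignment output order is fixed (ref_id, ref_start), and
pipeline reruns on identical inputs produce byte-identical tables.

## Known limitations

* No gapped alignment, genome-wide mapping, or quality-aware scoring; the
  reference sets define the universe of mappable reads.
* No statistical calling of *new* modification sites (no multiple-testing
  control across positions); the site report quantifies known sites.
* m¹G vs m²G (and other chemically distinct modifications with similar
  misincorporation signatures) are not distinguished.
* The Argonaute filter is a size/abundance/consistency screen, not evidence
  of Argonaute loading.
* Differential expression between samples is out of scope; the multi-sample
  site matrix is descriptive.
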