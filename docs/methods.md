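# Methods

This note documents the models, formulas, parameter choices and known
limitations behind the `upep` package: a desk-scale toolkit for
locating upstream open reading frames (uORFs) on eukaryotic mRNAs and
screening them for the two classic signatures of a functional
uORF-encoded peptide (uPEP) — cross-species conservation at the amino
acid level, and an excess of synonymous over non-synonymous
substitution relative to the transcript's main ORF.

## Coordinates and ORF conventions

Internally every interval is 0-based, half-open; all user-facing
output is 1-based inclusive (GenBank/RefSeq style). An ORF interval
runs from its AUG through its stop codon inclusive, so a complete ORF
spans `3·(L+1)` nucleotides for `L` coding codons and its peptide has
length `L` (initiator Met included). Transcripts are sense-strand
mRNA only; `U` is normalised to `T` and lower case to upper on ingest.
The ambiguity code `N` is retained and treated as a mismatch
everywhere downstream (alignment scoring, the match sequence, codon
filtering), which biases identity estimates conservatively downward.

## uORF location

The main ORF (mORF) is the annotated CDS when one is present
(GenBank ingest takes the first CDS feature; fuzzy or missing starts
flag the record as mORF-undefined). Without annotation, the mORF is
the longest AUG-initiated, stop-terminated ORF over the three forward
frames, ties broken 5'-most — the standard heuristic for mRNA records.

A uORF is any AUG strictly 5' of the mORF start, extended in frame to
its first stop codon. Filters, all user-tunable:

| parameter | default | meaning |
|---|---|---|
| `min_len_codons` | 10 | minimum coding codons (stop excluded); 10 is the shortest peptide for which the conservation statistics are plausibly informative |
| `max_overlap_nt` | 0 | how far the uORF (stop included) may extend past the mORF start |
| `search_limit_nt` | unset | restrict uAUGs to the first N nt of the transcript |

Candidates without an in-frame stop inside the transcript are
excluded: a stopless "uORF" is an N-terminal extension of the mORF,
a different phenomenon. Only AUG starts are recognised; near-cognate
starts (CUG/GUG) are a documented non-goal. Nested uAUGs are reported
as independent uORFs, since each encodes its own peptide.

## Pairwise alignment

Transcript pairs are aligned globally with exact affine-gap dynamic
programming (Needleman–Wunsch/Gotoh, via Biopython's C implementation
with a custom ACGTN matrix). Scores default to +5 match, −4 mismatch,
gap open 50, gap extension 0; a gap run of length `L` costs
`open + extend·(L−1)`. End gaps are penalised like internal gaps, so
UTR-length differences appear as low-identity regions in the heatmap
rather than being absorbed silently. `N` scores as a mismatch against
everything, including itself.

From the aligned pair (Q′, R′) of length `m` the match sequence M is
derived: `M_i = 1` iff column *i* holds the same unambiguous
nucleotide in both rows (gaps and N give 0).

## Windowed identity profile and heatmap

For window size `w` (odd) and `z = ⌊w/2⌋`, each non-gap query column
`Q′_i` receives the average of M over the window `[i−z, i+z]` clipped
to `[1, m]`, the normaliser being the clipped column count — at the
two alignment ends this reduces to the asymmetric edge averages, in
the interior to `(1/(2z+1))·Σ M`. Window sums run over alignment
columns, so gap columns count as mismatches and indels depress local
identity, which is what a conservation track should show. Collecting
the values for non-gap query columns in order gives the profile P of
length q (the ungapped query length), one value per query nucleotide.

Defaults: `w = 21` (odd as the symmetric window requires; roughly
codon-scale smoothing) and the perceptually uniform `viridis`
gradient on a fixed 0–100% scale with the scale bar always drawn.
The precondition `w ≤ 2m−1` keeps the window from overrunning both
alignment ends at once; if it ever does, the clip-and-renormalise
rule above is the natural generalisation. The heatmap draws one
colour cell per query nucleotide, ORF bars lane-stacked above, and —
optionally — the reciprocal strip (reference as query) below.

## Translated conservation search

The uORF database is built from a reference transcript set; records
whose mORF start is undefined are excluded and counted, and the build
is deterministic (content-digest version tag). The bundle persists as
plain text: a peptide FASTA, the source transcript FASTA (the
downstream heatmap/Ka-Ks stages need the mRNAs), and a JSON sidecar.

Conservation is scored at the peptide level: each query uORF peptide
is aligned locally (Smith–Waterman) against every database peptide
under BLOSUM62 with BLAST-style gap costs `11 + k`. Comparing the
extracted uORF-frame peptides directly — rather than all-frame
translated search of whole transcripts — targets exactly the
quantity of interest (amino-acid-level uPEP conservation), avoids
spurious out-of-frame hits, and keeps the search desk-scale. Hits are
ranked by raw score (deterministic tie-breaks) and carry a
Karlin–Altschul-style bit score and database-size-aware expectation
(λ = 0.267, K = 0.041, the standard gapped BLOSUM62-11/1 constants)
as a significance guide, not a calibrated p-value.

The default reporting threshold (raw score 40) was calibrated once:
the 95th percentile of the maximum local-alignment score of random
15-residue peptides against a 10⁴-record random-peptide database is
38, so threshold 40 holds the false-hit rate under 5% at that
database size while planted homologues at 60% amino-acid identity
(24-residue peptides) score ≥ ~50.

## Ka/Ks estimation

Codon alignments are extracted from the global nucleotide alignment
in query-frame steps: each query codon of the ORF is paired with the
reference nucleotides aligned to exactly those three columns; codons
interrupted by a gap, containing N, or forming a stop in either
sequence are dropped and counted (the terminal query stop codon is
excluded silently, so an intact ORF of L coding codons yields L clean
columns). The reference ORF interval is validated but the pairing is
alignment-driven; at extreme synonymous divergence the optimal
nucleotide alignment can slip within an ORF, which is a property of
alignment, not of the estimators.

**NG86** (Nei–Gojobori). Sites: each codon position contributes the
fraction of its three possible changes that are synonymous; changes
to stop codons count as non-synonymous so that S + N = 3L exactly.
Differences: codon pairs differing at k positions are averaged over
all k! mutational pathways that avoid stop codons (equal weights; if
every pathway crosses a stop — impossible for k ≤ 2 under the
standard code — all pathways are used). pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected; p ≥ 3/4 sets a saturation flag rather than
raising.

**YN00** (after Yang–Nielsen). κ is estimated first from
fourfold-degenerate and nondegenerate sites whose degeneracy class
agrees between the two codons: within such a class the
transition/transversion ratio is undistorted by the structure of the
genetic code, so a Kimura two-parameter fit estimates κ directly (the
class estimates are combined weighted by site count). Estimating κ
instead from the ts/tv ratio among synonymous differences confounds κ
with code structure and overestimated it by ~75% in large-sample
diagnostics, which is why that simpler scheme was rejected. Sites are
then counted per codon with weights `κ^[ts] · π(target)` using F3x4
position-specific nucleotide frequencies (normalised to 3 sites per
codon), differences are pathway-averaged as in NG86 but split into
transitions and transversions within the synonymous and
non-synonymous classes, and each class is corrected with the K80
formula. When no degenerate site informs κ it falls back to 2 and the
result is flagged.

Undefined ratios (Ks = 0) are reported as a flag, never as infinity;
saturation likewise. NG86 is exactly symmetric in its two sequences;
YN00 is symmetric to numerical tolerance. Standard genetic code only.

For the conservation question, the mORF of the same transcript pair
is estimated alongside the uORF as an internal control: a uORF with
Ka/Ks well below the mORF's is under stronger purifying selection
than the background coding signal of that pair.

**Estimator calibration.** On pairs simulated under a codon model
(single-nucleotide exchanges, transition bias κ = 2, selection ω,
stops forbidden; branch length 0.3 substitutions/codon; 500 codons;
100 replicates), YN00 recovers ω = 0.1 and ω = 1.0 within about ±6%
in the mean and the two estimators correlate at r > 0.93. NG86, which
assumes no transition bias, shows its well-known downward bias under
κ = 2 — mean ω̂ runs ~12–15% low across replicate sets (asymptotically
nearer −19%; per-replicate ratio noise partly offsets the bias in
small-sample means). That bias is inherent to the method, and is the
reason the κ-aware YN00 estimator is the default.

## Synthetic data generator

The generator emulates RefSeq-like mRNA pairs with controlled
conservation structure. Query side: random UTRs, a random-codon CDS,
and uORF blocks planted at known coordinates; the 5'UTR is scrubbed
of stray AUGs (and uORF interiors are sampled AUG-free in all
frames), so the planted uORFs are provably the only ones — making the
truth record an exact oracle for the finder. Reference side, derived
segment-wise so coordinates stay exact:

- UTRs: per-site substitution to the target background identity with
  transition bias κ = 2; indels (1–3 nt, rate per site) only outside
  coding regions.
- planted uORFs: exactly `round((1−identity_aa)·L)` interior codons
  receive one non-synonymous change (count-based planting keeps short
  peptides on target instead of drifting binomially), plus accepted
  synonymous substitutions at the Poisson rate the acceptance model
  implies (accepted syn : nonsyn events = 0.24 : 0.76·ω, with
  −ln(identity) non-synonymous events per codon). ω = 0 means no
  amino acid ever changes and a fixed 0.24 accepted-synonymous events
  per codon supply nucleotide divergence. Start and stop codons are
  fixed so the homologue remains a findable uORF.
- CDS: per-codon proposals at the background mutational pressure,
  accepted always if synonymous, with probability ω_mORF otherwise,
  never into a stop.

Defaults (300 nt 5'UTR, 300-codon CDS, 200 nt 3'UTR, one 25-codon
uORF, background identity 0.7, ω_uORF 0.1, ω_mORF 0.2, indel rate
0.005/site) sketch a human-mouse-like orthologue pair. A companion
codon-pair simulator (continuous-time, Gillespie per codon, rates
∝ κ^[ts]·ω^[nonsyn], uniform sense-codon ancestor, time scaled to
substitutions per codon) serves as the independent oracle for the
rate estimators.

What the generator does **not** emulate — and hence what passing
tests do not show about real data: codon-usage and GC bias, Kozak
context, realistic indel length spectra or indels inside coding
regions, alternative splicing, sequencing error, paralogy, and
lineage-specific rate variation. Recovery rates measured on these
fixtures characterise the algorithms under the stated model, not
expected sensitivity on RefSeq.

## Problem sizes and determinism

The test and acceptance workloads use: 1000 random alignments for the
profile-formula oracle, 500 random pairs (length ≤ 12) for the
aligner oracle, 1000 random sequences × a 5-point parameter grid for
the uORF-finder oracle, 100 retrieval trials against 50-decoy
databases plus 200 false-hit trials, the full 61×61 codon-pair
enumeration, 2×100 simulated replicates of 500 codons for ω recovery,
and duplicate 50-transcript pipeline runs — sizes chosen so the whole
battery completes in well under a minute per stage on one CPU while
keeping sampling error comfortably inside the asserted tolerances.
Every stochastic step draws from an explicit seed; the pipeline
itself is deterministic, and identical inputs and configuration
produce byte-identical outputs.

## Known limitations

- Accession-based input is file-local only; there is no network fetch
  of RefSeq records, and no automatic database refresh — rebuild with
  `upep build-db` when the reference set changes.
- The expectation value attached to search hits uses fixed
  Karlin–Altschul constants, not a per-database fit; treat it as a
  ranking aid.
- Ka/Ks on very short uORFs (≈10 codons) rests on a handful of sites;
  the undefined/saturation flags fire often there, by design.
- The codon-alignment bridge trusts the nucleotide alignment; for
  deeply diverged pairs a dedicated codon-aware aligner would be
  preferable.
- Six-frame translated search of whole transcripts (tblastx-style) is
  out of scope; uORFs missed by the finder's filters cannot be found
  by the search.
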