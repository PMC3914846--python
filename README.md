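# upep

Location and conservation analysis of upstream open reading frames
(uORFs) in eukaryotic transcripts.

About half of eukaryotic mRNAs carry at least one AUG-initiated open
reading frame in their 5' untranslated region, and ribosome profiling
shows many are translated. A uORF whose encoded peptide (a "uPEP") is
functional should leave two footprints: the uORF is conserved across
species *at the amino acid level*, and it accumulates synonymous
substitutions in excess of non-synonymous ones (Ka/Ks < 1). `upep` is
a library + CLI for molecular biologists and comparative genomicists
who want to screen transcripts of interest for such candidates
without a web service or a cluster: it locates uORFs, searches their
peptides against a locally built uORF database, aligns transcript
pairs, renders windowed percent-identity heatmaps with ORF
annotation bars, and estimates Ka/Ks for the uORF with the main ORF
as an internal control.

## The statistics at the core

Given a query transcript Q (length q) and reference R, global affine
alignment (defaults +5 match, −4 mismatch, gap open 50, no extension
penalty) yields Q′, R′ and a binary match sequence M of common length
m, with `M_i = 1` iff column *i* is an identical, unambiguous
nucleotide. For an odd window w with z = ⌊w/2⌋, each non-gap query
column gets the windowed identity

    f(Q′_i) = (1 / |W_i|) · Σ_{j ∈ W_i} M_j,   W_i = [i−z, i+z] ∩ [1, m]

and the values, taken in query order, form the profile P of length q
that is rendered as a heatmap (one cell per query nucleotide). Gap
columns count as mismatches, so indels depress local identity.

Conservation search is peptide-level Smith–Waterman (BLOSUM62, gap
costs 11 + k) of query uORF peptides against every database peptide —
the translated-search idea narrowed to the uORF frames. Ka/Ks is
estimated by both Nei–Gojobori counting (NG86) and a Yang–Nielsen
style κ- and frequency-corrected estimator (YN00, the default); see
`docs/methods.md` for the exact procedures.

## Worked example

`examples/` contains one short script per capability. Building a
reference set with a planted homologue (uORF peptide at 60% identity
to the query's) and searching it:

```bash
$ python examples/03_build_db_and_search.py
database: 32 uORF peptides from 29 transcripts (2 records excluded: mORF start undefined)

hits at the calibrated threshold, most conserved first:
  SYN000303r.1     raw    70  bits  31.6  E 6.3e-06
    MTDTVRQASGPWGTARYLATHVDIS
    MADTERQVSGPRSIARYLTTDVETS
```

The two excluded records had an undefined mORF start (the database
builder's exclusion rule); the single hit is the planted homologue —
its 25-residue peptide aligns to the query's at raw score 70
(expectation 6.3·10⁻⁶ against this database), while the 30 decoy uORF
peptides stay below the calibrated threshold. Estimating selective
pressure on a pair whose uORF is under strong purifying selection
(generated with ω_uORF = 0.05 against ω_mORF = 0.6):

```bash
$ python examples/04_kaks.py
NG86:
  uORF: S   15.8  N   59.2  Sd   8.5  Nd   4.5  Ka 0.0802  Ks 0.9435  Ka/Ks 0.085
  mORF: S  214.8  N  685.2  Sd  50.5  Nd  93.5  Ka 0.1506  Ks 0.2820  Ka/Ks 0.534
  uORF ratio / mORF ratio = 0.159
```

S/N are synonymous/non-synonymous sites, Sd/Nd the observed
differences. The uORF's Ka/Ks of 0.085 — six times below the mORF
internal control — is exactly the signature of selection acting on
the encoded peptide. `examples/02_align_and_heatmap.py` renders the
corresponding heatmap; `examples/05_full_pipeline.py` runs the whole
flow into a per-hit artefact directory with a most-conserved-first
summary TSV.

The same stages are available as a CLI for file-based work:

```bash
upep find-uorfs --in transcripts.fasta --min-codons 10
upep build-db --in refseq_dir/ --out db/
upep run --query query.fasta --db db/ --out results/
upep heatmap --query q.fasta --ref r.fasta --window 21 --out hm/
```

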