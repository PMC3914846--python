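"""Build a uORF database and search it for conserved uPEP candidates.

A reference set of 30 decoy transcripts plus one true homologue (its
uORF peptide at 60% amino-acid identity to the query's) is built into
a peptide database; two records are emitted with an undefined mORF
start and excluded, as the database builder requires. The query's uORF
is then searched against every database peptide by local alignment
(BLOSUM62); the planted homologue should rank first.
"""

from upep import FixtureSpec, build_uorf_db, make_database, make_transcript_pair, search_conserved

spec = FixtureSpec(seed=303, uorf_identity_aa=0.6, omega_uorf=0.1)
query, homologue, _ = make_transcript_pair(spec)
reference_set = make_database(30, spec, planted=[homologue], n_flagged=2)

db = build_uorf_db(reference_set)
meta = db.source_meta
print(f"database: {meta['n_uorfs']} uORF peptides from {meta['n_transcripts']} transcripts "
      f"({meta['n_excluded_morf_undefined']} records excluded: mORF start undefined)")

hits = search_conserved(query, db)
print(f"\nhits at the calibrated threshold, most conserved first:")
for h in hits:
    print(f"  {h.ref_accession:<16} raw {h.raw_score:>5.0f}  bits {h.bit_like_score:5.1f}  "
          f"E {h.significance:.2g}")
    print(f"    {h.q_pep_aligned}\n    {h.r_pep_aligned}")
# the single hit is the planted homologue; decoy uORF peptides stay
# below threshold, so a real conservation signal is easy to spot
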