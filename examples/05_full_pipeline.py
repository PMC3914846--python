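"""End-to-end conserved-uPEP analysis run.

Query extraction, translated search against a database with one
planted homologue, then per-hit global alignment, heatmap rendering
and uORF/mORF Ka/Ks, all driven by one configuration object. The
summary TSV lists hits most-conserved-first; per-hit artefacts land in
subdirectories.
"""

from pathlib import Path

from upep import (
    FixtureSpec,
    RunConfig,
    build_uorf_db,
    make_database,
    make_transcript_pair,
    run_conserved_upep_search,
)

spec = FixtureSpec(seed=505, uorf_identity_aa=0.7, omega_uorf=0.1)
query, homologue, _ = make_transcript_pair(spec)
db = build_uorf_db(make_database(25, spec, planted=[homologue], n_flagged=2))

out = Path(__file__).parent / "pipeline_out"
cfg = RunConfig(output_dir=out, reciprocal_heatmap=True, kaks_method="YN00")
summary = run_conserved_upep_search(query, db, cfg)

print(summary.read_text())
for p in sorted(out.rglob("*")):
    if p.is_file():
        print(p.relative_to(out))
# summary.tsv: one row per hit (rank, accessions, uORF coordinates,
# scores, Ka/Ks of uORF and mORF); heatmap.png shows the query and
# reciprocal identity strips with ORF bars
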