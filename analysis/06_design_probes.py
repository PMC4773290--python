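"""EMSA probe design for the top prioritised variant of the study locus.

Writes results/probes.fa with the four strands (forward/reverse x ref/alt).
"""

from pyfaidx import Fasta

from regulocal.probes import design_emsa_probes
from _common import CAUSAL_IX, RESULTS, study_bundle

bundle, _ = study_bundle()
fasta_path = RESULTS / "locus_bundle" / "reference.fa"
if not fasta_path.exists():
    import regulocal as rl

    rl.write_fixture_bundle(bundle, RESULTS / "locus_bundle")
fasta = Fasta(str(fasta_path))

vid = bundle.variant_ids[CAUSAL_IX]
design = design_emsa_probes(
    fasta, bundle.spec.chrom, bundle.spec.positions[CAUSAL_IX],
    bundle.ref_alleles[CAUSAL_IX], bundle.alt_alleles[CAUSAL_IX],
    variant_id=vid, flank_bp=15,
)
(RESULTS / "probes.fa").write_text(design.to_fasta())
print(f"probes for {vid} (15 bp flanks, 31-mers):")
print(f"  forward ref: {design.forward_ref}")
print(f"  forward alt: {design.forward_alt}")
print(f"  reverse ref: {design.reverse_ref}")
print(f"  reverse alt: {design.reverse_alt}")
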