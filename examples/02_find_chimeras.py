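"""Detect L1 chimeric transcripts in simulated stranded paired-end reads.

One read of a chimeric pair matches the 5' 500 bp of an L1 element
(gapless, >=50 bp, <=1 mismatch) antisense to it; the mate aligns to >=30 bp
of unique sequence within 50 kb.  Retained pairs are clustered into loci per
element and transcript strand, and the planted truth tells us how well the
finder did.
"""

from lctscape import chimera, reference
from lctscape.simulate import SimConfig, simulate_genome, simulate_reads

cfg = SimConfig(seed=42, error_rate=0.0)
truth = simulate_genome(cfg)
pairs = simulate_reads(truth)

refs = {e.id: reference.extract_5p_sequence(truth.genome, e)[0]
        for e in truth.elements}
repeats = chimera.RepeatAnnotation.from_rmsk_rows(truth.rmsk_rows)
result = chimera.find_chimeras(pairs, refs, {e.id: e for e in truth.elements},
                               repeats)

print("filter accounting:", result.accounting())
print(f"pooled LCT loci: {len(result.pooled)} "
      f"(planted: {len(truth.lcts)})")
planted = {l.element_id for l in truth.lcts}
found = {l.element.id for l in result.pooled}
print(f"recall:    {len(found & planted)}/{len(planted)}")
print(f"precision: {len(found & planted)}/{len(found)}")

# at lower depth each library samples the LCT transcriptome only partially,
# which is why genome-wide surveys pool samples
sparse_cfg = SimConfig(seed=42, error_rate=0.0, base_read_count=2.0,
                       read_count_sd=2.0)
sparse_truth = simulate_genome(sparse_cfg)
sparse = chimera.find_chimeras(
    simulate_reads(sparse_truth),
    {e.id: reference.extract_5p_sequence(sparse_truth.genome, e)[0]
     for e in sparse_truth.elements},
    {e.id: e for e in sparse_truth.elements},
    chimera.RepeatAnnotation.from_rmsk_rows(sparse_truth.rmsk_rows))
curve = chimera.saturation_curve(sparse.per_sample_loci, n_perm=10, seed=0)
print("\nsaturation at low depth (mean pooled loci vs samples pooled):")
print(curve.to_string(index=False))
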