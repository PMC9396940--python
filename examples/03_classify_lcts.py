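"""Classify LCTs: 5' splice status, TSS region and polyadenylation.

Runs the three-rule splice classifier on detected loci, then the
walking-PCR and polyA RT-PCR pattern classifiers on the published-style
amplification matrices.
"""

from lctscape import annotation, chimera, reference
from lctscape.annotation import AmpPattern
from lctscape.simulate import SimConfig, simulate_genome, simulate_reads

cfg = SimConfig(seed=42, error_rate=0.0, frac_spliced=0.3)
truth = simulate_genome(cfg)
pairs = simulate_reads(truth)
refs = {e.id: reference.extract_5p_sequence(truth.genome, e)[0]
        for e in truth.elements}
result = chimera.find_chimeras(
    pairs, refs, {e.id: e for e in truth.elements},
    chimera.RepeatAnnotation.from_rmsk_rows(truth.rmsk_rows))

spliced_truth = {l.element_id: l.spliced for l in truth.lcts}
correct = 0
for locus in result.pooled:
    call = annotation.splice_status(locus)
    correct += (call.status == "spliced") == spliced_truth[locus.element.id]
print(f"splice calls matching planted truth: {correct}/{len(result.pooled)}")

# walking PCR: common/downstream/upstream primer outcomes locate the TSS
patterns = {
    "ASP450-like": (True, True, False),
    "ASP200-like": (True, False, False),
    "upstream-initiating": (True, True, True),
}
for name, amp in patterns.items():
    p = AmpPattern(name, "L1PA2",
                   dict(zip(("common", "downstream", "upstream"), amp)))
    print(f"{name}: {annotation.walking_classify(p)}")

# polyA status from three reverse-transcription conditions
rt = [AmpPattern(f"lct_{i}", "L1PA2",
                 {"random_hexamer": True, "oligodT": i < 11,
                  "polyU_oligodA": i < 22})
      for i in range(24)]
df, (lo, hi) = annotation.polya_classify(rt)
print(f"\nnon-polyA LCTs among 24 assayed: between {lo} and {hi}")
# A transcript amplifying only after artificial polyU tailing has no polyA
# tail; oligodT-negative but polyU-negative transcripts stay undetermined.
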