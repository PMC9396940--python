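"""Run the whole survey end to end and print the consolidated report.

Equivalent to `lctscape run --outdir <dir> --seed 42`: simulation,
reference construction, chimera finding, annotation, long-read TSS mapping,
deregulation prediction, methylation/CNV and chromatin profiling, each
stage writing a TSV plus a JSON summary.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from lctscape.pipeline import RunConfig, run_pipeline
from lctscape.simulate import SimConfig

with TemporaryDirectory() as tmp:
    cfg = RunConfig(outdir=Path(tmp), sim=SimConfig(seed=42, error_rate=0.0))
    bundle = run_pipeline(cfg)
    print((Path(tmp) / "report.md").read_text())
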