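"""Shared configuration for the analysis scripts: one synthetic region,
one seed, one results directory, so every numbered step works on the same
deterministic panel."""

import os

from esbalance import pipeline, synth

SEED = 20260101 % (2**31)
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def region() -> synth.RegionSpec:
    return synth.RegionSpec(n_rows=20, n_cols=20, seed=SEED)


def config(subdir: str = "pipeline") -> pipeline.PipelineConfig:
    return pipeline.PipelineConfig(
        region=region(),
        out_dir=os.path.join(RESULTS, subdir),
        seed=SEED,
        n_permutations=999,
    )


def outdir(name: str) -> str:
    path = os.path.join(RESULTS, name)
    os.makedirs(path, exist_ok=True)
    return path
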