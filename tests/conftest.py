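import json
from pathlib import Path

import pytest

from recvar import RunConfig, SimConfig, run_all
from recvar.synthetic_data import SimTruth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic cohort (7 cases,
    46 controls, 20,000 background variants, seed 42, default plant set),
    shared across tests that inspect its outputs."""
    out_dir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(
        out_dir=str(out_dir),
        simulate=SimConfig(seed=42),
        affected=31,
        cohort=179318,
    )
    result_dir = run_all(cfg)
    summary = json.loads((result_dir / "summary.json").read_text())
    truth = SimTruth.from_json((result_dir / "sim" / "truth.json").read_text())
    return {
        "dir": Path(result_dir),
        "summary": summary,
        "truth": truth,
        "vcf": result_dir / "sim" / "cohort.vcf",
        "samples": result_dir / "sim" / "samples.tsv",
    }
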