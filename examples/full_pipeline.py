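"""Run the whole analysis in one call and list the artifacts.

Equivalent to ``fishmorph run-all --seed 1 -o fauna_run`` on the shell;
every artifact is plain CSV / JSON / fcsv.
"""

import json
import tempfile
from pathlib import Path

from fishmorph import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    config = PipelineConfig(input_mode="simulate", seed=1,
                            output_dir=str(Path(tmp) / "fauna_run"))
    run_dir = run_pipeline(config)
    print("artifacts:")
    for path in sorted(run_dir.iterdir()):
        print("  ", path.name)
    log = json.loads((run_dir / "run_log.json").read_text())
    print("K retained:", log["K"])
    print("axis percentages:",
          {k: round(v, 1) for k, v in log["axis_percentages"].items()})
    print("nearest-to-mean species:", log["nearest_to_mean_species"])
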