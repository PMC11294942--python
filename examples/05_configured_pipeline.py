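"""Drive the end-to-end EM pipeline from a YAML run configuration.

Writes a config selecting a synthetic phantom input and the EM segmenter,
runs preprocess -> estimate K -> fit -> classify -> evaluate, and prints the
aggregated metrics table.  The same config works with the `lungseg
segment-em` shell command.
"""

import tempfile
from pathlib import Path

import yaml

from lungseg.config import load_config
from lungseg.pipeline import run_em_pipeline, write_metrics_csv

config = {
    "seed": 11,
    "synthetic": {"n": 6, "size": [48, 48], "n_nodules": [1, 2],
                  "noise_sd": 1.0},
    "preprocess": {"stages": []},
    "em": {"K": 3, "max_iter": 300},
    "evaluation": {"metrics": ["dice", "iou", "pri", "voi", "gce",
                               "accuracy", "sensitivity", "specificity"]},
}

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = Path(tmp) / "run.yaml"
    cfg_path.write_text(yaml.safe_dump(config))
    cfg = load_config(cfg_path)
    report = run_em_pipeline(cfg)
    write_metrics_csv(report, Path(tmp) / "metrics.csv")
    print(f"segmented {len(report.segmentations)} phantoms "
          f"(config hash {report.provenance['config_hash']})")
    print(report.report.format_table(percent=False))
    print("\nEach row is mean ± std over the 6 phantoms; the binary overlap is")
    print("scored against the true nodule masks after optimal label matching.")
    print("Variability is real: with only ~5% nodule pixels, the unsupervised")
    print("intensity mixture sometimes absorbs the nodule class into tissue.")
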