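"""Shared configuration for the numbered analysis scripts.

The desk-scale study: 60 subjects (37 malignant / 23 benign — the class
ratio of the full 542-subject design), SNR 30, all nine maps, RF and
L1R-LR classifiers with a reduced CV schedule.  Volumes and other bulky
intermediates live under ``scratch/``; every table a reader would consult
is written to ``results/``.
"""

from pathlib import Path

from mbdwi.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

CONFIG = PipelineConfig(
    seed=7,
    n_subjects=60,
    n_malignant=37,
    snr=30.0,
    classifiers=("rf", "l1r"),
    cv_repeats=5,
    n_boot=1000,
    mcnemar_repeats=20,
)

RESULTS.mkdir(exist_ok=True)
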