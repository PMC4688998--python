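"""Shared locations for the analysis drivers.

Bulky intermediates (genotype matrices, model dumps) live under scratch/;
small summary tables the later steps and the write-up consume live under
results/.  Run the drivers in order from the repository root:

    python analysis/01_simulate.py
    python analysis/02_adjust_blup.py
    ...
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "gs_run"
RESULTS = ROOT / "results"

for d in (SCRATCH, RESULTS):
    d.mkdir(parents=True, exist_ok=True)
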