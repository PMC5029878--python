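"""Run the complete pipeline end to end into a scratch directory.

Simulates a small 3-slice phantom stack and a cohort, reconstructs,
summarizes all three analysis slice levels and fits the change model,
leaving NIfTI maps, stamped CSV tables and a diagnostics JSON behind.
"""

import tempfile
from pathlib import Path

import pandas as pd

from musclefat import load_config, run_pipeline

config = load_config(text="""
phantom:
  grid_shape: [128, 128]
  n_slices: 3
  compartment_radius: 24
  bone_radius: 6
  subcutaneous_ring: 5
slice_offset_mm: 18
seed: 11
""")

out = run_pipeline(config, Path(tempfile.mkdtemp(prefix="musclefat_")))
print(f"artifacts in {out}:")
for p in sorted(out.rglob("*")):
    if p.is_file():
        print(f"  {p.relative_to(out)}")

print()
summary = pd.read_csv(out / "summary.csv", comment="#")
cols = ["slice_level", "total_ff", "dorsal_ff", "volar_ff", "total_csa_mm2"]
print("reconstructed compartment summaries (SNR 50):")
print(summary[cols].round(2).to_string(index=False))

changes = pd.read_csv(out / "changes.csv", comment="#")
print()
print("adjusted mean changes from the simulated cohort:")
print(changes.round(3).to_string(index=False))
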