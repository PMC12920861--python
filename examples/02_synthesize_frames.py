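"""Generate a small synthetic laryngoscopy cohort and inspect it.

Each frame shows two bright fold bands meeting at the anterior
commissure with a dark triangular glottal gap whose vertices are exactly
the ground-truth keypoints; the realized AGA therefore equals the
sampled angle by construction. Patients contribute 1-5 correlated
frames; per-frame AGA values follow a log-normal with median ~15 deg.
"""

import tempfile
from pathlib import Path

import numpy as np

from vfpose import SynthConfig, compute_aga, generate_dataset

cfg = SynthConfig(n_patients=12, width=320, height=240, seed=0)
out = Path(tempfile.mkdtemp()) / "cohort"
records = generate_dataset(cfg, out_dir=out)

agas = [compute_aga(r.triplet) for r in records]
n_onc = sum(r.oncologic for r in records)
print(f"{len(records)} frames from {cfg.n_patients} patients -> {out}")
print(f"AGA: median {np.median(agas):.1f} deg, range "
      f"{min(agas):.1f}-{max(agas):.1f} deg")
print(f"{n_onc} oncologic frames (bright occluding mass at the commissure)")
# The directory holds PNG frames, COCO keypoint JSON and a ground-truth CSV,
# readable back with vfpose.load_dataset with zero coordinate loss.
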