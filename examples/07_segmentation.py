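"""Segment binned tumor/normal read counts with circular binary segmentation.

Paired tumor and normal counts per genomic bin become library-scaled log2
ratios, median-centered so the tumor's modal (baseline-ploidy) state sits
at 0; CBS then finds change points by permutation testing and merges back
spurious splits (the "undo" step).
"""

import numpy as np

import crossonco as co
from crossonco.segmentation import BinnedTrack

rng = np.random.default_rng(0)
n = 200
starts = np.arange(n) * 100_000 + 1
normal = rng.poisson(400, n).astype(float)
# tumor: one extra copy on bins 80-140 over a 3N baseline (4/3 dosage)
dosage = np.ones(n)
dosage[80:140] = 4 / 3
tumor = rng.poisson(400 * dosage).astype(float)

track = BinnedTrack("s1", "1", starts, starts + 99_999, tumor, normal)
(track,) = co.compute_log_ratios([track], pseudocount=1.0)
profile = co.segment_profile(
    [track], "s1", co.GenotypeGroup.TP53_DIPLOID, baseline_ploidy=3,
    alpha=0.01, n_perm=500, undo_sd=1.0, seed=1,
)

print("segments (start bin, end bin, mean log2 ratio):")
for seg in profile.segments:
    lo = (seg.start_bp - 1) // 100_000
    hi = seg.end_bp // 100_000
    print(f"  bins {lo:3d}-{hi:3d}: {seg.value:+.3f}")
print(f"\nexpected: a segment near +{np.log2(4/3):.3f} (one extra copy on a "
      "triploid baseline) spanning roughly bins 80-140, 0 elsewhere")
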