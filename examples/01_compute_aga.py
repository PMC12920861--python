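"""Compute the anterior glottic angle (AGA) from three labeled keypoints.

The AGA is the clinical metric of vocal-fold motility: the angle at the
anterior commissure (A) between the free borders of the left and right
vocal folds (toward LV and RV). Coordinates are image pixels, x
rightward and y downward.
"""

from vfpose import Keypoint, KeypointTriplet, compute_aga

# an adducted larynx: apex at the top of the frame, folds opening downward
triplet = KeypointTriplet(
    LV=Keypoint(x=120.0, y=165.0),  # posterior angle of the left fold
    RV=Keypoint(x=80.0, y=160.0),   # posterior angle of the right fold
    A=Keypoint(x=100.0, y=30.0),    # anterior commissure
)

aga = compute_aga(triplet)
print(f"AGA = {aga:.2f} degrees")
# ~17.2 deg: a typical quiet-breathing angle (the clinical median is ~15 deg).
# Values near 0 mean fully adducted folds; > 40 deg indicates wide abduction.
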