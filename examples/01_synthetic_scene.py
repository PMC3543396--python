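"""Generate a synthetic two-photon scene with planted motion artifacts.

The red channel holds a static vessel network (the reference structure),
the green channel moving cell-like blobs; a chosen fraction of frames is
corrupted by full-field shifts, defocus blur or elastic warps and labelled
major/minor in the returned ground truth.
"""

from collections import Counter

from motiongate import SceneConfig, generate_scene

config = SceneConfig(T=100, H=96, W=96, rate_major=0.2, rate_minor=0.1, seed=7)
stack, truth = generate_scene(config)

print(f"stack: T={stack.T} frames of {stack.H}x{stack.W}, channels {stack.channel_names}")
print("label counts:", dict(Counter(truth.labels)))
first_major = int(truth.major_indices[0])
print(f"first major artifact at frame {first_major}: {truth.corruptions[first_major]}")
# Label counts match the requested rates (20 major + 10 minor of 100);
# each corruption record states how that frame was distorted.
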