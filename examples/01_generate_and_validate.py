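"""Generate a synthetic CAM study and validate it against its configuration.

Each CAM is one participant's belief network: concepts with affective
valences (-3..+3 or ambivalent) joined by signed connectors.
"""

from camkit.model import validate_against_config, write_cam
from camkit.synth import GenConfig, generate_cam_set

cfg = GenConfig(topology="two_cluster", n_cams=5, seed=1)
cams, truth = generate_cam_set(cfg)

study = cfg.study_config()
for cam in cams:
    violations = validate_against_config(cam, study)
    print(f"{cam.cam_id}: {cam.n_concepts} concepts, {cam.n_connectors} connectors, "
          f"violations={violations or 'none'}")

print("\nCanonical JSON of the first CAM (first 6 lines):")
print("\n".join(write_cam(cams[0]).splitlines()[:6]))
print("\nAn empty violation list means the CAM satisfies every study rule "
      "(minimum size, connectivity, word/character limits, feature switches).")
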