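"""Order parameters and state classification on a synthetic ensemble.

Generates a small two-replica bundle with planted conformational states,
superposes every frame on the 7TM core, measures the ECD tilt angle theta
and the ECD-7TM / ECD-ECL COM distances, and classifies each frame as
closed / semi-open / open / intermediate / ECD-unrestricted / on-side.
"""

import numpy as np

from msmkin import geometry, synthetic

spec = synthetic.GroundTruthSpec(n_replicas=2, n_frames=1000)
bundle = synthetic.simulate_trajectories(spec, seed=42)

ops = geometry.compute_order_parameters(
    bundle.ensemble, spec.groups(), spec.helix_group(),
    reference=bundle.reference_conformers[0])

print(ops[["replica", "frame", "theta_deg", "d_ecd_7tm", "state"]].head(8)
      .to_string(index=False))

print("\nstate occupancies (fraction of frames):")
for state, frac in ops["state"].value_counts(normalize=True).items():
    print(f"  {state:>16s}: {frac:.3f}")

hidden = np.array(spec.state_names)[bundle.stacked_labels()]
agreement = (ops["state"].to_numpy() == hidden).mean()
print(f"\nagreement with the hidden emitting state: {agreement:.1%}")
print("-> the classifier reads the planted states straight off the geometry;")
print("   disagreements come from frames whose noise crosses a band edge.")
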