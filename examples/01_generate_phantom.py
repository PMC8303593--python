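"""Generate one synthetic subject side and inspect its ground truth.

The phantom is a slab of mandibular bone with an elliptical canal (IAC) and
a nerve tube (IAN) inside it, rendered as a paired MRI-like volume (dark
cortical ring, hyperintense nerve) and CBCT-like volume (bright ring, no
nerve contrast).
"""

from iansegmap import PhantomParams, generate_subject_side

params = PhantomParams(seed=7)
mri, cbct, truth = generate_subject_side(params, side="left", subject_id="DEMO")

print(f"MRI volume  {mri.data.shape} at {mri.spacing[0]} mm")
print(f"CBCT volume {cbct.data.shape} at {cbct.spacing[0]} mm")
print(f"nerve midpoint (mm): {tuple(round(v, 2) for v in truth.nerve_center_mm)}")
print("true plane diameters (mm):")
for (structure, modality, plane), value in sorted(truth.true_diameters.items()):
    print(f"  {structure}-{modality:4s} {plane:8s} {value:6.2f}")
# The coronal diameters are the in-plane canal/nerve calibers; the axial and
# sagittal values of a straight tube are dominated by the slab length.
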