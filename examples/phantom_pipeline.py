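"""End-to-end imaging pipeline on a synthetic lung phantom.

Generates a paired inspiration/expiration CT with 15% gas-trapped (fSAD)
and 10% emphysematous tissue, a misaligned SPECT-like tracer volume with
two hot spots, then runs the full chain: mutual-information affine
alignment of the SPECT to the expiration CT, mass-preserving deformable
registration of expiration to inspiration, PRM classification, lobar
ventilation, and tracer statistics on the TLC domain. Prints recovery
diagnostics against the generator's ground truth.
"""

import ventiqct as vq

spec = vq.PhantomSpec(seed=1)
report = vq.run_pipeline(spec)

print("Pipeline report (recovered vs ground truth):")
print(report.summary().to_string())
print("\nPer-lobe tracer share (TC%) vs air-volume-change fraction:")
for lobe in report.tc_pct.index:
    print(f"  {lobe}: TC% = {report.tc_pct[lobe]:5.1f}   dVairF = {report.dvairf[lobe]:.3f}")
print(
    "\nThe fSAD/Emph percentages should match the seeded 15/10 within 2 points,\n"
    "the deformation error should be well under 2 mm, and the tissue\n"
    "conservation ratio should sit within 2% of 1 - the contract the\n"
    "registration and PRM stages are built to."
)
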