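"""Single-pass separation of (synthetic) blast-spiked whole blood.

Runs both transport paths — the deterministic per-gap capture product and a
Monte-Carlo simulation of individual cells — and prints per-type collection
efficiency (CE, % of processed cells recovered in the retentate) and
concentration ratio (CR, retentate over input concentration).
"""

import cifsim as cs

design = cs.design_element(1.0e-3, target_fr=20.0)
sample = cs.spiked_blood(seed=7, blast_per_ul=100.0)

det = cs.separate(design, sample)
mc = cs.separate(design, sample, mode="mc", n_cells=20_000, seed=7)

print(f"flow ratio {det.flow_ratio:.1f}; retentate {det.v_ret:.0f} µL of {det.v_in:.0f} µL")
print(f"{'type':>6} {'CE det %':>9} {'CE MC %':>8} {'CR fold':>8}")
for name in sample.names:
    print(f"{name:>6} {det.ce[name]:>9.1f} {mc.ce[name]:>8.1f} {det.cr[name]:>8.1f}")

# Large cells (MON, EOS, BLAST) are caught almost completely and concentrated
# ~21-fold (the 1+FR ceiling); platelets approach the fluid share 100/(1+FR).
# The model treats red cells as rigid 5.5 µm spheres, so their predicted CE
# is far above the few-percent loss of real, deformable discocytes.
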