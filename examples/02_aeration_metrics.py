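"""HU aeration compartments and global ventilation metrics for one subject.

Classifies lung voxels into hyper/normal/poor/non-aerated compartments,
derives the aerated-lung masks at EE and EI, and computes EELV, EILV,
Vt = EILV - EELV, global strain = Vt/EELV and Vmin = RR x Vt (volumes per
kg of body mass).
"""

from lungstrain import (
    PhantomSpec,
    aerated_mask,
    classify_aeration,
    compartment_fractions,
    dorsoventral_split,
    generate_subject,
    global_metrics,
)
from lungstrain.core import Compartment

spec = PhantomSpec(grid_shape=(48, 48, 48), lung_axes=(1.8, 1.5, 1.6))
subj = generate_subject("SB", "T1", spec, seed=4)

am_ee = classify_aeration(subj.ct_ee, subj.mask_ee)
am_ei = classify_aeration(subj.ct_ei, subj.mask_ei)
print("EE compartment fractions:")
for comp, frac in compartment_fractions(am_ee).items():
    print(f"  {comp.name.lower():18s} {100 * frac:5.1f} %")

gm = global_metrics(
    aerated_mask(am_ee),
    aerated_mask(am_ei),
    body_mass_kg=subj.manifest["body_mass_g"] / 1000,
    rr_per_min=subj.manifest["rr_per_min"],
)
print(f"EELV {gm.eelv_ml_kg:.2f} ml/kg, EILV {gm.eilv_ml_kg:.2f} ml/kg, "
      f"Vt {gm.vt_ml_kg:.2f} ml/kg")
print(f"global strain {gm.global_strain_pct:.1f} %  (whole-lung relative volume change)")
print(f"Vmin {gm.vmin_ml_min_kg:.0f} ml/(min kg) at RR {gm.rr_per_min:.0f}/min")

# equal-volume dorsal/ventral halves: collapse concentrates ventrally
dorsal, ventral, _ = dorsoventral_split(subj.mask_ee)
for name, half in (("dorsal", dorsal), ("ventral", ventral)):
    non = (subj.layout_ee[half.data] == Compartment.NON_AERATED).mean()
    print(f"{name:8s} half: non-aerated {100 * non:5.1f} %")
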