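"""Build a synthetic prostate phantom and a 19-needle transperineal plan.

The phantom stands in for a patient grid: an ellipsoidal gland (~40 mm span)
inside a softer block, with a traction-free entry face. The plan mimics a
brachytherapy template: 2 anchor needles near the midline, then 17 catheters
over the gland silhouette in an alternating order.
"""

import brachysim as bs
from brachysim.vtkio import export_domain

spec = bs.PhantomSpec()  # 20x15x15 mm gland, 80 mm block, 5 mm spacing
domain = bs.generate_phantom(spec)
plan = bs.generate_needle_plan(domain, n_anchor=2, n_catheter=17)

print(f"phantom: {domain.n_nodes} nodes, {domain.n_ips} integration points")
print(f"prostate nodes: {len(domain.prostate_nodes())}, "
      f"quadrature volume {domain.region_volume(bs.REGION_PROSTATE):.0f} mm^3")
for needle in list(plan)[:4]:
    print(f"  {needle.kind:8s} entry {needle.entry_point} "
          f"depth {needle.insertion_depth:.1f} mm radius {needle.radius} mm")
print(f"  ... {len(plan)} needles total")

export_domain(domain, "phantom.vtu")
print("wrote phantom.vtu (open in ParaView; 'region' marks the gland)")
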