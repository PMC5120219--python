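"""Measure the geometry of a bent two-domain cadherin fragment.

Builds a synthetic stand-in for a tandem EC-repeat pair whose linker is
bent ~90 degrees and carries three calcium sites with the atypical
site-2/site-3 spacing (8.48 Å versus the ~6.84 Å canonical average), then
recovers every quantity with the geometry module.
"""

import cadmech.geometry as geo
from cadmech.io_formats import DomainDefinition
from cadmech.synthetic_data import gen_two_domain_structure

structure, truth = gen_two_domain_structure(
    bend_angle=90.0, with_ca_sites=True, ca_spacings=(4.7, 8.48), seed=1
)
doms = {k: DomainDefinition(**v) for k, v in truth.labels["domains"].items()}
linker = (doms["linker"].first_residue, doms["linker"].last_residue)

bend = geo.bend_angle(structure, doms["domain1"], doms["domain2"])
sites = geo.locate_ca_sites(structure, linker)
rg = geo.radius_of_gyration(structure)
bsa = geo.buried_surface(structure, doms["domain1"], doms["domain2"])

print(f"inter-repeat bend angle : {bend:6.1f} deg   (0 deg = straight tandem)")
print(f"calcium sites at linker : {sites.n_sites}")
print(f"site-2/site-3 distance  : {sites.d23:6.2f} A   (canonical mean {geo.CANONICAL_D23_MEAN_A} A)")
print(f"radius of gyration      : {rg:6.1f} A")
print(f"buried interface area   : {bsa['bsa']:6.1f} A^2 over {len(bsa['interface_residues'])} residues")
print("\nA ~90 deg bend with a buried inter-domain interface is the signature")
print("of a calcium-free linker; the wide d23 marks the canonical-like site.")
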