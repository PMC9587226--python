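"""Detect high-density O-glycan patches (mucin-like regions).

A patch requires at least five identified sites within a 25-residue window;
overlapping qualifying windows that share sites merge into one maximal
patch, reported by its first and last member site.
"""

from glycopipe.patch_finder import find_patches, find_patches_catalog, rank_patches
from glycopipe.simulate import SimConfig, simulate_proteome, simulate_sites_and_psms
from glycopipe.site_catalog import build_catalog

# a hand-made illustration first: five sites inside one 25-aa window
demo = find_patches([10, 14, 18, 22, 26], "DEMO")
p = demo[0]
print(f"demo patch: {p.accession} {p.start}-{p.end}, {p.n_sites} sites, "
      f"density {p.density:.2f} sites/aa")

config = SimConfig(seed=5, n_proteins=40, n_sites=150, patch_fraction=0.3,
                   frac_below_cutoff=0.0)
proteome, features = simulate_proteome(config)
truth, psms = simulate_sites_and_psms(config, proteome, features)
catalog = build_catalog(psms, proteome)

patches = rank_patches(find_patches_catalog(catalog))
print(f"\n{len(patches)} patches found "
      f"(simulation planted {len(truth.patch_clusters)} clusters)")
print("accession\tspan\tsites")
for patch in patches[:8]:
    print(f"{patch.accession}\t{patch.start}-{patch.end}\t{patch.n_sites}")
# Ranking is by member count (ties: tighter span first), the order used when
# reporting the densest mucin-like regions of a glycoproteome.
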