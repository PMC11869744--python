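"""Microdiversity-aware strain comparison of two allele profiles.

Builds two tiny per-species allele-count profiles by hand, calls species
presence, and compares them site by site. The printed popANI treats a site
as a substitution only when the samples share no allele at all (major or
minor), while conANI compares consensus alleles — so a shared minor allele
suppresses a popANI substitution but not a conANI one.
"""

import numpy as np

from strainshare import AlleleProfile, compare_profiles, is_strain_shared, presence_call

genome_length = 1000
positions = np.arange(400)  # 40% of the genome covered in both samples

# sample A: fixed for base A at every covered site
counts_a = np.zeros((400, 4), dtype=int)
counts_a[:, 0] = 12

# sample B: mostly identical, one fixed difference (site 0 -> all G), one
# polymorphic site where the majority is C but a minor A allele remains
counts_b = counts_a.copy()
counts_b[0] = (0, 0, 12, 0)
counts_b[1] = (3, 9, 0, 0)

a = AlleleProfile("donor", "sp001", genome_length, positions, counts_a)
b = AlleleProfile("recipient", "sp001", genome_length, positions, counts_b)

for profile in (a, b):
    call = presence_call(profile)
    print(f"{profile.sample_id}: breadth {call.breadth:.2f} -> present={call.present}")

comparison = compare_profiles(a, b)
print(f"compared positions : {comparison.n_compared}")
print(f"popANI substitutions: {comparison.n_pop_subs} -> popANI {comparison.popani:.6f}")
print(f"conANI substitutions: {comparison.n_con_subs} -> conANI {comparison.conani:.6f}")
print(f"same strain at 99.999%? {is_strain_shared(comparison)}")

# The fixed difference counts against both metrics; the polymorphic site
# counts only against conANI because the minor A allele is shared. One
# substitution in 400 sites (popANI 0.9975) is far below the 99.999% strain
# threshold, so these two samples carry different strains.
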