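"""Filter candidate low-frequency variant sites on MAF and strand bias.

Builds a small strand-stratified allele-count table containing one genuine
low-frequency variant (balanced across strands) and one artifact (minor
allele confined to a single strand), then applies the standard filters:
minor allele frequency >= 0.5 % and strand bias < 1.
"""

import pandas as pd

from duplexkit import filter_sites, site_metrics

counts = pd.DataFrame(
    [
        # pos 13708: a real heteroplasmy — 6 of 1138 consensi, both strands
        ("mt", 13708, "G", 566, 566),
        ("mt", 13708, "A", 3, 3),
        # pos 7601: an artifact — minor allele only on the plus strand
        ("mt", 7601, "C", 540, 540),
        ("mt", 7601, "T", 12, 0),
        # pos 151: minor allele too rare to call (MAF < 0.5 %)
        ("mt", 151, "T", 800, 800),
        ("mt", 151, "G", 3, 2),
    ],
    columns=["chrom", "pos", "allele", "plus", "minus"],
)

sites = site_metrics(counts)
print("pos     depth   MAF      SB")
for s in sites:
    print(f"{s.pos:<8}{s.depth:<8}{100 * s.maf:.2f} %  {s.sb:.2f}")

kept = filter_sites(sites, maf_min=0.005, sb_max=1.0)
print("\npassing sites (MAF >= 0.5 %, SB < 1):", [s.pos for s in kept])
print("a low SB means the minor allele is supported evenly by both strands;")
print("strand-confined support is the signature of an artifact.")
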