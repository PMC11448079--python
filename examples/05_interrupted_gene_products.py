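"""Coding consequences of an element landing inside or beside a gene.

Uses the constructed single-locus instances: a 1,044-nt CDS (347-aa
product) split by a 195-nt insertion into 286-aa and 64-aa products,
and a stop-ablating insertion extending a CDS by +81 nt.
"""

from mobilome import impact_annotator as ia
from mobilome import synthetic_data as sd

ex = sd.make_split_cds_example()
intact = ia.product_summary(ex["cds"])
split = ia.split_products(ex["cds"], ex["offset"], ex["insert"])
print(f"intact CDS: {len(ex['cds'])} nt -> {intact} aa")
print(
    f"after a {len(ex['insert'])}-nt insertion at nt {ex['offset']}: "
    f"products of {split.lengths_aa[0]} aa and {split.lengths_aa[1]} aa"
)
# Product 1 runs from the original start to the first in-frame stop at
# the junction; product 2 is the longest ATG-initiated ORF downstream
# in the interrupted transcript.

ee = sd.make_extension_example()
delta = ia.cds_delta(ee["cds"], ee["offset"], ee["insert"])
print(
    f"stop-ablating insertion near the 3' end of a {len(ee['cds'])}-nt CDS "
    f"extends the coding region by {delta:+d} nt"
)
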