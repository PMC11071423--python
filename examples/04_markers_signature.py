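"""Tri-assay markers (gene expression, gene activity, differential
accessibility) for the ILC2 cluster, and the multiomic signature built from
their top-marker overlap."""

import numpy as np

from fmm import io as fio
import fmm

res = fmm.run_all(fio.RunConfig(seed=0))

ilc2 = res.ilc2_cluster
gex = res.gex_markers[res.gex_markers.cluster == ilc2]
ga = res.ga_markers[res.ga_markers.cluster == ilc2]
print(f"ILC2 cluster = {ilc2}; GEX markers: {len(gex)}, GA markers: {len(ga)}, "
      f"DA peaks mapped to genes: {len(res.da_peaks)}")
print("top 5 GEX markers:", ", ".join(gex.feature.head(5)))

sig = res.signature
print(f"multiomic signature: {len(sig.union)} unique genes")
print("Venn regions:", sig.overlap_counts)
# The triple overlap holds genes supported by expression, inferred activity
# from fragments, AND differential accessibility of a nearby peak — the
# highest-confidence layer of the signature.
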