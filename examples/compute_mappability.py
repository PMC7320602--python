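"""Compute the (k,e)-mappability of a small genome and export tracks.

Builds a 1 kb synthetic genome containing a 150 bp duplication, indexes
it, computes the (20,1)-frequency and mappability, and writes wig/bed
tracks.  Positions inside the duplicated blocks have frequency 2
(mappability 0.5); everything else is unique (mappability 1).
"""

import numpy as np

import mappability as mp
from mappability import writers

rng = np.random.default_rng(11)
seq = "".join(rng.choice(list("ACGT"), size=1000))
seq = seq[:800] + seq[200:350] + seq[800:]  # duplicate a 150 bp block

collection = mp.collection_from_strings([seq])
index = mp.build_index(collection)

freq = mp.frequency(index, collection, k=20, e=1)
mapp = mp.mappability(freq)

n_unique = int((mapp.values == 1.0).sum())
print(f"genome length: {len(seq)}  valid 20-mers: {len(freq)}")
print(f"unique 20-mers (mappability 1): {n_unique}")
print(f"repeated 20-mers (mappability 0.5): {int((mapp.values == 0.5).sum())}")
print(f"first repeated position: {int(freq.positions[freq.values > 1][0])}")

writers.write_wig(mapp, collection, "example_mappability.wig")
writers.write_bed(mapp, collection, "example_mappability.bed")
print("wrote example_mappability.wig / .bed")
# The repeated positions fall in the two copies of the duplicated block,
# [200, 350) and [800, 950), give or take chance matches at the copy
# boundaries (windows straddling a boundary repeat only if the flanking
# bases happen to agree).
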