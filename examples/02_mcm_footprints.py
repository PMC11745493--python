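"""MCM double-hexamer footprints at the rDNA origin from ChEC fragments.

A G1 MCM2-ChEC library is folded onto one 9.1 kb repeat; the 51-100 bp
(sub-nucleosomal footprint) size class is profiled and its peaks called.
In a sir2 background most helicases sit at a displaced site 150 bp right
of the loading site, so two closely spaced peaks appear.
"""

import numpy as np

from mcmtrace import (GenotypeParams, MCM_SIZE_CLASS, SimulationSpec,
                      call_peaks, default_genome_model,
                      repeat_class_profile, size_coord_matrix)
from mcmtrace.simulate import simulate_chec_timecourse

model = default_genome_model(150)
spec = SimulationSpec(model=model,
                      genotype=GenotypeParams.for_genotype("sir2"),
                      n_fragments=200_000, seed=2, timepoints=(0.0,))
g1 = simulate_chec_timecourse(spec)[0]
mdl = spec.with_model()

matrix = size_coord_matrix(g1, "repeat", 0, mdl.rdna.repeat_length,
                           (1, 300), fold_repeat=mdl)
by_length = matrix.counts[:, matrix.class_columns(MCM_SIZE_CLASS)].sum(axis=0)
modal = MCM_SIZE_CLASS[0] + int(np.argmax(by_length))
print(f"modal MCM-class fragment length : {modal} bp")

profile = repeat_class_profile(g1, mdl, MCM_SIZE_CLASS)
peaks = call_peaks(profile, smoothing_bw=10, min_separation=100)
for p in peaks.peaks:
    print(f"peak at repeat offset {p.position:5d}  height {p.height:8.1f}")
top2 = sorted(p.position for p in peaks.top(2))
print(f"peak separation                 : {top2[1] - top2[0]} bp")

# ~65 bp fragments are the protection of one MCM double-hexamer; the two
# peaks are the nondisplaced (loading) site and the site the helicase is
# pushed to by C-pro transcription, 150 bp apart.
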