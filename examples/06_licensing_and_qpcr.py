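"""Band-intensity and qPCR arithmetic: licensing, array size, copy
number and per-copy C-pro expression.

The licensing Southern destroys a restriction fragment wherever the
origin carries an MCM-MNase fusion; its depletion estimates the
licensed fraction. The uncut array band sizes the rDNA relative to a
reference strain; two-point qPCR calibration against 180- and 35-copy
standards gives absolute copies.
"""

from mcmtrace import (GenotypeParams, QpcrPanel, SimulationSpec,
                      active_origins_per_cell, copies_from_qpcr,
                      cpro_per_copy, default_genome_model,
                      licensed_fraction, relative_array_size,
                      simulate_licensing_assay)

model = default_genome_model(150)
gt = GenotypeParams.for_genotype("fun30 sir2")     # contracted 52-copy array
spec = SimulationSpec(model=model, genotype=gt, n_fragments=1, seed=6)

bands = simulate_licensing_assay(spec, cut_efficiency=1.0)
lf = licensed_fraction(bands)
print(f"licensed fraction          : {lf.value:.2f}"
      + ("  (clipped)" if lf.clipped else ""))
print(f"relative array size        : {relative_array_size(bands):.2f}")

print(f"active origins per cell    : "
      f"{active_origins_per_cell(8.45, 0.5):.1f}  (bubble/single-ARS)")

# qPCR: the unknown's dCt sits midway between the two standards
panel = QpcrPanel(ct_query=9.18, ct_ref=10.0,
                  std1_ct_query=8.0, std1_ct_ref=10.0,
                  std2_ct_query=10.36, std2_ct_ref=10.0)
print(f"qPCR copy estimate         : {copies_from_qpcr(panel):.1f}")

# C-pro RNA, one cycle higher and on a half-size array vs baseline
rel = cpro_per_copy(ct_cpro=19.0, ct_ref=15.0, copies=75,
                    baseline_ct_cpro=20.0, baseline_ct_ref=15.0,
                    baseline_copies=150)
print(f"C-pro per copy vs baseline : {rel:.1f}x")
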