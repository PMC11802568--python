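"""Generate a synthetic drug-treatment cohort with known ground truth.

The generator emulates replicate-collapsed differential-expression
signatures (z-scores relative to DMSO controls): 30 vehicle samples, 30
non-toxic drug-treated samples, and 30 toxic drug-treated samples whose
'Oxidative stress' pathways are shifted in proportion to log dose.
"""

from mdtr import SynthConfig, generate_cohort

config = SynthConfig(seed=1)
expr, meta, pathways, mech_map, truth = generate_cohort(config)

print(f"expression matrix: {expr.n_genes} genes x {expr.n_samples} samples")
print(f"groups: {meta.table['group'].value_counts().to_dict()}")
print(f"pathways: {len(pathways)} across {len(mech_map.mechanism_names)} mechanisms")
for name in mech_map.mechanism_names:
    print(f"  {name}: {len(mech_map.pathways_of(name))} pathways")
print(f"perturbed pathways (ground truth): {truth.perturbed_pathway_ids}")

top = meta.table[
    (meta.table.group == "TOXIC") & (meta.table.dose_um == max(config.doses))
].iloc[0]
print(f"\nexample toxic sample: {top.sample_id} ({top.drug}, {top.dose_um} uM)")
print(f"  applied z-shift scale: {truth.shift_magnitudes[top.sample_id]:.2f}")
# The shift scale is the mean dysregulation applied to the perturbed
# mechanism's genes; DMSO samples always have scale 0.
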