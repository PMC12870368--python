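"""Generate the default synthetic hen-faecal study and inspect its truth.

The generator plants a treatment DAG (compost -> acetate/butyrate up,
Romboutsia/Turicibacter down) inside Dirichlet-multinomial genus counts and
lognormal metabolite concentrations, clustered by farm.
"""

from microsem import generate_study

study = generate_study(seed=42)

print(f"counts table: {study.counts.data.shape[0]} samples x "
      f"{study.counts.data.shape[1]} genera (scale={study.counts.scale})")
print(f"metabolites:  {study.metabolites.data.shape[1]} compounds")
print(f"arms: {study.metadata.data['arm'].value_counts().to_dict()}")
print()
print("planted treatment effects (CLR / log units; sign = direction):")
for taxon, eff in study.truth.planted_taxa.items():
    print(f"  {taxon:35s} {eff:+.2f}")
for met, eff in study.truth.planted_metabolites.items():
    print(f"  {met:35s} {eff:+.2f}")
print()
print("structural DAG edges (parent -> child: coefficient):")
for (p, c), w in study.truth.model.edges.items():
    print(f"  {p} -> {c}: {w:+.1f}")
# A positive coefficient means the parent raises the child; the planted
# effects are what a perfect differential-abundance screen should recover.
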