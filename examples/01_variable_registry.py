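"""Inspect the packaged audit schema: domains, sources, and sizes.

The instrument assesses 53 variables on every tax parcel and 26 on
public-space nuisance points; each variable belongs to one substantive
domain.
"""

from blockscape import default_registry

registry = default_registry()

print(f"{len(registry)} variables total")
for domain, size in registry.domain_sizes().items():
    print(f"  {domain:<18} {size:>3} variables")
print(f"parcel-applicable: {len(registry.parcel_variables)}")
print(f"public-space:      {len(registry.public_space_variables)}")

print("\nterritoriality variables (physical markers of ownership/control):")
for var in registry.domain_variables("territoriality"):
    print(f"  {var.name:<22} source={var.source.value}")
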