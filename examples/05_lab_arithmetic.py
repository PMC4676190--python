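"""Closed-form lab arithmetic: doubling times and molar concentrations.

Converts an exponential growth rate to a doubling time (t_d = ln 2 / mu)
and mass or volume concentrations of stressor compounds to millimolar,
with caller-supplied molar masses and densities.
"""

from srna_atlas import comparative

mu = 0.14  # per hour, a glucose-limited fed-batch feed rate
td = comparative.doubling_time(mu)
print(f"growth rate {mu}/h -> doubling time {td:.2f} h (~{round(td)} h)")

compounds = [
    ("serine", 3.0, "g_per_l", 105.09, None),
    ("succinic acid", 32.0, "g_per_l", 118.09, None),
    ("itaconic acid", 29.0, "g_per_l", 130.10, None),
    ("butanol", 0.75, "percent_v_v", 74.12, 0.81),
]
print("\ngrowth-inhibiting concentrations in millimolar:")
for name, amount, unit, molar_mass, density in compounds:
    mm = comparative.to_millimolar(amount, molar_mass, density=density, unit=unit)
    shown = f"{amount} {'g/L' if unit == 'g_per_l' else '% v/v'}"
    print(f"  {name:>14}: {shown:>10} -> {mm:6.1f} mM (~{round(mm)} mM)")
print("\nMillimolar units make inhibitory strengths comparable across "
      "compounds with very different molar masses.")
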