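"""Ligand-exchange volume calculator.

Computes the volume of neat PEG thiol to add to a dried batch of DDT-capped
gold particles so the solution carries the desired excess of PEG per
attached DDT, via a per-particle mole balance: the dry mass splits into
gold cores and DDT shells, giving the number of attached DDT ligands.
"""

from ligandshell import ExchangeRecipe, peg_exchange_volume

recipe = ExchangeRecipe(
    m_dry=0.010,       # g of dried DDT-capped particles
    d_core=2.8,        # nm median core diameter from STEM
    excess_ratio=500,  # desired PEG added per attached DDT
)
v_cm3 = peg_exchange_volume(recipe)

print(f"dry mass          : {recipe.m_dry * 1e3:.1f} mg")
print(f"core diameter     : {recipe.d_core} nm "
      f"(A = {recipe.area_np:.2f} nm^2, V = {recipe.volume_np:.2f} nm^3)")
print(f"DDT surface density: {recipe.gamma_ddt} ligands/nm^2")
print(f"excess ratio R    : {recipe.excess_ratio}")
print(f"-> add {v_cm3:.3f} mL ({v_cm3 * 1e3:.0f} uL) of neat PEG thiol")
print("\nThe volume is linear in both R and the dry mass; halve either to")
print("halve the addition.")
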