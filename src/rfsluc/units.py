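"""Physical constants and unit conversions used throughout the pipeline.

All conversions live here so that every accounting stage agrees on scale.
Report units follow the summary-table conventions: nutrient applications and
nitrate leaching in Gg (10^9 g) of elemental N or P per year, phosphorus
runoff in Mg-P per year, soil erosion in Gg per year, nitrous oxide in
Tg CO2-equivalent per year, and committed land-use-change carbon in Tg CO2e.
"""

# mass scale: internal fluxes are kg/ha * ha = kg
KG_PER_MG = 1_000.0          # 1 Mg (tonne) = 1000 kg
KG_PER_GG = 1_000_000.0      # 1 Gg = 10^6 kg
KG_PER_TG = 1_000_000_000.0  # 1 Tg = 10^9 kg
G_PER_TG = 1e12

HA_PER_MHA = 1e6

# nitrous oxide: N2O-N mass to N2O mass, and 100-y global warming potential
N2O_MASS_RATIO = 44.0 / 28.0
GWP_N2O = 265.0

# ecosystem carbon: C mass to CO2 mass
CO2_PER_C = 44.0 / 12.0
# methane 100-y GWP (optional conversion-emission term)
GWP_CH4 = 28.0

# fuel accounting
ETHANOL_LHV_MJ_PER_L = 21.46
GASOLINE_G_CO2E_PER_MJ = 93.1
MJ_PER_MMBTU = 1055.06

# policy scale: 5.5 billion gallons/year of added ethanol demand = 20.8 GL/y
DEMAND_INCREMENT_BGY = 5.5
ANNUAL_ETHANOL_L = 20.8e9

# eligibility threshold: 15 acres in hectares
MIN_FIELD_HA = 6.07


def g_per_mj_to_kg_per_mmbtu(x: float) -> float:
    """Convert a fuel intensity from g CO2e/MJ to kg CO2e/mmBtu."""
    return x * MJ_PER_MMBTU / 1000.0
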