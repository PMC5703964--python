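"""Field constants shared across the package.

The single-cell reference area (178 µm²) converts islet cross-sectional
area to a dimensionless cell-equivalent count; the IEQ reference volume is
the volume of a 150 µm diameter sphere, the standard islet-mass unit of
clinical islet transplantation.
"""

import math

#: Reference area of one endocrine cell in a tissue section (µm²).
SINGLE_CELL_AREA_UM2: float = 178.0

#: Diameter of the reference islet defining one Islet Equivalent (µm).
IEQ_DIAMETER_UM: float = 150.0

#: Volume of one IEQ: sphere of 150 µm diameter (µm³).
V_IEQ_UM3: float = math.pi / 6.0 * IEQ_DIAMETER_UM**3

#: Default pancreatic tissue density (g/mL).
DEFAULT_DENSITY_G_PER_ML: float = 1.0

#: Islets larger than this effective diameter are counted separately (µm).
OVER_DIAMETER_THRESHOLD_UM: float = 40.0

#: Clinical islet-isolation success criterion (IEQ, strict "over").
YIELD_THRESHOLD_IEQ: float = 400_000.0
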