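"""Group-contribution solubility parameters for the bundled drug/polymer set.

Computes the Fedors total parameter and the van Krevelen dispersive/polar/
hydrogen-bonding split for every bundled compound from its structural group
counts, and prints them next to the corresponding molar volumes.  Values
are in MPa^0.5 (parameters) and cm^3/mol (volumes); drugs and polymers with
similar parameters are candidates for miscible amorphous dispersions.
"""

import asdscreen as asd
from asdscreen.pipeline import parameter_table

compounds = asd.load_all_compounds()
tables = {m: asd.load_bundled_table(m) for m in ("fedors", "van_krevelen")}

frame = parameter_table(compounds, tables)
print(frame.round(1).to_string(index=False))
print(
    "\ndelta_f/delta_vk: total solubility parameter under each method; "
    "delta_d/p/h: van Krevelen components.\n"
    "A drug-polymer pair with |delta_drug - delta_polymer| < 7 MPa^0.5 is "
    "conventionally read as miscible."
)
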