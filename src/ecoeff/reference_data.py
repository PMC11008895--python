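"""Reference tables used by the worked examples and benchmark checks.

Small published comparison datasets for the organic-rice analysis:

* a national agricultural carbon-sink series (10^4 t, 2012-2021) together
  with the reported grey-model and grey-neural fitted values and their
  reported relative errors (in %, base year zero by convention),
* average organic and conventional rice yields (kg/mu) per year,
* an itemized per-mu cost sheet for organic vs conventional cultivation
  (RMB/mu), with the farmer's own labour and land rent flagged as
  owner-imputed items.
"""

from __future__ import annotations

import pandas as pd

CARBON_SINK = pd.DataFrame({
    "year": range(2012, 2022),
    "actual": [15783.0, 15762, 15642, 15488, 15416, 15292, 15076, 15133,
               14962, 14980],
    "gm_simulated": [15783.0, 15557, 16003, 15322, 15350, 15792, 15350,
                     15038, 14675, 15125],
    "gm_error_pct": [0.0, 1.35, -2.31, 1.07, 0.43, -3.27, -1.82, 0.63,
                     1.92, -0.97],
    "gnn_simulated": [15783.0, 15725, 15852, 15479, 15365, 15361, 15065,
                      15069, 14522, 15080],
    "gnn_error_pct": [0.0, 0.23, -1.34, 0.06, 0.33, -0.45, 0.07, 0.42,
                      1.07, -0.67],
})

RICE_YIELDS = pd.DataFrame({
    "year": range(2012, 2022),
    "organic_yield": [437.0, 455, 469, 532, 573, 609, 627, 661, 673, 703],
    "conventional_yield": [684.0, 708, 736, 751, 763, 778, 791, 806, 824, 836],
})

#: item -> (organic RMB/mu, conventional RMB/mu)
RICE_COST_ITEMS = {
    "Machine Transplanting": (90.0, 90.0),
    "Machine Harvesting": (80.0, 110.0),
    "Organic Fertilizer": (250.0, 0.0),
    "Chemical Fertilizer": (0.0, 400.0),
    "Biological Pesticide": (15.0, 0.0),
    "Chemical Pesticide": (0.0, 300.0),
    "Seeds": (350.0, 300.0),
    "Manual Labor": (600.0, 600.0),
    "Land Rent": (700.0, 700.0),
    "Organic Certification": (200.0, 0.0),
    "Rice Storage and Transportation": (400.0, 400.0),
    "Product Packaging and Sales": (700.0, 0.0),
}

#: owner-imputed items excluded from the cash-cost variant
RICE_COST_IMPUTED = ["Manual Labor", "Land Rent"]
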