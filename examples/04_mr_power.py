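"""Lower-bound MR power at the study's sample size.

With summary-level instruments, the variance in methylation explained by
the strongest single mQTL lower-bounds the variance explained by the full
instrument, so these curves are conservative minimum power estimates.
"""

import pandas as pd

from epimediate import mr_power

tables = [mr_power(n=409, r2=r2, or_grid=[1.1, 1.2, 1.3, 1.5, 2.0, 3.0])
          for r2 in (0.05, 0.1, 0.2, 0.3, 0.5)]
grid = pd.concat(tables, ignore_index=True)
wide = grid.pivot(index="odds_ratio", columns="r2", values="power")
print("power (two-sided alpha 0.05, n = 409):")
print(wide.round(3).to_string())
print("\nrows: hazard ratio per unit exposure; columns: variance in the "
      "exposure explained by the instrument")
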