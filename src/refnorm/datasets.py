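"""Small bundled worked-example tables.

The CV table below is published data from a barley dark-induced leaf
senescence experiment: ddPCR quantification of a stable thioredoxin-like
transcript ("Ref C") at six time points (days of dark incubation) with
three biological replicates, normalized against pairs and one quadruple
of validated reference genes (A, B, D, E). ``cv_raw`` and ``cv_norm`` are
coefficients of variation across the replicates before and after
normalization, printed to two decimals; ``cv_reduce_pct`` is the percent
reduction the source reports (computed from unrounded CVs, so it can
differ from the value recomputed from the rounded pair by a rounding
half-ULP).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["senescence_cv_reduction_table"]

_CV_TABLE = """\
day,combo,cv_raw,cv_norm,cv_reduce_pct
0,A+B,0.73,0.03,95.2
0,A+D,0.73,0.09,87.9
0,A+E,0.73,0.14,80.3
0,B+D,0.73,0.13,82.6
0,B+E,0.73,0.16,78.3
0,D+E,0.73,0.22,70.1
0,A+B+D+E,0.73,0.12,83.2
3,A+B,0.66,0.17,74.7
3,A+D,0.66,0.16,75.7
3,A+E,0.66,0.08,87.5
3,B+D,0.66,0.21,68.0
3,B+E,0.66,0.13,79.9
3,D+E,0.66,0.13,79.8
3,A+B+D+E,0.66,0.15,77.8
5,A+B,0.16,0.18,-9.5
5,A+D,0.16,0.04,75.2
5,A+E,0.16,0.15,10.0
5,B+D,0.16,0.10,40.3
5,B+E,0.16,0.19,-14.3
5,D+E,0.16,0.08,51.4
5,A+B+D+E,0.16,0.11,32.0
7,A+B,0.17,0.10,43.1
7,A+D,0.17,0.13,26.4
7,A+E,0.17,0.09,49.7
7,B+D,0.17,0.12,30.7
7,B+E,0.17,0.07,60.3
7,D+E,0.17,0.09,46.6
7,A+B+D+E,0.17,0.09,45.5
10,A+B,0.65,0.10,84.6
10,A+D,0.65,0.08,88.0
10,A+E,0.65,0.05,92.1
10,B+D,0.65,0.06,91.1
10,B+E,0.65,0.05,92.0
10,D+E,0.65,0.13,80.0
10,A+B+D+E,0.65,0.04,93.7
12,A+B,0.98,0.23,76.7
12,A+D,0.98,0.24,75.5
12,A+E,0.98,0.21,79.0
12,B+D,0.98,0.11,89.2
12,B+E,0.98,0.14,86.2
12,D+E,0.98,0.13,86.8
12,A+B+D+E,0.98,0.05,95.4
"""


def senescence_cv_reduction_table() -> pd.DataFrame:
    """Published barley-senescence CV table (see module docstring)."""
    return pd.read_csv(StringIO(_CV_TABLE))
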