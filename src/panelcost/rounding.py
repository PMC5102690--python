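"""Euro rounding used at the reporting layer.

All model composition happens on unrounded floats; whole-euro rounding
(half away from zero, the convention of ordinary commercial rounding)
is applied only when a number is printed or exported.
"""

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties going away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
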