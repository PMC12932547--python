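"""Pure-formula utilities for plate and qPCR assays.

These are the arithmetic companions to the screening pipeline: halo
indices for phosphate solubilization (SI) and siderophore production
(SPI), percent inhibition for dual-culture (IE) and culture-filtrate
(IR) antagonism assays, and relative gene expression by the 2^-ddCT
method. All operations are unit-agnostic as long as paired measurements
share a convention (diameters with diameters, radii with radii).
"""

from __future__ import annotations

import math

from .errors import ValidationError


def halo_index(halo: float, colony: float) -> float:
    """Halo-to-colony diameter ratio.

    Covers both the solubilization index SI = D/d and the siderophore
    production index SPI = M/m — the same ratio read off different media.
    """
    if colony <= 0:
        raise ValidationError(f"colony diameter must be > 0, got {colony}")
    if halo < colony:
        raise ValidationError(
            f"halo ({halo}) smaller than colony ({colony}); a meaningful index needs halo >= colony"
        )
    return halo / colony


def inhibition_percent(treated: float, control: float) -> float:
    """Percent growth inhibition: (1 - treated/control) x 100.

    Covers IE (dual culture, radii toward the antagonist vs. solo) and
    IR (culture-filtrate plates vs. control plates). Negative values are
    permitted — they mean the treatment promoted pathogen growth.
    """
    if control <= 0:
        raise ValidationError(f"control measurement must be > 0, got {control}")
    if treated < 0:
        raise ValidationError(f"treated measurement must be >= 0, got {treated}")
    return (1.0 - treated / control) * 100.0


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by 2^-ddCT against a reference gene and control condition."""
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError(f"non-finite CT value in {cts}")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)
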