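"""IRM-ratio normalization: relative community quantity (RCQ).

RCQ of a genus in a sample is its relative abundance divided by the
relative abundance of the internal reference microorganism (IRM) in the
same sample. The ratio cancels the per-sample closure normalizer, so RCQ
columns do not sum to a constant — that is the point: it frees the data
from compositional closure and behaves as a semiquantitative proxy for
absolute abundance.

Zeros are handled asymmetrically, following the normalization's logic:

* IRM abundance 0 -> the denominator becomes a pseudo-count of
  0.5 x detection limit (default detection limit 0.002%, hence
  pseudo-count 0.001%);
* a non-IRM genus at 0 stays 0 regardless of the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, ValidationError
from .io import AbundanceTable, StudyDesign, total_sum_scale

logger = logging.getLogger(__name__)

DEFAULT_DETECTION_LIMIT = 0.002  # percent; smallest reliably observed relative abundance
PSEUDO_COUNT_FACTOR = 0.5  # pseudo-count = 0.5 x detection limit, fixed

MODES = ("per_sample", "group_mean")


@dataclass(frozen=True)
class RCQTable:
    """IRM-normalized quantities per taxon per sample, with a pseudo-count audit trail."""

    data: pd.DataFrame = field(repr=False)  # taxa x samples, dimensionless ratios
    irm_genus: str
    detection_limit: float
    mode: str
    pseudo_count_applied: pd.Series = field(repr=False)  # bool per sample

    @property
    def pseudo_count(self) -> float:
        return PSEUDO_COUNT_FACTOR * self.detection_limit

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def compute_rcq(
    table: AbundanceTable,
    irm_genus: str,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    mode: str = "per_sample",
    design: StudyDesign | None = None,
) -> RCQTable:
    """Divide every genus's relative abundance by the IRM's.

    ``per_sample`` (default) uses each sample's own IRM abundance as the
    denominator, which preserves per-sample values for rank tests.
    ``group_mean`` divides all samples of a group by the group-mean IRM
    abundance and requires ``design``. Counts or fraction input is
    total-sum scaled to percent first, so the pseudo-count is always on
    the percent scale (and RCQ is invariant to the input scale).
    """
    if irm_genus not in table.taxa:
        raise ValidationError(f"IRM genus {irm_genus!r} not in table")
    if detection_limit <= 0:
        raise ConfigurationError(f"detection limit must be > 0, got {detection_limit}")
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    if table.unit != "percent":
        table = total_sum_scale(table)
    pseudo = PSEUDO_COUNT_FACTOR * detection_limit
    values = table.data.to_numpy(dtype=float)
    irm = table.data.loc[irm_genus].to_numpy(dtype=float)

    if mode == "per_sample":
        denom = np.where(irm > 0, irm, pseudo)
        applied = irm == 0
    else:
        if design is None:
            raise ConfigurationError("group_mean mode requires a study design")
        design.check_covers(table)
        group_of = design.group_of_sample()
        denom = np.empty_like(irm)
        applied = np.zeros_like(irm, dtype=bool)
        groups = {group_of[s] for s in table.samples}
        for group in groups:
            cols = [j for j, s in enumerate(table.samples) if group_of[s] == group]
            gmean = irm[cols].mean()
            if gmean == 0:
                denom[cols] = pseudo
                applied[cols] = True
            else:
                denom[cols] = gmean
    if (denom < 2 * detection_limit).any():
        logger.warning(
            "IRM %r denominator below 2x detection limit in %d sample(s); "
            "normalization may be unstable near zero",
            irm_genus,
            int((denom < 2 * detection_limit).sum()),
        )
    rcq = values / denom
    # genera absent from a sample stay 0 even when the denominator was a
    # pseudo-count (0 / pseudo = 0 holds arithmetically; keep it explicit)
    rcq[values == 0] = 0.0
    return RCQTable(
        pd.DataFrame(rcq, index=table.data.index, columns=table.data.columns),
        irm_genus=irm_genus,
        detection_limit=detection_limit,
        mode=mode,
        pseudo_count_applied=pd.Series(applied, index=table.samples),
    )


def rcq_group_sums(rcq: RCQTable, design: StudyDesign) -> dict[str, float]:
    """Per group, the mean over samples of the per-sample sum of RCQ values.

    A diagnostic of how far the normalization moved the community away
    from closure (relative-abundance columns always sum to 100; RCQ
    columns do not). Reported for inspection only; the quantity has no
    closed-form target except in ``group_mean`` mode with a positive
    denominator, where each sample's sum equals 100 / group-mean IRM %.
    """
    out = {}
    for group in design.groups:
        samples = [s for s in design.samples_in_group(group) if s in rcq.data.columns]
        if not samples:
            raise DesignError(f"group {group!r} has no samples in the RCQ table")
        col_sums = rcq.data.loc[:, samples].sum(axis=0)
        out[group] = float(col_sums.mean())
    return out
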