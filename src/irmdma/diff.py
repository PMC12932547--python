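"""Differential genus screening on relative abundances (PA-DMA) or RCQ (IRMRA-DMA).

Both screens are the same machinery applied to a different scale:
Wilcoxon rank-sum for two groups, Kruskal-Wallis for three or more, a
low-abundance filter (group-mean relative abundance must exceed a
threshold in at least one group, evaluated on the percent scale even
when testing RCQ so the two methods share one genus universe), and a
direction call against a declared reference group. Raw p < alpha is the
default significance rule; Benjamini-Hochberg adjustment is available
by option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import AbundanceTable, StudyDesign, total_sum_scale
from .ranktests import (
    EXACT_CUTOFF,
    benjamini_hochberg,
    kruskal_wallis,
    spearman_rho,
    wilcoxon_rank_sum,
)
from .rcq import RCQTable

__all__ = [
    "ScreenConfig",
    "DiffTestResult",
    "run_dma",
    "wild_enriched_set",
    "results_to_frame",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "spearman_rho",
]

PA_DMA = "PA-DMA"
IRMRA_DMA = "IRMRA-DMA"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of a differential screen.

    alpha: significance level on the (possibly adjusted) p-value.
    abundance_threshold: low-abundance filter in percent relative
        abundance; a genus passes if its group mean exceeds it in >= 1
        group (strict >), always evaluated on the percent scale.
    mtc: multiple-testing mode, "none" (raw p, the default) or "bh".
    exact_cutoff: largest group size for the exact Wilcoxon distribution.
    center: "mean" or "median" — the per-group location used for
        direction calls and enrichment comparisons.
    """

    alpha: float = 0.05
    abundance_threshold: float = 0.005
    mtc: str = "none"
    exact_cutoff: int = EXACT_CUTOFF
    center: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.abundance_threshold < 0:
            raise ConfigurationError("abundance threshold must be >= 0")
        if self.mtc not in ("none", "bh"):
            raise ConfigurationError(f"mtc must be 'none' or 'bh', got {self.mtc!r}")
        if self.center not in ("mean", "median"):
            raise ConfigurationError(f"center must be 'mean' or 'median', got {self.center!r}")


@dataclass(frozen=True)
class DiffTestResult:
    genus: str
    method: str  # PA-DMA | IRMRA-DMA
    comparison: str  # e.g. "wild|cult1" or "wild|cult1|cult2"
    group_means: dict[str, float]  # per-group center on the tested scale
    statistic: float
    p: float
    p_adjusted: float
    direction: str  # up | down | none, relative to the reference group
    passed_abundance_filter: bool
    significant: bool
    reference: str


def _center(values: np.ndarray, how: str) -> float:
    return float(np.median(values)) if how == "median" else float(values.mean())


def _direction(ref: float, others: list[float]) -> str:
    if all(ref > o for o in others):
        return "up"
    if all(ref < o for o in others):
        return "down"
    return "none"


def run_dma(
    values,
    design: StudyDesign,
    groups: list[str],
    config: ScreenConfig = ScreenConfig(),
    method: str = PA_DMA,
    reference: str | None = None,
    filter_table: AbundanceTable | None = None,
) -> list[DiffTestResult]:
    """Screen every genus for differential abundance across ``groups``.

    ``values`` is an :class:`AbundanceTable` (PA-DMA) or an
    :class:`RCQTable` (IRMRA-DMA); the rank test runs on the supplied
    scale. The abundance filter always uses percent relative abundances:
    for PA-DMA the tested table itself (scaled if needed), for
    IRMRA-DMA a ``filter_table`` with the same taxa must be supplied.
    Results are sorted by p then genus name.
    """
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups to compare")
    if len(set(groups)) != len(groups):
        raise ConfigurationError(f"overlapping/duplicate groups: {groups}")
    reference = reference or groups[0]
    if reference not in groups:
        raise ConfigurationError(f"reference group {reference!r} not among {groups}")

    if isinstance(values, RCQTable):
        if filter_table is None:
            raise ConfigurationError(
                "IRMRA-DMA screening needs a percent-scale filter_table for the "
                "low-abundance filter"
            )
        test_data = values.data
    elif isinstance(values, AbundanceTable):
        if values.unit != "percent":
            values = total_sum_scale(values)
        test_data = values.data
        filter_table = filter_table or values
    else:
        raise ConfigurationError(f"unsupported values table type {type(values).__name__}")

    if filter_table.unit != "percent":
        filter_table = total_sum_scale(filter_table)
    if list(filter_table.taxa) != list(test_data.index):
        raise ValidationError("filter table and tested table cover different taxa")

    group_samples = {g: design.samples_in_group(g) for g in groups}
    seen: dict[str, str] = {}
    for g, ss in group_samples.items():
        for s in ss:
            if s in seen:
                raise ConfigurationError(f"sample {s!r} appears in groups {seen[s]!r} and {g!r}")
            seen[s] = g
    missing = [s for s in seen if s not in test_data.columns]
    if missing:
        raise ValidationError(f"samples not in tested table: {sorted(missing)}")

    comparison = "|".join(groups)
    others = [g for g in groups if g != reference]

    records = []
    for genus in test_data.index:
        by_group = {g: test_data.loc[genus, ss].to_numpy(dtype=float) for g, ss in group_samples.items()}
        if len(groups) == 2:
            stat, p = wilcoxon_rank_sum(
                by_group[groups[0]], by_group[groups[1]], exact_cutoff=config.exact_cutoff
            )
        else:
            stat, p = kruskal_wallis([by_group[g] for g in groups])
        centers = {g: _center(v, config.center) for g, v in by_group.items()}
        pa_means = {
            g: float(filter_table.data.loc[genus, ss].mean()) for g, ss in group_samples.items()
        }
        passed = any(m > config.abundance_threshold for m in pa_means.values())
        direction = _direction(centers[reference], [centers[g] for g in others])
        records.append((genus, centers, stat, p, passed, direction))

    pvals = np.array([r[3] for r in records])
    padj = benjamini_hochberg(pvals) if config.mtc == "bh" else pvals.copy()

    results = []
    for (genus, centers, stat, p, passed, direction), pa in zip(records, padj):
        significant = bool(passed and pa < config.alpha)
        results.append(
            DiffTestResult(
                genus=genus,
                method=method,
                comparison=comparison,
                group_means=centers,
                statistic=stat,
                p=float(p),
                p_adjusted=float(pa),
                direction=direction,
                passed_abundance_filter=passed,
                significant=significant,
                reference=reference,
            )
        )
    results.sort(key=lambda r: (r.p, r.genus))
    return results


def wild_enriched_set(
    results: list[DiffTestResult],
    target_group: str,
    comparison_groups: list[str],
) -> set[str]:
    """Genera significant in the k-group test AND strictly most abundant in the target.

    The location comparison is on the same scale the test used (the
    per-group centers stored in each result).
    """
    if target_group in comparison_groups:
        raise ConfigurationError(f"target group {target_group!r} is among the comparison groups")
    out = set()
    for r in results:
        needed = [target_group, *comparison_groups]
        missing = [g for g in needed if g not in r.group_means]
        if missing:
            raise ConfigurationError(
                f"result for {r.genus!r} lacks group(s) {missing}; was the test run on "
                "exactly target + comparison groups?"
            )
        if not r.significant:
            continue
        tgt = r.group_means[target_group]
        if all(tgt > r.group_means[g] for g in comparison_groups):
            out.add(r.genus)
    return out


def results_to_frame(results: list[DiffTestResult]) -> pd.DataFrame:
    """Tabulate results with volcano-ready columns.

    ``log2_fc`` is log2(reference center / comparator center) where the
    comparator is the first non-reference group; zero centers give
    +/-inf and 0/0 gives NaN, which plotting layers may clip.
    """
    rows = []
    for r in results:
        others = [g for g in r.group_means if g != r.reference]
        ref_c = r.group_means[r.reference]
        comp_c = r.group_means[others[0]] if others else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            l2fc = float(np.log2(np.float64(ref_c) / np.float64(comp_c)))
            nlp = float(-np.log10(r.p)) if r.p > 0 else np.inf
        row = {
            "genus": r.genus,
            "method": r.method,
            "comparison": r.comparison,
            "reference": r.reference,
            **{f"mean_{g}": v for g, v in r.group_means.items()},
            "statistic": r.statistic,
            "p": r.p,
            "p_adjusted": r.p_adjusted,
            "direction": r.direction,
            "passed_abundance_filter": r.passed_abundance_filter,
            "significant": r.significant,
            "log2_fc": l2fc,
            "neg_log10_p": nlp,
        }
        rows.append(row)
    return pd.DataFrame(rows)
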