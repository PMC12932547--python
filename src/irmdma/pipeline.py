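"""End-to-end orchestration: validate -> screen IRM -> normalize -> screen -> compare.

Every output file is plain TSV/JSON and records its provenance (method,
mode, thresholds, reference genus), so a rerun with the same inputs and
configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diff import IRMRA_DMA, PA_DMA, ScreenConfig, results_to_frame, run_dma, wild_enriched_set
from .errors import NoCandidateError
from .io import AbundanceTable, StudyDesign, read_abundance_table, read_design, total_sum_scale
from .irm import screen_irm
from .compare import compare_sets
from .rcq import DEFAULT_DETECTION_LIMIT, compute_rcq, rcq_group_sums

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    table: str
    design: str
    out_dir: str
    unit: str = "percent"
    irm: str = "auto"  # genus name, or "auto" to take the top-ranked passing candidate
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    irm_threshold: float = 0.005
    abundance_threshold: float = 0.005
    alpha: float = 0.05
    mode: str = "per_sample"
    mtc: str = "none"
    presence_rule: str = "any"
    groups: tuple[str, ...] = ()  # target groups to compare; empty = all target groups
    reference: str | None = None  # defaults to the first compared group
    seed: int = 0  # recorded for provenance; no resampling in the default tests

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        return cls(**d)


def _candidates_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "genus": c.genus,
                **{f"mean_{g}": m for g, m in c.group_means.items()},
                "min_group_mean": c.min_mean,
                "host_present_all_sites": all(c.host_presence.values()),
                "companion_absent_all_sites": all(c.companion_absence.values()),
                "passes_threshold": c.passes_threshold,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the result bundle.

    Writes ``irm_candidates.tsv``, ``rcq.tsv``, ``diff_pa.tsv``,
    ``diff_irm.tsv``, ``comparison.json`` and ``run_manifest.json`` into
    the output directory and returns the manifest dict. Raises
    :class:`NoCandidateError` when ``irm = "auto"`` finds no passing
    candidate (the CLI maps this to exit code 3) and a
    :class:`ValidationError` subclass on bad input (exit code 2).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = read_abundance_table(config.table, unit=config.unit)
    design = read_design(config.design)
    design.check_covers(table)
    pct = table if table.unit == "percent" else total_sum_scale(table)

    manifest: dict = {
        "irmdma_version": __version__,
        "config": {
            "table": str(config.table),
            "design": str(config.design),
            "unit": config.unit,
            "irm": config.irm,
            "detection_limit": config.detection_limit,
            "irm_threshold": config.irm_threshold,
            "abundance_threshold": config.abundance_threshold,
            "alpha": config.alpha,
            "mode": config.mode,
            "mtc": config.mtc,
            "presence_rule": config.presence_rule,
            "seed": config.seed,
        },
    }

    # --- reference-taxon screen -------------------------------------------
    if config.irm == "auto":
        sites_without_companions = [
            s for s in design.sites if not design.groups_at_site(s, "companion")
        ]
        if sites_without_companions:
            raise NoCandidateError(
                "automatic IRM screening needs a companion group at every site; "
                f"missing at: {sites_without_companions}"
            )
        candidates = screen_irm(pct, design, config.irm_threshold, config.presence_rule)
        _candidates_frame(candidates).to_csv(
            out / "irm_candidates.tsv", sep="\t", index=False, lineterminator="\n"
        )
        passing = [c for c in candidates if c.passes_threshold]
        if not passing:
            raise NoCandidateError(
                "automatic IRM screening found no genus that is host-specific at every "
                "site and above the abundance threshold in every host group"
            )
        irm_genus = passing[0].genus
        manifest["irm_candidates"] = [c.genus for c in candidates]
    else:
        irm_genus = config.irm
        (out / "irm_candidates.tsv").write_text(
            "genus\tsource\n%s\tuser-specified\n" % irm_genus, encoding="utf-8"
        )
    manifest["irm_genus"] = irm_genus

    # --- normalization -----------------------------------------------------
    rcq = compute_rcq(
        pct, irm_genus, detection_limit=config.detection_limit, mode=config.mode, design=design
    )
    rcq_df = rcq.data.copy()
    rcq_df.index.name = "taxon"
    rcq_df.to_csv(out / "rcq.tsv", sep="\t", lineterminator="\n")
    manifest["rcq"] = {
        "mode": rcq.mode,
        "detection_limit": rcq.detection_limit,
        "pseudo_count": rcq.pseudo_count,
        "pseudo_count_samples": sorted(
            rcq.pseudo_count_applied.index[rcq.pseudo_count_applied].tolist()
        ),
        "group_mean_rcq_sums": rcq_group_sums(rcq, design),
    }

    # --- differential screens ---------------------------------------------
    groups = list(config.groups) if config.groups else [
        g for site in design.sites for g in design.groups_at_site(site, "target")
    ]
    reference = config.reference or groups[0]
    comparisons = [g for g in groups if g != reference]
    screen = ScreenConfig(
        alpha=config.alpha, abundance_threshold=config.abundance_threshold, mtc=config.mtc
    )

    pa_results = run_dma(pct, design, groups, screen, method=PA_DMA, reference=reference)
    irm_results = run_dma(
        rcq, design, groups, screen, method=IRMRA_DMA, reference=reference, filter_table=pct
    )
    results_to_frame(pa_results).to_csv(
        out / "diff_pa.tsv", sep="\t", index=False, lineterminator="\n"
    )
    results_to_frame(irm_results).to_csv(
        out / "diff_irm.tsv", sep="\t", index=False, lineterminator="\n"
    )

    if len(groups) >= 3:
        set_pa = wild_enriched_set(pa_results, reference, comparisons)
        set_irm = wild_enriched_set(irm_results, reference, comparisons)
        compared = "wild_enriched"
    else:
        set_pa = {r.genus for r in pa_results if r.significant}
        set_irm = {r.genus for r in irm_results if r.significant}
        compared = "significant"

    comp = compare_sets(set_pa, set_irm)
    comparison = {
        "compared_sets": compared,
        "method_a": PA_DMA,
        "method_b": IRMRA_DMA,
        "common": sorted(comp.common),
        "a_only": sorted(comp.a_only),
        "b_only": sorted(comp.b_only),
        "n_common": len(comp.common),
        "n_a_only": len(comp.a_only),
        "n_b_only": len(comp.b_only),
    }
    (out / "comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    manifest["groups"] = groups
    manifest["reference"] = reference
    manifest["comparison"] = {
        k: comparison[k] for k in ("n_common", "n_a_only", "n_b_only", "compared_sets")
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
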