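"""Screening for an internal reference microorganism (IRM).

An IRM is a host-specific normalization anchor: a genus detected in the
target plant's rhizosphere at every sampled site, never detected in any
co-located companion plant's rhizosphere, and abundant enough in every
host group for a ratio denominator to be stable. Eligibility here is
purely distributional (presence/absence plus an abundance floor); no
phylogenetic or functional vetting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DesignError, ValidationError
from .io import AbundanceTable, StudyDesign, total_sum_scale

DEFAULT_IRM_THRESHOLD = 0.005  # percent relative abundance


@dataclass(frozen=True)
class PresenceProfile:
    genus: str
    group: str
    present: bool
    prevalence: float  # fraction of the group's samples with abundance > 0
    mean_abundance: float  # group-mean relative abundance (%)


@dataclass(frozen=True)
class IRMCandidate:
    genus: str
    host_presence: dict[str, bool]  # site -> present in target group(s)
    companion_absence: dict[str, bool]  # site -> absent from all companion groups
    group_means: dict[str, float]  # host group -> mean abundance (%)
    passes_threshold: bool

    @property
    def min_mean(self) -> float:
        return min(self.group_means.values())


def parse_presence_rule(rule: str) -> float:
    """Translate a presence rule into a minimum prevalence.

    ``"any"`` means detected (>0) in at least one sample; ``"prevalence:f"``
    requires detection in at least a fraction ``f`` of the group's samples.
    """
    if rule == "any":
        return 0.0
    if rule.startswith("prevalence:"):
        f = float(rule.split(":", 1)[1])
        if not 0 <= f <= 1:
            raise ConfigurationError(f"prevalence fraction must be in [0, 1], got {f}")
        return f
    raise ConfigurationError(f"unknown presence rule {rule!r}")


def presence_profile(
    table: AbundanceTable,
    design: StudyDesign,
    group: str,
    rule: str = "any",
) -> dict[str, PresenceProfile]:
    """Presence/absence profile of every genus within one group.

    Default rule: present iff detected (abundance > 0) in >= 1 sample of
    the group. A stricter ``prevalence:<f>`` rule requires detection in a
    fraction >= f of samples (``any`` is prevalence > 0).
    """
    min_prev = parse_presence_rule(rule)
    samples = design.samples_in_group(group)
    sub = table.subset_samples(samples).data
    detected = (sub.to_numpy(dtype=float) > 0)
    prevalence = detected.mean(axis=1)
    means = sub.to_numpy(dtype=float).mean(axis=1)
    profiles = {}
    for i, genus in enumerate(sub.index):
        prev = float(prevalence[i])
        present = prev >= min_prev and prev > 0
        profiles[genus] = PresenceProfile(genus, group, present, prev, float(means[i]))
    return profiles


def site_unique_genera(
    host_profiles: dict[str, PresenceProfile],
    companion_profiles: dict[str, PresenceProfile],
) -> set[str]:
    """Genera present in the host group and absent from the companion group."""
    if set(host_profiles) != set(companion_profiles):
        raise ValidationError("host and companion profiles cover different taxa")
    return {
        g
        for g, p in host_profiles.items()
        if p.present and not companion_profiles[g].present
    }


def irm_candidates(site_unique_sets: list[set[str]]) -> set[str]:
    """Intersect per-site host-unique genus sets across all screened sites."""
    if len(site_unique_sets) < 2:
        raise ConfigurationError(
            f"IRM screening needs >= 2 sites, got {len(site_unique_sets)}"
        )
    return set.intersection(*site_unique_sets)


def apply_irm_threshold(
    candidates: set[str],
    table: AbundanceTable,
    design: StudyDesign,
    host_groups: list[str],
    threshold: float = DEFAULT_IRM_THRESHOLD,
) -> list[IRMCandidate]:
    """Flag candidates whose group-mean abundance reaches ``threshold`` in EVERY host group.

    The comparison is inclusive (>=). Output is ranked by the minimum
    across-group mean, descending, ties broken lexicographically — when
    several genera qualify all are reported; no silent winner is picked.
    """
    if threshold <= 0:
        raise ConfigurationError(f"threshold must be > 0, got {threshold}")
    unknown = set(candidates) - set(table.taxa)
    if unknown:
        raise ValidationError(f"candidate genera not in table: {sorted(unknown)}")
    if table.unit != "percent":
        table = total_sum_scale(table)
    # Sites where a candidate was screened: presence/absence flags recomputed
    # for the report so each candidate record is self-contained.
    out = []
    for genus in candidates:
        means = {}
        for group in host_groups:
            samples = design.samples_in_group(group)
            means[group] = float(table.data.loc[genus, samples].mean())
        host_presence = {}
        companion_absence = {}
        for site in design.sites:
            tgt = design.groups_at_site(site, "target")
            comp = design.groups_at_site(site, "companion")
            if tgt:
                host_presence[site] = all(
                    (table.data.loc[genus, design.samples_in_group(g)] > 0).any()
                    for g in tgt
                )
            if comp:
                companion_absence[site] = all(
                    not (table.data.loc[genus, design.samples_in_group(g)] > 0).any()
                    for g in comp
                )
        passes = all(m >= threshold for m in means.values())
        out.append(IRMCandidate(genus, host_presence, companion_absence, means, passes))
    out.sort(key=lambda c: (-c.min_mean, c.genus))
    return out


def screen_irm(
    table: AbundanceTable,
    design: StudyDesign,
    threshold: float = DEFAULT_IRM_THRESHOLD,
    rule: str = "any",
) -> list[IRMCandidate]:
    """Full IRM screen: per-site host-unique sets -> cross-site intersection -> threshold.

    Each site contributes one host-unique set: genera present (under
    ``rule``) in every target group at the site and absent from every
    companion group at the site. Sites without a companion group cannot
    be screened and raise a :class:`DesignError`.
    """
    design.check_covers(table)
    if table.unit != "percent":
        table = total_sum_scale(table)
    site_sets = []
    host_groups: list[str] = []
    for site in design.sites:
        targets = design.groups_at_site(site, "target")
        companions = design.groups_at_site(site, "companion")
        if not targets:
            raise DesignError(f"site {site!r} has no target group")
        if not companions:
            raise DesignError(f"site {site!r} has no companion group; cannot screen IRM")
        host_groups.extend(g for g in targets if g not in host_groups)
        present_all_targets = None
        for g in targets:
            prof = presence_profile(table, design, g, rule)
            s = {genus for genus, p in prof.items() if p.present}
            present_all_targets = s if present_all_targets is None else present_all_targets & s
        absent_all_companions = set(table.taxa)
        for g in companions:
            prof = presence_profile(table, design, g, rule="any")
            absent_all_companions -= {genus for genus, p in prof.items() if p.present}
        site_sets.append((present_all_targets or set()) & absent_all_companions)
    cands = irm_candidates(site_sets)
    return apply_irm_threshold(cands, table, design, host_groups, threshold)
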