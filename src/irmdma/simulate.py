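"""Synthetic genus communities with known ground truth, and a method benchmark.

The generator works at the genus-table level (no read simulation): each
taxon has an absolute abundance per sample in arbitrary units, samples
are closed to proportions and sequenced as a multinomial draw at a fixed
depth, and the percent table is derived from the counts. Because the
absolute scale is known, every taxon carries an exact truth flag for any
group contrast — the currency the benchmark trades in.

Two mechanisms central to the compositional false-positive problem are
built in:

* a *bloomer* taxon whose absolute surge in some groups shifts total
  microbial load, mechanically depressing every other taxon's relative
  abundance without touching its absolute abundance;
* a designated *reference taxon* (IRM) with a stable absolute level in
  all target-host groups and absolute absence in companion groups, so
  the host-specificity screen is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .diff import IRMRA_DMA, PA_DMA, ScreenConfig, run_dma
from .io import AbundanceTable, StudyDesign
from .rcq import DEFAULT_DETECTION_LIMIT, compute_rcq


@dataclass(frozen=True)
class GroupSpec:
    name: str
    site: str
    role: str  # target | companion
    n_samples: int = 6


@dataclass(frozen=True)
class TaxonEffect:
    """A multiplicative fold change on the ABSOLUTE scale for one taxon in one group."""

    taxon: int
    group: str
    fold: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to draw a community with known truth.

    Per-taxon baseline absolute abundances are log-normal
    (``baseline_log_mean``/``baseline_log_sd``), optionally pinned for
    specific taxa via ``baseline_override`` (used to give a bloomer a
    large share of the community). Per-sample noise is an independent
    log-normal factor with ``noise_log_sd``. ``irm_taxon`` has its
    absolute level set directly per group via ``irm_levels`` (0 in
    companion groups). ``differential`` lists planted signal taxa,
    ``bloomers`` lists load-shifting taxa; both are folds on the
    absolute scale.
    """

    n_taxa: int
    groups: tuple[GroupSpec, ...]
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 0.3
    noise_log_sd: float = 0.3
    differential: tuple[TaxonEffect, ...] = ()
    bloomers: tuple[TaxonEffect, ...] = ()
    baseline_override: dict[int, float] = field(default_factory=dict)
    irm_taxon: int = 0
    irm_levels: dict[str, float] = field(default_factory=dict)
    depth: int = 50_000
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ConfigurationError("need >= 2 taxa")
        if not self.groups:
            raise ConfigurationError("need >= 1 group")
        if any(g.n_samples < 1 for g in self.groups):
            raise ConfigurationError("every group needs >= 1 sample")
        if self.depth < 1:
            raise ConfigurationError("sequencing depth must be >= 1")
        for eff in (*self.differential, *self.bloomers):
            if eff.fold <= 0:
                raise ConfigurationError(f"fold changes must be > 0, got {eff.fold}")
            if not 0 <= eff.taxon < self.n_taxa:
                raise ConfigurationError(f"taxon index {eff.taxon} out of range")
        if not 0 <= self.irm_taxon < self.n_taxa:
            raise ConfigurationError(f"IRM taxon index {self.irm_taxon} out of range")
        names = {g.name for g in self.groups}
        for eff in (*self.differential, *self.bloomers):
            if eff.group not in names:
                raise ConfigurationError(f"effect group {eff.group!r} not in scenario groups")
        for g in self.groups:
            if g.role == "target" and self.irm_levels.get(g.name, 0.0) <= 0:
                raise ConfigurationError(
                    f"target group {g.name!r} needs a positive IRM level in a stable-IRM scenario"
                )

    def taxon_name(self, i: int) -> str:
        return f"g{i:03d}"

    @property
    def irm_genus(self) -> str:
        return self.taxon_name(self.irm_taxon)

    @property
    def target_groups(self) -> list[str]:
        return [g.name for g in self.groups if g.role == "target"]

    def expected_fold(self, taxon: int, group: str) -> float:
        """Net absolute-scale fold applied to a taxon in a group (1 = baseline)."""
        f = 1.0
        for eff in (*self.differential, *self.bloomers):
            if eff.taxon == taxon and eff.group == group:
                f *= eff.fold
        return f


@dataclass(frozen=True)
class SyntheticCommunity:
    """A drawn community: absolute truth, sampled counts, derived percent table."""

    absolute: pd.DataFrame = field(repr=False)  # taxa x samples, arbitrary units
    counts: pd.DataFrame = field(repr=False)  # multinomial draws at fixed depth
    design: StudyDesign
    config: ScenarioConfig
    seed: int

    @property
    def total_load(self) -> pd.Series:
        return self.absolute.sum(axis=0)

    @property
    def percent_table(self) -> AbundanceTable:
        pct = self.counts / self.counts.sum(axis=0) * 100.0
        return AbundanceTable(pct, "percent")

    @property
    def count_table(self) -> AbundanceTable:
        return AbundanceTable(self.counts.astype(float), "counts")

    def truth_differential(self, group_a: str, group_b: str) -> set[str]:
        """Taxa truly differential on the ABSOLUTE scale between two groups."""
        cfg = self.config
        out = set()
        for i in range(cfg.n_taxa):
            if i == cfg.irm_taxon:
                la = cfg.irm_levels.get(group_a, 0.0)
                lb = cfg.irm_levels.get(group_b, 0.0)
                if la != lb:
                    out.add(cfg.taxon_name(i))
            elif cfg.expected_fold(i, group_a) != cfg.expected_fold(i, group_b):
                out.add(cfg.taxon_name(i))
        return out


def simulate_community(config: ScenarioConfig, seed: int) -> SyntheticCommunity:
    """Draw one community: log-normal absolute abundances -> multinomial counts.

    Fully reproducible: (config, seed) determines every draw through one
    ``numpy.random.default_rng`` stream.
    """
    rng = np.random.default_rng(seed)
    n = config.n_taxa
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    for i, level in config.baseline_override.items():
        base[i] = level

    sample_ids, rows = [], []
    for g in config.groups:
        for r in range(1, g.n_samples + 1):
            sid = f"{g.name}_r{r}"
            sample_ids.append(sid)
            rows.append((sid, g.site, g.role, g.name, str(r)))
    n_samples = len(sample_ids)

    means = np.empty((n, n_samples))
    col = 0
    for g in config.groups:
        m = base.copy()
        for i in range(n):
            m[i] *= config.expected_fold(i, g.name)
        m[config.irm_taxon] = config.irm_levels.get(g.name, 0.0)
        for _ in range(g.n_samples):
            means[:, col] = m
            col += 1

    noise = np.exp(rng.normal(0.0, config.noise_log_sd, size=(n, n_samples)))
    absolute = means * noise  # zero means stay exactly zero

    totals = absolute.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("a sample drew zero total load; check the scenario")
    props = absolute / totals
    counts = np.empty((n, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(config.depth, props[:, j])

    taxa = pd.Index([config.taxon_name(i) for i in range(n)], name="taxon")
    design = StudyDesign(
        pd.DataFrame(rows, columns=["sample", "site", "host_role", "group", "replicate"])
    )
    return SyntheticCommunity(
        absolute=pd.DataFrame(absolute, index=taxa, columns=sample_ids),
        counts=pd.DataFrame(counts, index=taxa, columns=sample_ids),
        design=design,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

def _three_site_groups(n_samples: int = 6) -> tuple[GroupSpec, ...]:
    """One wild and two cultivated target groups, each with a companion plot."""
    return (
        GroupSpec("wild", "site1", "target", n_samples),
        GroupSpec("cult1", "site2", "target", n_samples),
        GroupSpec("cult2", "site3", "target", n_samples),
        GroupSpec("comp_wild", "site1", "companion", n_samples),
        GroupSpec("comp_cult1", "site2", "companion", n_samples),
        GroupSpec("comp_cult2", "site3", "companion", n_samples),
    )


def null_load_shift(
    n_taxa: int = 200,
    n_samples: int = 6,
    depth: int = 50_000,
    bloom_fold: float = 20.0,
) -> ScenarioConfig:
    """No real signal, but a bloomer shifts total load in the two cultivated groups.

    The bloomer starts at roughly a third of the community's absolute
    load and surges 20-fold in the cultivated groups, so every other
    taxon's relative abundance is compressed there while its absolute
    abundance is untouched — the textbook closure artifact. The
    reference taxon holds an absolute level of 1 in all target groups.
    """
    bloomer = 1
    return ScenarioConfig(
        n_taxa=n_taxa,
        groups=_three_site_groups(n_samples),
        baseline_log_mean=0.0,
        baseline_log_sd=0.3,
        noise_log_sd=0.3,
        differential=(),
        bloomers=(
            TaxonEffect(bloomer, "cult1", bloom_fold),
            TaxonEffect(bloomer, "cult2", bloom_fold),
        ),
        baseline_override={bloomer: 0.5 * n_taxa},
        irm_taxon=0,
        irm_levels={"wild": 1.0, "cult1": 1.0, "cult2": 1.0},
        depth=depth,
        label="null_load_shift",
    )


def planted_signal(
    n_taxa: int = 50,
    n_samples: int = 6,
    depth: int = 50_000,
    n_planted: int = 10,
    fold: float = 4.0,
) -> ScenarioConfig:
    """Ten wild-enriched taxa at 4-fold absolute enrichment, no load shift.

    Taxa 1..n_planted are elevated in the wild group on the absolute
    scale; the reference taxon (index 0) is stable across target groups
    and absent from companions, so the automatic host-specificity screen
    should recover it.
    """
    return ScenarioConfig(
        n_taxa=n_taxa,
        groups=_three_site_groups(n_samples),
        baseline_log_mean=0.0,
        baseline_log_sd=0.3,
        noise_log_sd=0.3,
        differential=tuple(TaxonEffect(i, "wild", fold) for i in range(1, n_planted + 1)),
        bloomers=(),
        irm_taxon=0,
        irm_levels={"wild": 1.0, "cult1": 1.0, "cult2": 1.0},
        depth=depth,
        label="planted_signal",
    )


BUILTIN_SCENARIOS = {
    "null_load_shift": null_load_shift,
    "planted_signal": planted_signal,
}


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a plain mapping (YAML/JSON scenario file).

    A mapping with just ``{"builtin": name}`` (plus optional overrides
    understood by the builtin) loads a named built-in scenario.
    """
    d = dict(d)
    if "builtin" in d:
        name = d.pop("builtin")
        if name not in BUILTIN_SCENARIOS:
            raise ConfigurationError(
                f"unknown builtin scenario {name!r}; available: {sorted(BUILTIN_SCENARIOS)}"
            )
        return BUILTIN_SCENARIOS[name](**d)
    d["groups"] = tuple(GroupSpec(**g) for g in d.get("groups", ()))
    d["differential"] = tuple(TaxonEffect(**e) for e in d.get("differential", ()))
    d["bloomers"] = tuple(TaxonEffect(**e) for e in d.get("bloomers", ()))
    d["baseline_override"] = {int(k): float(v) for k, v in d.get("baseline_override", {}).items()}
    return ScenarioConfig(**d)


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkResult:
    """Per-method error rates averaged over replicates, plus the per-rep table."""

    summary: pd.DataFrame = field(repr=False)  # index: method; columns: fpr, tpr
    per_rep: pd.DataFrame = field(repr=False)  # columns: rep, method, fpr, tpr
    n_reps: int
    alpha: float
    groups: tuple[str, str]

    @property
    def reps_pa_exceeds_irm(self) -> int:
        """Replicates in which the PA screen's FPR strictly exceeds the ratio screen's."""
        wide = self.per_rep.pivot(index="rep", columns="method", values="fpr")
        return int((wide[PA_DMA] > wide[IRMRA_DMA]).sum())


def _rates(significant: set[str], truth: set[str], universe: list[str]) -> tuple[float, float]:
    nulls = [g for g in universe if g not in truth]
    fp = sum(1 for g in nulls if g in significant)
    tp = sum(1 for g in truth if g in significant)
    fpr = fp / len(nulls) if nulls else 0.0
    tpr = tp / len(truth) if truth else 0.0
    return fpr, tpr


def run_benchmark(
    config: ScenarioConfig,
    seed: int,
    n_reps: int = 100,
    alpha: float = 0.05,
    groups: tuple[str, str] | None = None,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    abundance_threshold: float = 0.005,
) -> BenchmarkResult:
    """Repeatedly simulate ``config`` and score PA-DMA vs IRMRA-DMA error rates.

    For each replicate (seeded deterministically as ``seed + rep``), a
    two-group Wilcoxon screen runs on the percent table (PA-DMA) and on
    the RCQ table normalized to the scenario's designated reference
    taxon (IRMRA-DMA). FPR is the fraction of truly-null taxa called
    significant, TPR the fraction of planted differential taxa
    recovered, each averaged over replicates. Default contrast: the
    first two target groups.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    targets = config.target_groups
    if groups is None:
        if len(targets) < 2:
            raise ConfigurationError("scenario has fewer than 2 target groups")
        groups = (targets[0], targets[1])
    screen = ScreenConfig(alpha=alpha, abundance_threshold=abundance_threshold)
    irm_genus = config.irm_genus

    rows = []
    for rep in range(n_reps):
        comm = simulate_community(config, seed=seed + rep)
        pct = comm.percent_table
        if irm_genus not in pct.taxa:
            raise ValidationError(f"IRM taxon {irm_genus!r} absent from the generated table")
        truth = comm.truth_differential(*groups)
        universe = pct.taxa

        pa_res = run_dma(pct, comm.design, list(groups), screen, method=PA_DMA)
        pa_sig = {r.genus for r in pa_res if r.significant}
        fpr, tpr = _rates(pa_sig, truth, universe)
        rows.append({"rep": rep, "method": PA_DMA, "fpr": fpr, "tpr": tpr})

        rcq = compute_rcq(pct, irm_genus, detection_limit=detection_limit)
        irm_res = run_dma(
            rcq, comm.design, list(groups), screen, method=IRMRA_DMA, filter_table=pct
        )
        irm_sig = {r.genus for r in irm_res if r.significant}
        fpr, tpr = _rates(irm_sig, truth, universe)
        rows.append({"rep": rep, "method": IRMRA_DMA, "fpr": fpr, "tpr": tpr})

    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby("method")[["fpr", "tpr"]].mean()
    return BenchmarkResult(
        summary=summary, per_rep=per_rep, n_reps=n_reps, alpha=alpha, groups=groups
    )
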