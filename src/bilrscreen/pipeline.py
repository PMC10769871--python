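"""Top-level workflows: candidate discovery and cohort profiling.

``run_discovery`` composes the comparative screen (orthogroup clustering,
oxidoreductase filter, phenotype-pattern match) with the profile-HMM
classification of a protein family. ``run_profiling`` runs the per-sample
metagenome workflow and the cohort prevalence comparisons. Both are
deterministic for a fixed config + seed and emit a machine-readable
:class:`RunReport`.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field

from . import hmm, profiler, screen
from .config import RunConfig
from .synthetic import BilrFamilyFixture, MetagenomeFixture, PangenomeFixture

__all__ = ["RunReport", "DiscoveryResult", "ProfilingResult", "run_discovery", "run_profiling"]


@dataclass
class RunReport:
    """Per-stage record counts and a parameter echo."""

    stages: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    wall_clock_s: float = 0.0

    def log(self, stage: str, **counts) -> None:
        self.stages[stage] = {**self.stages.get(stage, {}), **counts}
        msg = ", ".join(f"{k}={v}" for k, v in counts.items())
        print(f"[{stage}] {msg}", file=sys.stderr)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "parameters": self.parameters,
            "seed": self.seed,
            "wall_clock_s": self.wall_clock_s,
        }


@dataclass
class DiscoveryResult:
    screen_result: screen.ScreenResult
    calls: list[hmm.BilRCall]
    profile: hmm.ProfileHMM
    report: RunReport


@dataclass
class ProfilingResult:
    profiles: list[profiler.SampleProfile]
    prevalence: dict[str, profiler.PrevalenceResult]
    age_bins: dict[int, tuple[int, int, float]]
    report: RunReport


def run_discovery(
    pangenome: PangenomeFixture | None,
    family: BilrFamilyFixture | None,
    config: RunConfig | None = None,
    groups: list[screen.Orthogroup] | None = None,
) -> DiscoveryResult:
    """Candidate discovery: comparative screen + profile-HMM classification.

    ``groups`` short-circuits the RBH clustering with precomputed
    orthogroups (e.g. recorded fixture truth); otherwise the pangenome's
    proteomes are clustered here.
    """
    config = config or RunConfig()
    t0 = time.time()
    report = RunReport(parameters=config.to_dict(), seed=config.seed)

    screen_result = screen.ScreenResult(candidates=[], audit={})
    if pangenome is not None:
        if groups is None:
            groups = screen.cluster_orthogroups(
                pangenome.proteomes,
                min_score_ratio=config.min_score_ratio,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
        report.log(
            "cluster",
            proteins_in=sum(len(p) for p in pangenome.proteomes.values()),
            groups_out=len(groups),
        )
        screen_result = screen.screen_candidates(
            groups,
            pangenome.ec_table,
            pangenome.phenotype,
            min_members=config.min_ec_members,
            all_members=config.ec_all_members,
        )
        n_ox = sum(1 for a in screen_result.audit.values() if a["oxidoreductase_pass"])
        report.log(
            "screen",
            groups_in=len(groups),
            oxidoreductase_groups=n_ox,
            candidates=len(screen_result.candidates),
        )

    calls: list[hmm.BilRCall] = []
    profile = None
    if family is not None:
        profile = hmm.build_profile(
            family.clade1_alignment(),
            family.reference_id,
            reference_residue_span=(1, family.core_length),
            motif_reference_positions=family.motif_positions,
        )
        profile = hmm.calibrate(
            profile,
            n_random=config.calibration_n,
            random_length=config.calibration_length,
            seed=config.seed,
        )
        report.log("hmm_build", match_columns=profile.n_match, mu=round(profile.mu, 3))
        calls = hmm.scan_database(
            profile,
            dict(family.sequences),
            family.domain_table,
            evalue_max=config.evalue_max,
            min_length_fraction=config.min_length_fraction,
            motif=config.motif,
            motif_mode=config.motif_mode,
        )
        verdicts = {}
        for c in calls:
            verdicts[c.verdict] = verdicts.get(c.verdict, 0) + 1
        report.log("classify", targets=len(calls), **verdicts)

    report.wall_clock_s = time.time() - t0
    return DiscoveryResult(
        screen_result=screen_result, calls=calls, profile=profile, report=report
    )


DEFAULT_COMPARISONS = (
    ("infant", "healthy_adult"),
    ("CD", "healthy_adult"),
    ("UC", "healthy_adult"),
)


def run_profiling(
    metagenome: MetagenomeFixture | list,
    gene_refs: list[str] | None = None,
    host_ref: str | None = None,
    config: RunConfig | None = None,
    comparisons=DEFAULT_COMPARISONS,
) -> ProfilingResult:
    """Per-sample bilR profiling plus cohort prevalence comparisons.

    Accepts a :class:`MetagenomeFixture` or a raw sample list
    ``[(sample_id, reads, age_days, cohort), ...]`` with explicit
    references. Prevalence is compared (absence proportions) for each
    cohort pair in ``comparisons`` present in the data.
    """
    config = config or RunConfig()
    t0 = time.time()
    report = RunReport(parameters=config.to_dict(), seed=config.seed)
    if isinstance(metagenome, MetagenomeFixture):
        samples = metagenome.samples
        gene_refs = metagenome.gene_refs
        host_ref = metagenome.host_ref
    else:
        samples = metagenome
        if gene_refs is None or host_ref is None:
            raise ValueError("raw sample lists need explicit gene_refs and host_ref")

    profiles = []
    for sid, reads, age, cohort in samples:
        profiles.append(
            profiler.profile_sample(
                sid,
                reads,
                gene_refs,
                host_ref,
                cohort=cohort,
                age_days=age,
                min_reads=config.min_reads,
                cpm_threshold=config.cpm_threshold,
                host_k=config.host_k,
                map_k=config.map_k,
                min_identity=config.min_identity,
                min_shared_fraction=config.min_shared_fraction,
                cpm_denominator=config.cpm_denominator,
            )
        )
    report.log(
        "profile",
        samples_in=len(profiles),
        qc_pass=sum(p.qc_pass for p in profiles),
        present=sum(p.present for p in profiles if p.qc_pass),
    )

    groups, audit = profiler.cohort_filter(
        profiles, healthy_min_age_days=config.healthy_min_age_days
    )
    report.log("cohort_filter", **audit)

    age_bins = profiler.bin_by_age(
        groups["infant"],
        bin_width_days=config.age_bin_days,
        range_days=config.age_range_days,
    )

    prevalence = {}
    for a, b in comparisons:
        ga, gb = groups.get(a, []), groups.get(b, [])
        if not ga or not gb:
            continue
        res = profiler.prevalence_test(
            sum(not s.present for s in ga),
            len(ga),
            sum(not s.present for s in gb),
            len(gb),
            continuity_correction=config.continuity_correction,
            labels=(a, b),
        )
        prevalence[f"{a}_vs_{b}"] = res
        report.log(f"prevalence:{a}_vs_{b}", statistic=round(res.statistic, 4), p=res.p_value)

    report.wall_clock_s = time.time() - t0
    return ProfilingResult(
        profiles=profiles, prevalence=prevalence, age_bins=age_bins, report=report
    )
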