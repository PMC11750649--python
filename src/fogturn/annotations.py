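"""Gold-standard outcomes derived from episode annotations.

Expert video annotation of freezing episodes is the reference against which
the sensor metrics are validated.  This module derives from interval
annotations:

* percent time frozen (%TF) — total and split by trembling / akinetic type,
* the episode-type labelling rule (trembling iff oscillation visible for
  strictly more than 50% of the episode),
* a deterministic two-rater consensus policy, and
* the four-way subgrouping of subjects by crossing self-reported freezing
  (questionnaire item) with expert-observed freezing:
  non-freezer, unaware (expert-only), aware (both), possible (self-report only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import Episode, FogAnnotation

SUBGROUPS = ("non_freezer", "unaware", "aware", "possible")


@dataclass(frozen=True)
class AnnotationSummary:
    """%TF outcomes and episode counts for one trial.

    Episode types are exclusive, so ``tf_total_pct`` always equals
    ``tf_trembling_pct + tf_akinetic_pct``.
    """

    tf_total_pct: float
    tf_trembling_pct: float
    tf_akinetic_pct: float
    n_episodes_trembling: int
    n_episodes_akinetic: int


@dataclass
class SubjectRecord:
    """Self-report, expert classification and derived subgroup for a subject."""

    subject_id: str
    self_report_fog: bool
    nfogq_total: int
    expert_freezer: bool
    subgroup: str
    annotation_summary: AnnotationSummary | None = None
    covariates: dict = field(default_factory=dict)


def label_episode_type(trembling_fraction: float) -> str:
    """Label an episode from the fraction of its duration showing 3-8 Hz leg oscillation.

    Trembling requires oscillation for *strictly more than* half the episode;
    exactly 50% is labelled akinetic.
    """
    if not 0.0 <= trembling_fraction <= 1.0:
        raise ValueError(f"trembling_fraction={trembling_fraction} outside [0, 1]")
    return "trembling" if trembling_fraction > 0.5 else "akinetic"


def percent_time_frozen(annotation: FogAnnotation) -> AnnotationSummary:
    """Percent of trial duration spent frozen, overall and per episode type."""
    annotation.validate()
    dur = annotation.trial_duration_s
    if dur <= 0:
        raise ValueError("trial duration must be positive")
    t_tremble = sum(e.duration_s for e in annotation.episodes if e.type == "trembling")
    t_akinetic = sum(e.duration_s for e in annotation.episodes if e.type == "akinetic")
    return AnnotationSummary(
        tf_total_pct=100.0 * (t_tremble + t_akinetic) / dur,
        tf_trembling_pct=100.0 * t_tremble / dur,
        tf_akinetic_pct=100.0 * t_akinetic / dur,
        n_episodes_trembling=sum(e.type == "trembling" for e in annotation.episodes),
        n_episodes_akinetic=sum(e.type == "akinetic" for e in annotation.episodes),
    )


def _jaccard(a: Episode, b: Episode) -> float:
    inter = max(0.0, min(a.end_s, b.end_s) - max(a.start_s, b.start_s))
    union = max(a.end_s, b.end_s) - min(a.start_s, b.start_s)
    return inter / union if union > 0 else 0.0


def consensus_episodes(
    rater_a: FogAnnotation,
    rater_b: FogAnnotation,
    min_overlap: float = 0.5,
) -> FogAnnotation:
    """Deterministic stand-in for the human moderator step.

    Episodes from the two raters are greedily paired by interval overlap
    (Jaccard).  A pair with Jaccard >= ``min_overlap`` is retained: if the
    type labels agree the consensus interval is the union of the two; if they
    disagree the consensus shrinks to the intersection, takes rater A's label
    and is flagged.  Unmatched episodes are dropped and flagged.
    """
    rater_a.validate()
    rater_b.validate()
    if rater_a.trial_duration_s != rater_b.trial_duration_s:
        raise ValueError(
            f"raters annotate different durations: "
            f"{rater_a.trial_duration_s} vs {rater_b.trial_duration_s}"
        )

    pairs: list[tuple[float, int, int]] = []
    for i, ea in enumerate(rater_a.episodes):
        for j, eb in enumerate(rater_b.episodes):
            jac = _jaccard(ea, eb)
            if jac >= min_overlap:
                pairs.append((jac, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    consensus: list[Episode] = []
    flags: list[str] = []
    for jac, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ea, eb = rater_a.episodes[i], rater_b.episodes[j]
        if ea.type == eb.type:
            consensus.append(
                Episode(min(ea.start_s, eb.start_s), max(ea.end_s, eb.end_s), ea.type)
            )
        else:
            start = max(ea.start_s, eb.start_s)
            end = min(ea.end_s, eb.end_s)
            consensus.append(Episode(start, end, ea.type))
            flags.append(
                f"type disagreement at [{start:g}, {end:g}) s: "
                f"{rater_a.rater_id}={ea.type}, {rater_b.rater_id}={eb.type}; kept {ea.type}"
            )
    for i, ea in enumerate(rater_a.episodes):
        if i not in used_a:
            flags.append(
                f"unmatched episode [{ea.start_s:g}, {ea.end_s:g}) s from {rater_a.rater_id}"
            )
    for j, eb in enumerate(rater_b.episodes):
        if j not in used_b:
            flags.append(
                f"unmatched episode [{eb.start_s:g}, {eb.end_s:g}) s from {rater_b.rater_id}"
            )

    return FogAnnotation(
        rater_id=f"consensus({rater_a.rater_id},{rater_b.rater_id})",
        episodes=consensus,
        trial_duration_s=rater_a.trial_duration_s,
        disagreements=flags,
    ).validate()


def assign_subgroup(self_report: bool, expert: bool) -> str:
    """Map (self-report, expert) flags to the unique subgroup.

    (False, False) -> non_freezer; (False, True) -> unaware;
    (True, True) -> aware; (True, False) -> possible.
    """
    if expert:
        return "aware" if self_report else "unaware"
    return "possible" if self_report else "non_freezer"


def cohort_partition(records: list[SubjectRecord]) -> pd.DataFrame:
    """Count subjects per subgroup, with the percentages reported for a cohort.

    Percentages are of the whole cohort, and additionally of the relevant
    reference denominator: unaware/aware as a share of expert-rated freezers,
    possible as a share of self-reported freezers.
    """
    n = len(records)
    counts = {g: 0 for g in SUBGROUPS}
    for rec in records:
        expected = assign_subgroup(rec.self_report_fog, rec.expert_freezer)
        if rec.subgroup != expected:
            raise ValueError(
                f"subject {rec.subject_id}: subgroup {rec.subgroup!r} inconsistent "
                f"with flags (self={rec.self_report_fog}, expert={rec.expert_freezer})"
            )
        counts[rec.subgroup] += 1
    n_expert = counts["unaware"] + counts["aware"]
    n_self = counts["aware"] + counts["possible"]

    def pct(x, denom):
        return 100.0 * x / denom if denom else 0.0

    rows = []
    for g in SUBGROUPS:
        denom_name, denom = {
            "non_freezer": ("cohort", n),
            "unaware": ("expert_freezers", n_expert),
            "aware": ("expert_freezers", n_expert),
            "possible": ("self_reported", n_self),
        }[g]
        rows.append(
            {
                "subgroup": g,
                "count": counts[g],
                "pct_of_cohort": pct(counts[g], n),
                "reference_denominator": denom_name,
                "pct_of_reference": pct(counts[g], denom),
            }
        )
    rows.append(
        {
            "subgroup": "expert_freezers",
            "count": n_expert,
            "pct_of_cohort": pct(n_expert, n),
            "reference_denominator": "cohort",
            "pct_of_reference": pct(n_expert, n),
        }
    )
    rows.append(
        {
            "subgroup": "self_reported",
            "count": n_self,
            "pct_of_cohort": pct(n_self, n),
            "reference_denominator": "cohort",
            "pct_of_reference": pct(n_self, n),
        }
    )
    return pd.DataFrame(rows)
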