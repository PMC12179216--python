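"""Imaging-based disease staging from structure-level FA parameters.

Each of the 36 structure FA means is z-transformed against the control
group's mean and standard deviation; the z-values of a pattern's member
structures are arithmetically averaged into a pattern-specific <FA> score.
Scores are reported on a shifted scale with the control average centered
at 0.5 (a raw-z scale is available as a toggle), so the affectation
threshold mu - 0.47 sigma becomes 0.5 - 0.47 = 0.03 on the reported scale.
With normally distributed control scores the fixed offset 0.47 leaves 68%
of controls above the threshold by construction.

A subject's three affectation bits map onto imaging-based categorization
steps: CS-alpha when pattern 1 alone is affected (pattern 3 is ignored),
CS-beta when patterns 1 and 2 but not 3 are affected, CS-chi when all
three are affected, and "uncategorized" whenever pattern 1 is spared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, SampleSizeError, ScoringError
from .synthetic import AtlasDefinition

logger = logging.getLogger("pspdti")

DEFAULT_THRESHOLD_OFFSET = 0.47
#: Minimum fraction of non-missing member structures for a pattern mean.
MIN_PATTERN_COVERAGE = 0.5

CATEGORIES = ("CSalpha", "CSbeta", "CSchi", "uncategorized")


@dataclass
class ControlReference:
    """Per-structure control mean and SD used for the z-transformation."""

    mu: pd.Series
    sigma: pd.Series
    n_controls: int


@dataclass
class PatternScores:
    subject_id: str
    timepoint: str
    scores: tuple[float, float, float]  # patterns 1..3, reported scale
    affected: tuple[bool, bool, bool]
    scale: str = "shifted"  # "shifted" (controls at 0.5) or "raw_z"


@dataclass
class CategoryResult:
    subject_id: str
    timepoint: str
    category: str  # one of CATEGORIES


@dataclass
class LongitudinalSummary:
    delta_scores: tuple[float, float, float]  # mean patient score change per pattern
    n_pairs: int
    retest_floor_mean: float  # mean over structures of mean |delta FA| in controls
    retest_floor_sd: float
    n_control_pairs: int


def fit_control_reference(table: pd.DataFrame, control_ids: Sequence[str]) -> ControlReference:
    """Sample mean and SD (ddof=1) of each structure over control baselines."""
    sub = table.xs("baseline", level="timepoint")
    controls = sub.loc[sub.index.intersection(control_ids)]
    if len(controls) < 2:
        raise SampleSizeError(f"control reference needs >= 2 controls, got {len(controls)}")
    mu = controls.mean()
    sigma = controls.std(ddof=1)
    zero = sigma[sigma == 0]
    if len(zero):
        raise DegenerateDesignError(
            f"zero control variance for structure {zero.index[0]!r}"
        )
    return ControlReference(mu=mu, sigma=sigma, n_controls=len(controls))


def pattern_scores(
    table: pd.DataFrame,
    ref: ControlReference,
    atlas: AtlasDefinition,
    threshold_offset: float = DEFAULT_THRESHOLD_OFFSET,
    scale: str = "shifted",
) -> list[PatternScores]:
    """Pattern-specific <FA> scores and affectation decisions per scan.

    z = (FA - mu) / sigma per structure; a pattern's score is the mean of
    its member-structure z values (shifted by +0.5 on the default scale).
    Missing structures are dropped from the mean as long as at least half
    of a pattern's members are present; "affected" is a strict comparison
    below the threshold.
    """
    if scale not in ("shifted", "raw_z"):
        raise ScoringError(f"unknown score scale {scale!r}")
    if list(table.columns) != list(ref.mu.index):
        raise ScoringError("structure table columns do not match the control reference")
    shift = 0.5 if scale == "shifted" else 0.0
    threshold = shift - threshold_offset

    members = {k: [s.name for s in atlas.structures if s.pattern == k] for k in (1, 2, 3)}
    z = (table - ref.mu) / ref.sigma

    results = []
    for (sid, tp), row in z.iterrows():
        scores = []
        affected = []
        for k in (1, 2, 3):
            vals = row[members[k]].dropna()
            if len(vals) < MIN_PATTERN_COVERAGE * len(members[k]):
                raise ScoringError(
                    f"scan ({sid}, {tp}): pattern {k} has only {len(vals)} of "
                    f"{len(members[k])} structures available"
                )
            if len(vals) < len(members[k]):
                logger.warning(
                    "scan (%s, %s): pattern %d mean uses %d of %d structures",
                    sid, tp, k, len(vals), len(members[k]),
                )
            score = float(vals.mean()) + shift
            scores.append(score)
            affected.append(score < threshold)
        results.append(
            PatternScores(
                subject_id=sid,
                timepoint=tp,
                scores=tuple(scores),
                affected=tuple(affected),
                scale=scale,
            )
        )
    return results


def categorize(scores: PatternScores) -> CategoryResult:
    """Map the three affectation bits to a categorization step.

    Pattern 1 affectation is required for any step; CS-alpha ignores
    pattern 3 entirely.
    """
    a1, a2, a3 = scores.affected
    if not a1:
        category = "uncategorized"
    elif not a2:
        category = "CSalpha"
    elif not a3:
        category = "CSbeta"
    else:
        category = "CSchi"
    return CategoryResult(scores.subject_id, scores.timepoint, category)


def nominal_specificity(threshold_offset: float = DEFAULT_THRESHOLD_OFFSET) -> float:
    """P(Z > -offset) for standard normal Z: the design specificity of the
    fixed threshold mu - offset*sigma on normally distributed controls."""
    if threshold_offset < 0:
        raise ScoringError("threshold offset must be non-negative")
    return float(stats.norm.sf(-threshold_offset))


def diagnostic_performance(
    scores: Sequence[PatternScores], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-pattern specificity and sensitivity of the affectation decision.

    Specificity: fraction of controls not affected; sensitivity: fraction
    of patients affected. Values are percentages.
    """
    controls = [s for s in scores if groups[s.subject_id] == "control"]
    patients = [s for s in scores if groups[s.subject_id] == "psp"]
    if not controls or not patients:
        raise SampleSizeError("diagnostic performance needs both controls and patients")
    rows = []
    for k in range(3):
        spec = 100.0 * sum(not s.affected[k] for s in controls) / len(controls)
        sens = 100.0 * sum(s.affected[k] for s in patients) / len(patients)
        rows.append({"pattern": k + 1, "specificity_pct": spec, "sensitivity_pct": sens})
    return pd.DataFrame(rows).set_index("pattern")


def categorization_summary(results: Sequence[CategoryResult]) -> dict:
    """Counts per categorization step and the percentage assigned to any CS."""
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    total = len(results)
    assigned = total - counts["uncategorized"]
    pct = 100.0 * assigned / total if total else 0.0
    return {**counts, "total": total, "categorized_pct": pct}


def psprs_group_summary(
    scores: Sequence[PatternScores],
    psprs_stage: Mapping[str, int],
    grouping: Sequence[frozenset[int] | set[int]] = ({1}, {2}, {3, 4}),
) -> pd.DataFrame:
    """Mean pattern scores within clinical severity (PSPRS stage) groups.

    The default grouping pools the two most severe stages ("3 + 4").
    Empty groups are logged and omitted.
    """
    rows = []
    for group in grouping:
        label = "+".join(str(s) for s in sorted(group))
        member = [
            s for s in scores
            if s.subject_id in psprs_stage and psprs_stage[s.subject_id] in group
        ]
        if not member:
            logger.warning("PSPRS group %s: no patients, row omitted", label)
            continue
        means = np.mean([s.scores for s in member], axis=0)
        rows.append(
            {
                "psprs_group": label,
                "n": len(member),
                "pattern1": float(means[0]),
                "pattern2": float(means[1]),
                "pattern3": float(means[2]),
            }
        )
    return pd.DataFrame(rows).set_index("psprs_group")


def longitudinal_summary(
    scores: Sequence[PatternScores],
    table: pd.DataFrame,
    control_ids: Sequence[str],
    patient_ids: Sequence[str],
) -> LongitudinalSummary:
    """Patient score progression and the control test-retest noise floor.

    Delta scores are mean baseline-to-follow-up pattern score changes over
    patients with both timepoints. The noise floor is computed from
    controls with two scans: per structure, the mean absolute FA
    difference between scans, summarized as mean +/- SD over structures.
    """
    by_key = {(s.subject_id, s.timepoint): s for s in scores}
    paired_patients = [
        sid for sid in patient_ids
        if (sid, "baseline") in by_key and (sid, "followup") in by_key
    ]
    if not paired_patients:
        raise SampleSizeError("no patients with paired baseline/follow-up scores")
    deltas = np.array(
        [
            np.subtract(by_key[(sid, "followup")].scores, by_key[(sid, "baseline")].scores)
            for sid in paired_patients
        ]
    )

    idx = table.index
    paired_controls = [
        sid for sid in control_ids
        if (sid, "baseline") in idx and (sid, "followup") in idx
    ]
    if paired_controls:
        base = table.loc[[(s, "baseline") for s in paired_controls]].to_numpy()
        follow = table.loc[[(s, "followup") for s in paired_controls]].to_numpy()
        per_structure = np.nanmean(np.abs(follow - base), axis=0)
        floor_mean = float(np.nanmean(per_structure))
        floor_sd = float(np.nanstd(per_structure, ddof=1))
    else:
        floor_mean = float("nan")
        floor_sd = float("nan")
    return LongitudinalSummary(
        delta_scores=tuple(float(d) for d in deltas.mean(axis=0)),
        n_pairs=len(paired_patients),
        retest_floor_mean=floor_mean,
        retest_floor_sd=floor_sd,
        n_control_pairs=len(paired_controls),
    )
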