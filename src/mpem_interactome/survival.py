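"""Prognostic gene screening by expression-stratified log-rank tests.

Each gene's cohort is split at the median expression value (ties go to
the low stratum), the two strata are compared with the standard two-group
log-rank test, and genes with p below a raw cutoff (default 0.001, with
no multiplicity adjustment — the screen emulates a published raw-cutoff
criterion) are called prognostic.  Direction is decided by comparing
restricted mean survival between strata: unfavourable when the
high-expression stratum survives shorter.

The log-rank statistic is chi2 = (sum_j (O_1j - E_1j))^2 / sum_j V_j over
distinct event times j, with the usual hypergeometric variance
V_j = d_j (n_1j / n_j)(1 - n_1j / n_j)(n_j - d_j)/(n_j - 1), referred to a
chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentResult, hypergeom_overlap
from .io import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SurvivalCohort", "PrognosticCall", "logrank", "prognostic_screen", "prognostic_set_enrichment"]


@dataclass
class SurvivalCohort:
    """Patient follow-up times, event indicators and per-gene expression."""

    time: np.ndarray  # months, > 0
    event: np.ndarray  # 1 = death, 0 = censored
    expression: pd.DataFrame  # patients x genes

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time <= 0):
            raise ValidationError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValidationError("event indicators must be 0/1")
        if len(self.time) != len(self.event) or len(self.time) != len(self.expression):
            raise ValidationError("time, event and expression lengths disagree")

    @property
    def n(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class PrognosticCall:
    gene: str
    chi2: float | None
    p: float | None
    direction: str  # {"favourable", "unfavourable", "none"}
    threshold: float


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    ``group`` is a boolean/0-1 label per observation.  With zero events
    the test is undefined and (0, 1) is returned with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValidationError("both groups must be non-empty")
    if events.sum() == 0:
        logger.warning("log-rank test with zero events; returning p = 1")
        return 0.0, 1.0

    event_times = np.unique(times[events == 1])
    # at-risk and event counts at each distinct event time
    n_j = (times[None, :] >= event_times[:, None]).sum(axis=1).astype(float)
    n1_j = (times[None, group] >= event_times[:, None]).sum(axis=1).astype(float)
    d_j = ((times[None, :] == event_times[:, None]) & (events[None, :] == 1)).sum(axis=1).astype(float)
    d1_j = ((times[None, group] == event_times[:, None]) & (events[None, group] == 1)).sum(axis=1).astype(float)

    e1_j = d_j * n1_j / n_j
    with np.errstate(invalid="ignore", divide="ignore"):
        v_j = d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    v_j = np.where(n_j > 1, v_j, 0.0)
    v = float(v_j.sum())
    if v == 0:
        return 0.0, 1.0
    chi2 = float((d1_j - e1_j).sum() ** 2 / v)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, max(p, np.nextafter(0, 1))


def km_restricted_mean(times, events, tau: float | None = None) -> float:
    """Area under the Kaplan-Meier curve up to ``tau`` (default: last time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if tau is None:
        tau = float(times.max())
    event_times = np.unique(times[events == 1])
    event_times = event_times[event_times <= tau]
    # stepwise KM estimate
    grid = np.concatenate([[0.0], event_times, [tau]])
    surv = 1.0
    area = 0.0
    prev_t = 0.0
    for t in event_times:
        area += surv * (t - prev_t)
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        surv *= 1.0 - d / n_at_risk
        prev_t = t
    area += surv * (tau - prev_t)
    return float(area)


def prognostic_screen(
    cohort: SurvivalCohort,
    genes=None,
    p_threshold: float = 0.001,
    split: str = "median",
) -> list[PrognosticCall]:
    """Screen genes for prognostic value by median-split log-rank tests."""
    if split != "median":
        raise ValidationError(f"unsupported split {split!r}")
    if cohort.n < 4:
        raise ValidationError("need at least 4 patients")
    genes = list(genes) if genes is not None else list(cohort.expression.columns)
    calls = []
    for gene in genes:
        expr = cohort.expression[gene].to_numpy(dtype=float)
        high = expr > np.median(expr)  # ties to the low stratum
        if high.sum() < 2 or (~high).sum() < 2:
            calls.append(PrognosticCall(gene, None, None, "none", p_threshold))
            continue
        chi2, p = logrank(cohort.time, cohort.event, high)
        if p < p_threshold:
            tau = float(cohort.time.max())
            rm_high = km_restricted_mean(cohort.time[high], cohort.event[high], tau)
            rm_low = km_restricted_mean(cohort.time[~high], cohort.event[~high], tau)
            direction = "unfavourable" if rm_high < rm_low else "favourable"
        else:
            direction = "none"
        calls.append(PrognosticCall(gene, chi2, p, direction, p_threshold))
    return calls


def prognostic_set_enrichment(
    interactome_nodes, prognostic_sets: GeneSetCollection, universe
) -> list[EnrichmentResult]:
    """Overlap of the interactome with per-cancer prognostic gene sets."""
    out = []
    for label, members in sorted(prognostic_sets.sets.items()):
        if not members:
            logger.warning("skipping empty prognostic set %r", label)
            continue
        out.append(hypergeom_overlap(interactome_nodes, members, universe, label=label))
    return out
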