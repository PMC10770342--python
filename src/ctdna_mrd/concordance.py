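"""Tumour–plasma concordance analytics.

Concordance is computed on post-filter somatic variants only: germline and
clonal-hematopoiesis variants are excluded upstream before the Venn
decomposition.  Per-participant variant sets pool (deduplicate) repeated
plasma timepoints before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

from .cohort_io import VariantCall, VariantKey
from .filtering import call_vaf


@dataclass(frozen=True)
class ConcordanceSummary:
    """Per-participant Venn decomposition of somatic variants.

    ``concordance_pct`` is 100 * shared / union, or None when the participant
    has no variant in either source (the no-detection flag).
    """

    participant_id: str
    n_tumour_only: int
    n_plasma_only: int
    n_shared: int

    @property
    def union_size(self) -> int:
        return self.n_tumour_only + self.n_plasma_only + self.n_shared

    @property
    def concordance_pct(self) -> float | None:
        if self.union_size == 0:
            return None
        return 100.0 * self.n_shared / self.union_size

    @property
    def no_detection(self) -> bool:
        return self.union_size == 0


def venn_counts(
    tumour_keys: set[VariantKey], plasma_keys: set[VariantKey]
) -> tuple[int, int, int]:
    """(n_tumour_only, n_plasma_only, n_shared) partitioning the union."""
    shared = tumour_keys & plasma_keys
    return len(tumour_keys - shared), len(plasma_keys - shared), len(shared)


def participant_concordance(
    participant_id: str,
    tumour_keys: set[VariantKey],
    plasma_keys: set[VariantKey],
) -> ConcordanceSummary:
    t, p, s = venn_counts(tumour_keys, plasma_keys)
    return ConcordanceSummary(participant_id, t, p, s)


@dataclass(frozen=True)
class CohortConcordance:
    n_participants: int
    n_with_any_variant: int
    n_with_both_sources: int
    n_full_concordance: int
    n_tumour_only: int
    n_plasma_only: int
    n_shared: int
    gene_tallies: Mapping[str, int]
    median_vaf_shared_tumour: float | None
    median_vaf_shared_plasma: float | None

    @property
    def union_size(self) -> int:
        return self.n_tumour_only + self.n_plasma_only + self.n_shared


def cohort_concordance_report(
    summaries: Sequence[ConcordanceSummary],
    tumour_calls: Iterable[VariantCall] = (),
    plasma_calls: Iterable[VariantCall] = (),
) -> CohortConcordance:
    """Aggregate per-participant summaries into cohort-level counts.

    ``n_with_both_sources`` counts participants with at least one variant in
    tumour AND at least one in plasma (shared or not);
    ``n_full_concordance`` counts participants whose detected variants are all
    shared.  When calls are supplied, per-gene tallies cover all surviving
    calls and the per-source median VAFs are computed over shared variants
    only (the source-matched pairs).
    """
    tumour_calls, plasma_calls = list(tumour_calls), list(plasma_calls)
    n_any = sum(1 for s in summaries if not s.no_detection)
    n_both = sum(1 for s in summaries
                 if (s.n_tumour_only + s.n_shared) > 0 and (s.n_plasma_only + s.n_shared) > 0)
    n_full = sum(1 for s in summaries
                 if not s.no_detection and s.concordance_pct == 100.0)

    genes: dict[str, int] = {}
    seen: set[tuple[str, str, VariantKey]] = set()
    for c in tumour_calls + plasma_calls:
        ident = (c.participant_id, c.source.value, c.key)
        if ident in seen:
            continue
        seen.add(ident)
        genes[c.gene] = genes.get(c.gene, 0) + 1

    tumour_by = {(c.participant_id, c.key): c for c in tumour_calls}
    plasma_by = {(c.participant_id, c.key): c for c in plasma_calls}
    shared_ids = sorted(set(tumour_by) & set(plasma_by), key=str)
    med_t = median(call_vaf(tumour_by[i]) for i in shared_ids) if shared_ids else None
    med_p = median(call_vaf(plasma_by[i]) for i in shared_ids) if shared_ids else None

    return CohortConcordance(
        n_participants=len(summaries),
        n_with_any_variant=n_any,
        n_with_both_sources=n_both,
        n_full_concordance=n_full,
        n_tumour_only=sum(s.n_tumour_only for s in summaries),
        n_plasma_only=sum(s.n_plasma_only for s in summaries),
        n_shared=sum(s.n_shared for s in summaries),
        gene_tallies=genes,
        median_vaf_shared_tumour=med_t,
        median_vaf_shared_plasma=med_p,
    )


def summaries_from_calls(
    tumour_calls: Iterable[VariantCall],
    plasma_calls: Iterable[VariantCall],
    participant_ids: Iterable[str] | None = None,
) -> list[ConcordanceSummary]:
    """Build per-participant summaries from flat somatic call lists.

    ``participant_ids`` fixes the participant universe (so participants with
    no detection still receive a summary); defaults to those seen in calls.
    """
    t_sets: dict[str, set[VariantKey]] = {}
    p_sets: dict[str, set[VariantKey]] = {}
    for c in tumour_calls:
        t_sets.setdefault(c.participant_id, set()).add(c.key)
    for c in plasma_calls:
        p_sets.setdefault(c.participant_id, set()).add(c.key)
    if participant_ids is None:
        pids = sorted(set(t_sets) | set(p_sets))
    else:
        pids = list(participant_ids)
    return [participant_concordance(pid, t_sets.get(pid, set()), p_sets.get(pid, set()))
            for pid in pids]
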