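"""Ordered variant-adjudication pipeline for plasma calls, with an audit ledger.

The pipeline turns raw plasma variant calls into a residual-disease variant
set through six ordered steps:

1. remove calls with random-forest probability score < 0.7 (missing scores are
   removed under the conservative default policy);
2. remove calls with VAF below 1% (these stay eligible for ddPCR add-back);
3. classify the origin of every score-passing plasma variant — including the
   low-VAF pool, which may return via add-back — against matched buffy coat /
   saliva / tumour calls, and drop germline and clonal-hematopoiesis variants
   from the somatic pool (they remain in ``origin_labels``);
4. remove calls outside the panel target regions;
5. adjudicate against ddPCR: orthogonally confirmed variants are added back
   (even from below the 1% gate), negative ones are excluded outright;
6. remove calls with VAF above 40% (likely germline) unless ddPCR-confirmed.

Every step appends a ledger entry (step name, n_in, n_removed, n_added,
removed keys) and the conservation identity
``n_in[k+1] == n_in[k] - n_removed[k] + n_added[k]`` holds on every run.

Origin classification is a pure function of source-presence patterns under
exact (chrom, pos, ref, alt) concordance: a plasma variant concordant with
buffy coat but not saliva is clonal hematopoiesis; concordant with saliva
(with or without buffy coat) is germline; present in neither matched normal
is somatic.  Without a saliva sample CH cannot be distinguished from
germline, so buffy-concordant variants are labelled germline and flagged
``ch_indeterminate``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .cohort_io import Source, TargetRegion, VariantCall, VariantKey
from .ddpcr import DdpcrCall
from .errors import ConfigError, DataError, UndefinedVafError


class Origin(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    CLONAL_HEMATOPOIESIS = "clonal_hematopoiesis"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class OriginLabel:
    key: VariantKey
    participant_id: str
    label: Origin
    evidence: frozenset[Source]
    ch_indeterminate: bool = False


@dataclass(frozen=True)
class LedgerStep:
    """Bookkeeping for one filter step."""

    name: str
    n_in: int
    n_removed: int
    n_added: int
    removed: tuple[VariantKey, ...] = ()
    added: tuple[VariantKey, ...] = ()

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed + self.n_added


@dataclass
class FilteredCallSet:
    """Surviving somatic plasma calls plus the complete audit trail."""

    surviving: list[VariantCall]
    ledger: list[LedgerStep]
    origin_labels: list[OriginLabel]
    fates: dict[tuple[str, VariantKey], str] = field(default_factory=dict)

    def check_conservation(self) -> None:
        """Assert the step-count identity; raises DataError on violation."""
        for prev, nxt in zip(self.ledger, self.ledger[1:]):
            if nxt.n_in != prev.n_out:
                raise DataError(
                    f"ledger broken between {prev.name!r} and {nxt.name!r}: "
                    f"{prev.n_in} - {prev.n_removed} + {prev.n_added} != {nxt.n_in}")
        if self.ledger and self.ledger[-1].n_out != len(self.surviving):
            raise DataError("final ledger count does not match surviving set")


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the adjudication pipeline.

    Defaults are the validated operating point: RF gate 0.7, VAF window
    [1%, 40%] with inclusive boundaries, missing RF scores removed.
    """

    rf_threshold: float = 0.7
    min_vaf: float = 1.0
    max_vaf: float = 40.0
    missing_rf: str = "remove"          # or "keep"
    ddpcr_min_droplets: int = 3
    ddpcr_min_ratio: float = 10.0

    def __post_init__(self):
        if self.min_vaf > self.max_vaf:
            raise ConfigError(f"min_vaf {self.min_vaf} > max_vaf {self.max_vaf}")
        if self.missing_rf not in ("remove", "keep"):
            raise ConfigError(f"missing_rf must be 'remove' or 'keep', got {self.missing_rf!r}")


def compute_vaf(ta: int, tr: int, to: int) -> float:
    """Variant allele frequency as a percentage: 100 * TA / (TA + TR + TO)."""
    total = ta + tr + to
    if total <= 0:
        raise UndefinedVafError("VAF undefined: ta + tr + to == 0")
    return 100.0 * ta / total


def call_vaf(call: VariantCall) -> float:
    return compute_vaf(call.ta, call.tr, call.to)


def filter_by_rf_score(
    calls: Sequence[VariantCall],
    threshold: float = 0.7,
    missing: str = "remove",
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (kept, removed) by the caller's RF probability score.

    Calls scoring exactly at the threshold are kept (removal is strictly
    below-threshold).  Missing scores follow ``missing`` policy.
    """
    kept, removed = [], []
    for c in calls:
        if c.rf_score is None:
            (kept if missing == "keep" else removed).append(c)
        elif c.rf_score >= threshold:
            kept.append(c)
        else:
            removed.append(c)
    return kept, removed


def filter_by_vaf_window(
    calls: Sequence[VariantCall],
    min_vaf: float = 1.0,
    max_vaf: float = 40.0,
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Split calls into (kept, removed_low, removed_high); boundaries inclusive."""
    if min_vaf > max_vaf:
        raise ConfigError(f"min_vaf {min_vaf} > max_vaf {max_vaf}")
    kept, low, high = [], [], []
    for c in calls:
        v = call_vaf(c)
        if v < min_vaf:
            low.append(c)
        elif v > max_vaf:
            high.append(c)
        else:
            kept.append(c)
    return kept, low, high


def _single_participant(groups: Mapping[str, Iterable[VariantCall]]) -> str | None:
    pids = {c.participant_id for calls in groups.values() for c in calls}
    if len(pids) > 1:
        raise DataError(f"calls from more than one participant: {sorted(pids)}")
    return pids.pop() if pids else None


def classify_origin(
    plasma_calls: Sequence[VariantCall],
    buffy_calls: Sequence[VariantCall] = (),
    saliva_calls: Sequence[VariantCall] | None = None,
    tumour_calls: Sequence[VariantCall] = (),
) -> list[OriginLabel]:
    """Label the origin of each plasma variant from its multi-source pattern.

    ``saliva_calls=None`` means no saliva sample was collected for this
    participant (distinct from a collected sample with no calls); in that case
    buffy-concordant variants are germline with ``ch_indeterminate=True``.
    All call lists must belong to one participant.
    """
    saliva_collected = saliva_calls is not None
    saliva = list(saliva_calls) if saliva_collected else []
    pid = _single_participant({
        "plasma": plasma_calls, "buffy": buffy_calls,
        "saliva": saliva, "tumour": tumour_calls,
    })
    buffy_keys = {c.key for c in buffy_calls}
    saliva_keys = {c.key for c in saliva}
    tumour_keys = {c.key for c in tumour_calls}

    labels = []
    seen = set()
    for c in plasma_calls:
        if c.key in seen:        # one label per distinct plasma variant
            continue
        seen.add(c.key)
        in_buffy, in_saliva = c.key in buffy_keys, c.key in saliva_keys
        evidence = {Source.PLASMA}
        if in_buffy:
            evidence.add(Source.BUFFY_COAT)
        if in_saliva:
            evidence.add(Source.SALIVA)
        if c.key in tumour_keys:
            evidence.add(Source.TUMOUR_FFPE)
        ch_flag = False
        if saliva_collected:
            if in_buffy and not in_saliva:
                label = Origin.CLONAL_HEMATOPOIESIS
            elif in_saliva:
                label = Origin.GERMLINE
            else:
                label = Origin.SOMATIC
        else:
            if in_buffy:
                label = Origin.GERMLINE
                ch_flag = True   # CH cannot be excluded without saliva
            else:
                label = Origin.SOMATIC
        labels.append(OriginLabel(c.key, pid or c.participant_id, label,
                                  frozenset(evidence), ch_flag))
    return labels


def build_region_index(regions: Sequence[TargetRegion]) -> dict[str, IntervalTree]:
    index: dict[str, IntervalTree] = {}
    for r in regions:
        index.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.gene)
    return index


def restrict_to_targets(
    calls: Sequence[VariantCall],
    regions: Sequence[TargetRegion],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (kept, removed) by overlap with panel target regions.

    Variant positions are 1-based and BED intervals 0-based half-open, so a
    call is on-target when ``pos - 1`` falls in some interval on the same
    (verbatim-compared) chromosome.
    """
    index = build_region_index(regions)
    kept, removed = [], []
    for c in calls:
        tree = index.get(c.chrom)
        if tree is not None and tree.overlaps_point(c.pos - 1):
            kept.append(c)
        else:
            removed.append(c)
    return kept, removed


def _ddpcr_verdicts(ddpcr_calls: Iterable[DdpcrCall]) -> dict[tuple[str, VariantKey], bool]:
    verdicts: dict[tuple[str, VariantKey], bool] = {}
    for d in ddpcr_calls:
        k = (d.participant_id, d.key)
        if k in verdicts and verdicts[k] != d.positive:
            raise DataError(f"conflicting duplicate ddPCR calls for {d.participant_id} {d.key}")
        verdicts[k] = d.positive
    return verdicts


def apply_ddpcr_adjudication(
    kept: Sequence[VariantCall],
    removed_low: Sequence[VariantCall],
    ddpcr_calls: Sequence[DdpcrCall],
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Override filter fates with orthogonal ddPCR evidence.

    Returns (final_kept, added_back, excluded): variants with a positive ddPCR
    call are retained — including ones removed at the low-VAF gate, which are
    added back — while variants with a negative call are excluded regardless
    of prior retention.  Variants without ddPCR evidence keep their fate.
    """
    verdicts = _ddpcr_verdicts(ddpcr_calls)
    final_kept, excluded = [], []
    for c in kept:
        verdict = verdicts.get((c.participant_id, c.key))
        (excluded if verdict is False else final_kept).append(c)
    added_back = [c for c in removed_low
                  if verdicts.get((c.participant_id, c.key)) is True]
    final_kept.extend(added_back)
    return final_kept, added_back, excluded


def run_filter_pipeline(
    plasma_calls: Sequence[VariantCall],
    buffy_calls: Sequence[VariantCall] = (),
    saliva_calls: Sequence[VariantCall] | None = None,
    tumour_calls: Sequence[VariantCall] = (),
    regions: Sequence[TargetRegion] = (),
    ddpcr_calls: Sequence[DdpcrCall] = (),
    config: FilterConfig | None = None,
) -> FilteredCallSet:
    """Run the six-step adjudication pipeline for one participant's calls.

    Deterministic for fixed inputs and config; the returned callset carries
    the surviving somatic plasma calls, the per-step ledger, origin labels for
    every plasma variant reaching the classification step, and a per-call fate
    map keyed by (participant, variant key).
    """
    cfg = config or FilterConfig()
    _single_participant({"plasma": plasma_calls, "buffy": buffy_calls,
                         "saliva": saliva_calls or [], "tumour": tumour_calls})
    ledger: list[LedgerStep] = []
    fates: dict[tuple[str, VariantKey], str] = {}

    def note(calls, fate):
        for c in calls:
            fates[(c.participant_id, c.key)] = fate

    # 1. RF probability-score gate
    current = list(plasma_calls)
    kept, removed = filter_by_rf_score(current, cfg.rf_threshold, cfg.missing_rf)
    ledger.append(LedgerStep("rf_score_gate", len(current), len(removed), 0,
                             tuple(c.key for c in removed)))
    note(removed, "removed:rf_score_gate")
    current = kept

    # 2. low-VAF gate (removed calls stay eligible for ddPCR add-back)
    kept, removed_low, _ = filter_by_vaf_window(current, cfg.min_vaf, float("inf"))
    ledger.append(LedgerStep("low_vaf_gate", len(current), len(removed_low), 0,
                             tuple(c.key for c in removed_low)))
    note(removed_low, "removed:low_vaf_gate")
    current = kept

    # 3. germline / clonal-hematopoiesis exclusion.  Labels cover the low-VAF
    # pool too: ddPCR confirms a variant's presence, not its somatic origin,
    # so germline/CH calls must stay excluded even if later add-back eligible.
    labels = classify_origin(list(current) + removed_low,
                             buffy_calls, saliva_calls, tumour_calls)
    somatic_keys = {l.key for l in labels if l.label is Origin.SOMATIC}
    removed = [c for c in current if c.key not in somatic_keys]
    kept = [c for c in current if c.key in somatic_keys]
    ledger.append(LedgerStep("germline_ch_exclusion", len(current), len(removed), 0,
                             tuple(c.key for c in removed)))
    note(removed, "removed:germline_ch_exclusion")
    current = kept

    # 4. on-target restriction
    kept, removed = restrict_to_targets(current, regions)
    ledger.append(LedgerStep("on_target_restriction", len(current), len(removed), 0,
                             tuple(c.key for c in removed)))
    note(removed, "removed:off_target")
    current = kept

    # 5. ddPCR adjudication: confirmed variants added back, refuted excluded
    addback_pool = [c for c in removed_low if c.key in somatic_keys]
    final_kept, added_back, excluded = apply_ddpcr_adjudication(
        current, addback_pool, ddpcr_calls)
    ledger.append(LedgerStep("ddpcr_adjudication", len(current), len(excluded),
                             len(added_back),
                             tuple(c.key for c in excluded),
                             tuple(c.key for c in added_back)))
    note(excluded, "removed:ddpcr_negative")
    note(added_back, "added_back:ddpcr_positive")
    current = final_kept

    # 6. high-VAF (likely germline) gate; ddPCR-confirmed calls are exempt
    verdicts = _ddpcr_verdicts(ddpcr_calls)
    kept, removed = [], []
    for c in current:
        confirmed = verdicts.get((c.participant_id, c.key)) is True
        if call_vaf(c) > cfg.max_vaf and not confirmed:
            removed.append(c)
        else:
            kept.append(c)
    ledger.append(LedgerStep("high_vaf_gate", len(current), len(removed), 0,
                             tuple(c.key for c in removed)))
    note(removed, "removed:high_vaf_gate")
    note(kept, "kept")
    for c in added_back:   # add-back survives unless > max and unconfirmed (impossible)
        fates[(c.participant_id, c.key)] = "added_back:ddpcr_positive"

    callset = FilteredCallSet(
        surviving=kept,
        ledger=ledger,
        origin_labels=labels,
        fates=fates,
    )
    callset.check_conservation()
    return callset


def run_cohort_pipeline(
    calls: Sequence[VariantCall],
    regions: Sequence[TargetRegion] = (),
    ddpcr_calls: Sequence[DdpcrCall] = (),
    config: FilterConfig | None = None,
    saliva_collected: set[str] | None = None,
) -> dict[str, FilteredCallSet]:
    """Group mixed-source calls by participant and adjudicate each.

    ``saliva_collected`` names the participants with a saliva sample;
    by default saliva is assumed collected only where saliva calls exist
    (a conservative inference — pass the set explicitly when known).
    """
    by_pid: dict[str, dict[Source, list[VariantCall]]] = {}
    for c in calls:
        by_pid.setdefault(c.participant_id, {}).setdefault(c.source, []).append(c)
    ddpcr_by_pid: dict[str, list[DdpcrCall]] = {}
    for d in ddpcr_calls:
        ddpcr_by_pid.setdefault(d.participant_id, []).append(d)
    out = {}
    for pid in sorted(by_pid):
        groups = by_pid[pid]
        has_saliva = (pid in saliva_collected if saliva_collected is not None
                      else Source.SALIVA in groups)
        out[pid] = run_filter_pipeline(
            groups.get(Source.PLASMA, []),
            groups.get(Source.BUFFY_COAT, []),
            groups.get(Source.SALIVA, []) if has_saliva else None,
            groups.get(Source.TUMOUR_FFPE, []),
            regions,
            ddpcr_by_pid.get(pid, []),
            config,
        )
    return out
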