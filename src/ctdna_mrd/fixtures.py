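"""Programmatic worked-example fixtures.

Small, fully deterministic cohorts whose category counts match the published
validation and concordance tallies of the assay this pipeline models.  They
are *constructed* to those printed totals — synthetic stand-ins for the
controlled-access study data — and exist so the real code paths (ddPCR
caller, filter pipeline, concordance, status assignment) can be exercised
end-to-end at desk scale:

* a 48-assay ddPCR validation set of which exactly 14 meet both positivity
  thresholds (boundary cases included) and 34 fail at least one;
* a 60-participant tumour/plasma concordance cohort with 72 somatic variants:
  36 tumour-only, 24 plasma-only, 12 shared; 41 participants with a variant
  in at least one source, 11 with both, 6 fully concordant;
* a 130-participant post-treatment cohort (64 NAT / 66 ADJ) in which the
  filter pipeline leaves 10 participants ctDNA-positive (7 NAT, 3 ADJ)
  carrying 13 variants across 6 genes;
* a 20-variant single-participant set exercising every filter step for
  ledger bookkeeping checks.
"""

from __future__ import annotations

from .cohort_io import (
    Arm, DdpcrAssay, Impact, NodeStatus, ParticipantRecord, Pcr, Source,
    TargetRegion, VariantCall, VariantKey,
)
from .synthetic import panel_regions

_GENE_ANCHORS = {r.gene: r for r in panel_regions()}


def _key(gene: str, offset: int, ref: str = "C", alt: str = "T") -> VariantKey:
    r = _GENE_ANCHORS[gene]
    return VariantKey(r.chrom, r.start + 1 + offset, ref, alt)   # 1-based, on-target


def _call(pid: str, source: Source, key: VariantKey, gene: str, vaf_pct: float,
          day: int = 40, rf: float | None = 0.95, depth: int = 10000,
          impact: Impact = Impact.MODERATE) -> VariantCall:
    ta = round(depth * vaf_pct / 100.0)
    return VariantCall(
        participant_id=pid, sample_id=f"{pid}-{source.value}-d{day}",
        source=source, collection_day=day,
        chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt, gene=gene,
        ta=ta, tr=depth - ta, to=0, rf_score=rf, impact=impact,
    )


# ---------------------------------------------------------------------------
# ddPCR validation fixture: 48 assays, 14 positive / 34 negative

def ddpcr_validation_assays() -> list[DdpcrAssay]:
    """48 ddPCR assays of which exactly 14 satisfy >=3 FAM-only droplets AND
    >=10x fluorescence ratio.  Positives sit in PIK3CA/TP53/KRAS (the genes
    in which confirmations clustered); negatives fail the droplet condition,
    the ratio condition, or both — boundary rows included."""
    rows: list[tuple[str, int, int, float]] = []
    # 14 true positives (participant, droplet count, ratio); first row is the
    # exact inclusive boundary (3 droplets, 10.0x).
    positives = [
        ("V01", "TP53", 3, 10.0), ("V02", "TP53", 5, 18.2), ("V03", "TP53", 9, 25.0),
        ("V04", "TP53", 14, 31.5), ("V05", "TP53", 22, 44.0),
        ("V06", "PIK3CA", 4, 12.7), ("V07", "PIK3CA", 7, 15.3),
        ("V08", "PIK3CA", 11, 28.9), ("V09", "PIK3CA", 35, 52.1),
        ("V10", "PIK3CA", 160, 88.0), ("V11", "KRAS", 3, 11.4),
        ("V12", "KRAS", 6, 19.8), ("V13", "KRAS", 48, 61.3), ("V14", "KRAS", 640, 97.5),
    ]
    # 20 failing the droplet condition (including 2 droplets at high ratio),
    # 10 failing the ratio condition (including 9.9x just under threshold),
    # 4 failing both.
    negatives = (
        [("N%02d" % i, g, d, r) for i, (g, d, r) in enumerate([
            ("TP53", 2, 50.0), ("TP53", 2, 12.5), ("TP53", 1, 30.0), ("TP53", 0, 0.0),
            ("EGFR", 2, 22.0), ("EGFR", 1, 14.8), ("EGFR", 0, 41.0), ("EGFR", 2, 11.1),
            ("ERBB2", 1, 18.0), ("ERBB2", 2, 33.3), ("GNAS", 0, 10.0), ("GNAS", 1, 25.6),
            ("KIT", 2, 19.0), ("KIT", 1, 44.2), ("BRAF", 2, 16.4), ("BRAF", 0, 12.0),
            ("AKT1", 1, 10.5), ("AKT1", 2, 28.7), ("TP53", 1, 15.2), ("PIK3CA", 2, 10.0),
        ], start=1)]
        + [("N%02d" % i, g, d, r) for i, (g, d, r) in enumerate([
            ("TP53", 5, 9.9), ("TP53", 8, 6.2), ("PIK3CA", 4, 3.0), ("PIK3CA", 12, 8.8),
            ("KRAS", 6, 1.4), ("KRAS", 3, 9.0), ("EGFR", 20, 5.5), ("ERBB2", 7, 7.7),
            ("GNAS", 15, 2.2), ("KIT", 4, 9.5),
        ], start=21)]
        + [("N%02d" % i, g, d, r) for i, (g, d, r) in enumerate([
            ("TP53", 0, 0.0), ("PIK3CA", 1, 4.1), ("EGFR", 2, 9.8), ("BRAF", 0, 2.5),
        ], start=31)]
    )
    assays = []
    for idx, (pid, gene, droplets, ratio) in enumerate(positives + negatives):
        assays.append(DdpcrAssay(
            key=_key(gene, offset=idx % 120, ref="G", alt="A"),
            participant_id=pid, fam_droplets=droplets,
            fluorescence_ratio=ratio, total_droplets=20000,
        ))
    return assays


# ---------------------------------------------------------------------------
# Tumour/plasma concordance fixture: 60 participants, 72 somatic variants

# (participant index, n shared, n tumour-only, n plasma-only); participants
# 1-6 are fully concordant, 1-11 have variants in both sources, 42-60 none.
_CONCORDANCE_MANIFEST = (
    [(1, 1, 0, 0), (2, 1, 0, 0), (3, 1, 0, 0), (4, 1, 0, 0), (5, 2, 0, 0), (6, 2, 0, 0),
     (7, 1, 2, 0), (8, 1, 0, 1), (9, 1, 1, 1), (10, 1, 0, 2), (11, 0, 2, 1)]
    + [(i, 0, 2, 0) for i in range(12, 26)]    # 14 participants, 28 tumour-only
    + [(i, 0, 1, 0) for i in range(26, 29)]    # 3 participants, 3 tumour-only
    + [(i, 0, 0, 2) for i in range(29, 35)]    # 6 participants, 12 plasma-only
    + [(i, 0, 0, 1) for i in range(35, 42)]    # 7 participants, 7 plasma-only
)

_SHARED_GENES = ["TP53"] * 9 + ["PIK3CA", "KRAS", "PIK3CA"]
_OTHER_GENES = ["TP53", "PIK3CA", "EGFR", "KRAS", "ERBB2", "AKT1", "BRAF"]


def concordance_cohort() -> tuple[list[VariantCall], list[VariantCall], list[str]]:
    """(tumour_calls, plasma_calls, participant_ids) for the 60-participant
    concordance worked example.  Shared variants carry a high tumour VAF and a
    low plasma VAF (the study-reported ordering); all calls are post-filter
    somatic."""
    tumour, plasma = [], []
    pids = [f"C{i:03d}" for i in range(1, 61)]
    shared_i = other_i = 0
    tumour_vafs = [25.0, 28.5, 30.9, 32.9, 34.0, 36.6, 38.1, 40.0, 27.2, 31.4, 33.3, 35.8]
    plasma_vafs = [1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 1.1, 1.3, 1.5, 1.7, 1.9, 2.4]
    for idx, n_shared, n_tum, n_pla in _CONCORDANCE_MANIFEST:
        pid = f"C{idx:03d}"
        for _ in range(n_shared):
            gene = _SHARED_GENES[shared_i]
            key = _key(gene, offset=shared_i, ref="G", alt="T")
            tumour.append(_call(pid, Source.TUMOUR_FFPE, key, gene,
                                tumour_vafs[shared_i], day=-30))
            plasma.append(_call(pid, Source.PLASMA, key, gene, plasma_vafs[shared_i]))
            shared_i += 1
        for _ in range(n_tum):
            gene = _OTHER_GENES[other_i % len(_OTHER_GENES)]
            key = _key(gene, offset=20 + other_i, ref="A", alt="C")
            tumour.append(_call(pid, Source.TUMOUR_FFPE, key, gene, 22.0, day=-30))
            other_i += 1
        for _ in range(n_pla):
            gene = _OTHER_GENES[other_i % len(_OTHER_GENES)]
            key = _key(gene, offset=20 + other_i, ref="A", alt="G")
            plasma.append(_call(pid, Source.PLASMA, key, gene, 2.5))
            other_i += 1
    return tumour, plasma, pids


# ---------------------------------------------------------------------------
# Post-treatment status fixture: 130 participants, 10 ctDNA-positive

# positive participants -> list of (gene, vaf%, impact, needs_ddpcr_addback)
_POSITIVE_VARIANTS = {
    "NAT001": [("TP53", 12.4, Impact.HIGH, False), ("TP53", 2.9, Impact.MODERATE, False)],
    "NAT002": [("TP53", 10.8, Impact.HIGH, False), ("TP53", 2.6, Impact.MODERATE, False)],
    "NAT003": [("TP53", 2.8, Impact.MODERATE, False)],
    "NAT025": [("TP53", 1.9, Impact.MODERATE, False)],
    "NAT026": [("EGFR", 1.4, Impact.MODERATE, False)],
    "NAT027": [("EGFR", 1.2, Impact.MODERATE, False)],
    "NAT028": [("EGFR", 1.6, Impact.MODERATE, False)],
    "ADJ001": [("ERBB2", 1.0, Impact.MODERATE, False)],
    "ADJ002": [("GNAS", 2.1, Impact.MODERATE, False)],
    "ADJ003": [("KIT", 1.3, Impact.MODERATE, False), ("PIK3CA", 0.6, Impact.MODERATE, True)],
}


def post_treatment_cohort():
    """The 130-participant worked example for status assignment.

    Returns (plasma_calls_by_pid, ddpcr_assays, clinical_records,
    sample_days_by_pid, regions).  Every participant has one post-treatment
    plasma draw at day 40; ten participants (7 NAT — 3 with pCR, 4 without —
    and 3 ADJ) carry 13 true variants in 6 genes, one of which (PIK3CA at
    0.6% VAF) sits below the 1% gate and is rescued by a confirming ddPCR
    assay, exercising the add-back path.
    """
    pids = [f"NAT{i:03d}" for i in range(1, 65)] + [f"ADJ{i:03d}" for i in range(1, 67)]
    plasma: dict[str, list[VariantCall]] = {pid: [] for pid in pids}
    assays: list[DdpcrAssay] = []
    offset = 0
    for pid, variants in _POSITIVE_VARIANTS.items():
        for gene, vaf, impact, addback in variants:
            key = _key(gene, offset=offset % 140, ref="C", alt="A")
            offset += 1
            plasma[pid].append(_call(pid, Source.PLASMA, key, gene, vaf, impact=impact))
            if addback:
                assays.append(DdpcrAssay(key=key, participant_id=pid,
                                         fam_droplets=6, fluorescence_ratio=24.0,
                                         total_droplets=20000))
    records = []
    for pid in pids:
        nat = pid.startswith("NAT")
        idx = int(pid[3:])
        pcr = (Pcr.YES if idx <= 24 else Pcr.NO) if nat else Pcr.NOT_APPLICABLE
        positive = pid in _POSITIVE_VARIANTS
        event = positive and pid in ("NAT001", "NAT002", "NAT025", "ADJ002")
        records.append(ParticipantRecord(
            participant_id=pid, arm=Arm.NAT if nat else Arm.ADJ, pcr=pcr,
            age_group="50-59", tumour_stage="T2",
            node_status=NodeStatus.POSITIVE if nat and idx % 2 == 0 else NodeStatus.NEGATIVE,
            capecitabine=bool(nat and pcr is Pcr.NO and idx <= 37),
            followup_day=750, event=event, event_day=200 if event else None,
        ))
    sample_days = {pid: [40] for pid in pids}
    return plasma, assays, records, sample_days, panel_regions()


# ---------------------------------------------------------------------------
# 20-variant filter-ledger fixture (single participant)

def filter_ledger_fixture():
    """One participant's 20 plasma calls spanning every filter step.

    Returns (plasma, buffy, saliva, tumour, regions, ddpcr_assays).  Expected
    fates: 3 removed at the RF gate, 3 at the low-VAF gate (one of which is
    ddPCR-confirmed and added back), 2 at germline/CH exclusion, 2 off-target,
    2 excluded on negative ddPCR, 1 at the high-VAF gate (a second high-VAF
    call is ddPCR-confirmed and exempt) — leaving 8 survivors.
    """
    pid = "L001"
    plasma, buffy, saliva, assays = [], [], [], []

    def add(gene, off, vaf, rf=0.95, ref="C", alt="T", off_target=False):
        if off_target:
            r = _GENE_ANCHORS[gene]
            key = VariantKey(r.chrom, r.end + 5000, ref, alt)
        else:
            key = _key(gene, offset=off, ref=ref, alt=alt)
        call = _call(pid, Source.PLASMA, key, gene, vaf, rf=rf)
        plasma.append(call)
        return key

    def assay(key, positive):
        assays.append(DdpcrAssay(
            key=key, participant_id=pid,
            fam_droplets=8 if positive else 1,
            fluorescence_ratio=30.0 if positive else 4.0,
            total_droplets=20000))

    # survive all gates (6 clean somatic calls)
    for i, (gene, vaf) in enumerate([("TP53", 2.0), ("TP53", 12.0), ("PIK3CA", 3.5),
                                     ("KRAS", 1.0), ("EGFR", 5.0), ("ERBB2", 40.0)]):
        add(gene, i, vaf)
    # removed at RF gate: two low scores and one missing score
    add("TP53", 10, 2.0, rf=0.69)
    add("KIT", 10, 3.0, rf=0.10)
    add("GNAS", 10, 2.0, rf=None)
    # removed at low-VAF gate; the PIK3CA call is ddPCR-confirmed -> added back
    k = add("PIK3CA", 12, 0.5)
    assay(k, True)
    add("BRAF", 12, 0.7)
    add("AKT1", 12, 0.9)
    # germline (buffy + saliva) and clonal hematopoiesis (buffy only)
    k = add("EGFR", 14, 48.0, ref="G", alt="A")
    buffy.append(_call(pid, Source.BUFFY_COAT, k, "EGFR", 50.0))
    saliva.append(_call(pid, Source.SALIVA, k, "EGFR", 49.0, day=-30))
    k = add("TP53", 15, 1.1, ref="G", alt="C")
    buffy.append(_call(pid, Source.BUFFY_COAT, k, "TP53", 1.2))
    # off-target calls
    add("TP53", 0, 2.0, ref="A", alt="G", off_target=True)
    add("KRAS", 0, 3.0, ref="A", alt="G", off_target=True)
    # ddPCR-negative calls excluded at adjudication
    k = add("GNAS", 16, 2.0, ref="T", alt="A")
    assay(k, False)
    k = add("KIT", 16, 19.4, ref="T", alt="A")
    assay(k, False)
    # high-VAF pair: one removed, one ddPCR-confirmed and exempt
    add("MET", 17, 45.0)
    k = add("NOTCH1", 17, 78.4)
    assay(k, True)

    assert len(plasma) == 20
    return plasma, buffy, saliva, [], panel_regions(), assays
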