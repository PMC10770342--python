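"""Synthetic cohort generator emulating the pipeline's inputs.

Generates fully-labelled cohorts — variant call tables for plasma, buffy coat,
saliva and FFPE tumour, a ddPCR results table, a clinical table and
ground-truth records — so that every pipeline stage is testable without access
to controlled sequencing data.

The generative model, per participant: Poisson numbers of somatic, germline,
clonal-hematopoiesis (CH) and artifact variants; each variant placed in a toy
38-region hotspot panel (artifacts optionally jittered off-target); true VAFs
drawn per origin (log-normal for somatic/CH/artifact on the percent scale,
near-50% normal for germline); read counts drawn binomially from the true VAF
at Poisson-distributed depth (mean 7500x — a simple approximation of the
amplicon assay without UMI or error-model simulation); random-forest caller
scores drawn from Beta distributions, high for true variants and low for
artifacts.  Source presence follows the origin: germline variants appear in
plasma, buffy coat, saliva and tumour; CH in plasma and buffy coat but not
saliva; somatic in plasma and/or tumour only; artifacts in plasma only.
ddPCR assays are generated for low-VAF plasma calls (and a fraction of
high-VAF ones) with a logistic detection-probability curve in true VAF for
real variants; artifacts never confirm.  Survival times are exponential with
the hazard multiplied by the configured true hazard ratio for
ctDNA-positive participants, under independent exponential censoring plus an
administrative follow-up cap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_io import (
    Arm, DdpcrAssay, Impact, NodeStatus, ParticipantRecord, Pcr, Source,
    TargetRegion, VariantCall, VariantKey, write_clinical_table,
    write_ddpcr_table, write_target_bed, write_variant_table,
)
from .errors import ConfigError

_BASES = ("A", "C", "G", "T")

# Toy hotspot panel: 38 windows named for recurrently-mutated cancer genes.
# Coordinates are merely plausible anchors; only the interval logic matters.
_PANEL = [
    ("TP53", "chr17", 7577000), ("PIK3CA", "chr3", 178936000),
    ("KRAS", "chr12", 25398200), ("EGFR", "chr7", 55259400),
    ("ERBB2", "chr17", 37880900), ("GNAS", "chr20", 57484400),
    ("KIT", "chr4", 55599300), ("POLE", "chr12", 133250200),
    ("MAP2K1", "chr15", 66727400), ("MAP2K2", "chr19", 4117500),
    ("NRAS", "chr1", 115256500), ("HRAS", "chr11", 534200),
    ("BRAF", "chr7", 140453100), ("AKT1", "chr14", 105246500),
    ("ALK", "chr2", 29443600), ("APC", "chr5", 112175200),
    ("ATM", "chr11", 108117800), ("CDH1", "chr16", 68847200),
    ("CDKN2A", "chr9", 21971100), ("CTNNB1", "chr3", 41266100),
    ("ESR1", "chr6", 152419900), ("FBXW7", "chr4", 153249300),
    ("FOXL2", "chr3", 138664400), ("GNA11", "chr19", 3118900),
    ("GNAQ", "chr9", 80409400), ("IDH1", "chr2", 209113100),
    ("IDH2", "chr15", 90631800), ("MET", "chr7", 116411900),
    ("MLH1", "chr3", 37067200), ("NOTCH1", "chr9", 139399400),
    ("PDGFRA", "chr4", 55152000), ("PTPN11", "chr12", 112926800),
    ("RAF1", "chr3", 12645600), ("RET", "chr10", 43617400),
    ("ROS1", "chr6", 117645500), ("SMAD4", "chr18", 48591800),
    ("SMO", "chr7", 128846300), ("VHL", "chr3", 10183700),
]
_REGION_WIDTH = 150


def panel_regions() -> list[TargetRegion]:
    """The packaged toy hotspot panel: 38 regions, one per gene."""
    return [TargetRegion(chrom, start, start + _REGION_WIDTH, gene)
            for gene, chrom, start in _PANEL]


class TrueLabel(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"
    CLONAL_HEMATOPOIESIS = "clonal_hematopoiesis"
    ARTIFACT = "artifact"


@dataclass(frozen=True)
class TruthRecord:
    key: VariantKey
    participant_id: str
    true_label: TrueLabel
    true_vaf: float
    sources: tuple[Source, ...] = ()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-conditions knobs of the generator.

    Defaults mirror the emulated study: a 130-participant cohort split 64/66
    between neoadjuvant (NAT) and adjuvant (ADJ) arms, pCR in 24/64 NAT
    participants, tumour + saliva sequenced for a 60-participant subset, mean
    depth 7500x, post-treatment plasma drawn a median ~55 days (1.8 months)
    after treatment completion, per-participant Poisson rates tuned to the
    observed detection burden (P(any somatic plasma variant) ~= 7.7%, ~0.26
    artifact calls and ~0.05 germline calls per participant), a somatic
    tumour/plasma source split of 12:36:24 (both : tumour-only : plasma-only)
    and a true ctDNA-positive hazard ratio of 14.61 on an exponential baseline.
    """

    n_participants: int = 130
    nat_fraction: float = 64 / 130
    pcr_rate: float = 24 / 64
    tumour_saliva_fraction: float = 60 / 130
    somatic_rate: float = 0.08            # Poisson mean per participant
    germline_rate: float = 0.05
    ch_rate: float = 0.02
    artifact_rate: float = 0.26
    artifact_offtarget_frac: float = 0.3
    somatic_source_probs: tuple[float, float, float] = (12 / 72, 36 / 72, 24 / 72)
    rf_true_beta: tuple[float, float] = (8.0, 2.0)
    rf_artifact_beta: tuple[float, float] = (2.0, 8.0)
    rf_true_range: tuple[float, float] = (0.0, 1.0)      # clip window
    rf_artifact_range: tuple[float, float] = (0.0, 1.0)
    somatic_vaf_lognorm: tuple[float, float] = (0.7, 1.0)   # ln(%) mean, sd
    somatic_vaf_range: tuple[float, float] = (0.1, 78.4)
    tumour_vaf_lognorm: tuple[float, float] = (3.3, 0.6)
    ch_vaf_lognorm: tuple[float, float] = (0.0, 0.5)
    germline_vaf_normal: tuple[float, float] = (50.0, 5.0)
    artifact_vaf_lognorm: tuple[float, float] = (-0.36, 1.0)
    artifact_vaf_range: tuple[float, float] = (0.1, 19.4)
    depth_mean: float = 7500.0
    other_allele_rate: float = 5e-4       # per-read chance of a third allele
    collection_day_mean: float = 55.0
    collection_day_sd: float = 30.0
    window_days: int = 213
    multi_timepoint: bool = False
    ddpcr_low_vaf_window: tuple[float, float] = (0.5, 1.5)
    ddpcr_high_vaf_prob: float = 0.2
    ddpcr_v50: float = 0.3                # VAF% at 50% detection probability
    ddpcr_slope: float = 2.0              # logistic slope on log10 VAF
    ddpcr_total_droplets: int = 20000
    baseline_hazard: float = 2.1e-4       # events per day, ctDNA-negative
    true_hr: float = 14.61
    censoring_rate: float = 0.85
    max_followup_day: int = 1600
    seed: int | None = None

    def __post_init__(self):
        for name in ("nat_fraction", "pcr_rate", "tumour_saliva_fraction",
                     "artifact_offtarget_frac", "ddpcr_high_vaf_prob",
                     "censoring_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("somatic_rate", "germline_rate", "ch_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.true_hr <= 0:
            raise ConfigError("true_hr must be > 0")
        if abs(sum(self.somatic_source_probs) - 1.0) > 1e-9:
            raise ConfigError("somatic_source_probs must sum to 1")
        for name in ("rf_true_beta", "rf_artifact_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} parameters must be > 0")


def separable_config(n_participants: int = 200, seed: int | None = None) -> GeneratorConfig:
    """A noise-free operating point where truth recovery must be exact:
    caller scores fully separated around 0.7, somatic VAFs inside the
    [1, 40]% window with margin, and a perfectly sensitive ddPCR."""
    return GeneratorConfig(
        n_participants=n_participants,
        somatic_rate=1.0,
        ch_rate=0.2,
        germline_rate=0.3,
        artifact_rate=1.0,
        rf_true_range=(0.75, 1.0),
        rf_artifact_range=(0.0, 0.65),
        somatic_vaf_range=(3.0, 35.0),
        ddpcr_v50=1e-6,
        ddpcr_slope=50.0,
        seed=seed,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort: calls for all sources, assays, clinical, truth."""

    calls: list[VariantCall]
    ddpcr_assays: list[DdpcrAssay]
    clinical: list[ParticipantRecord]
    truth: list[TruthRecord]
    regions: list[TargetRegion]
    config: GeneratorConfig
    tissue_participants: frozenset[str] = frozenset()  # saliva+tumour collected

    def calls_for(self, participant_id: str, source: Source) -> list[VariantCall]:
        return [c for c in self.calls
                if c.participant_id == participant_id and c.source == source]

    def sample_days(self, participant_id: str) -> list[int]:
        """Collection days of the participant's plasma samples (with or
        without calls) — one post-treatment draw per participant by default."""
        return self._sample_days[participant_id]

    _sample_days: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.calls, outdir / "variants.tsv")
        write_ddpcr_table(self.ddpcr_assays, outdir / "ddpcr.csv")
        write_clinical_table(self.clinical, outdir / "clinical.csv")
        write_target_bed(self.regions, outdir / "targets.bed")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("participant_id\tchrom\tpos\tref\talt\ttrue_label\ttrue_vaf\tsources\n")
            for t in self.truth:
                srcs = ",".join(s.value for s in t.sources)
                fh.write(f"{t.participant_id}\t{t.key.chrom}\t{t.key.pos}\t{t.key.ref}\t"
                         f"{t.key.alt}\t{t.true_label.value}\t{t.true_vaf!r}\t{srcs}\n")


def _lognormal_vaf(rng, mu_sigma, lo_hi):
    mu, sigma = mu_sigma
    lo, hi = lo_hi
    return float(np.clip(np.exp(rng.normal(mu, sigma)), lo, hi))


def _draw_key(rng, regions, used: set, off_target: bool) -> tuple[VariantKey, str]:
    for _ in range(100):
        r = regions[rng.integers(len(regions))]
        if off_target:
            pos = r.end + int(rng.integers(500, 5000)) + 1
        else:
            pos = int(rng.integers(r.start, r.end)) + 1   # 1-based inside [start, end)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        key = VariantKey(r.chrom, pos, str(ref), str(alt))
        if key not in used:
            used.add(key)
            return key, r.gene
    raise RuntimeError("could not draw a fresh variant key")  # pragma: no cover


def _read_counts(rng, cfg, true_vaf):
    depth = max(int(rng.poisson(cfg.depth_mean)), 10)
    ta = int(rng.binomial(depth, true_vaf / 100.0))
    to = int(rng.binomial(depth - ta, cfg.other_allele_rate)) if depth > ta else 0
    return ta, depth - ta - to, to


def _rf_score(rng, beta, clip):
    return float(np.clip(rng.beta(*beta), *clip))


_IMPACTS = [Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER]


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a labelled cohort; reproducible for a fixed seed.

    ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    regions = panel_regions()
    n = cfg.n_participants
    n_nat = int(round(n * cfg.nat_fraction))
    subset = set(rng.choice(n, int(round(n * cfg.tumour_saliva_fraction)),
                            replace=False).tolist())

    calls: list[VariantCall] = []
    assays: list[DdpcrAssay] = []
    truth: list[TruthRecord] = []
    records: list[ParticipantRecord] = []
    sample_days: dict[str, list[int]] = {}
    truly_positive: list[bool] = []

    for i in range(n):
        pid = f"P{i + 1:04d}"
        arm = Arm.NAT if i < n_nat else Arm.ADJ
        has_tissue = i in subset
        day = int(np.clip(round(rng.normal(cfg.collection_day_mean,
                                           cfg.collection_day_sd)), 0, cfg.window_days))
        plasma_days = [day]
        if cfg.multi_timepoint:
            plasma_days = [-60, day, 400]
        sample_days[pid] = plasma_days
        used: set[VariantKey] = set()

        n_by_label = {
            TrueLabel.SOMATIC: rng.poisson(cfg.somatic_rate),
            TrueLabel.GERMLINE: rng.poisson(cfg.germline_rate),
            TrueLabel.CLONAL_HEMATOPOIESIS: rng.poisson(cfg.ch_rate),
            TrueLabel.ARTIFACT: rng.poisson(cfg.artifact_rate),
        }
        plasma_somatic = False
        for label, count in n_by_label.items():
            for _ in range(count):
                off_target = (label is TrueLabel.ARTIFACT
                              and rng.random() < cfg.artifact_offtarget_frac)
                key, gene = _draw_key(rng, regions, used, off_target)

                if label is TrueLabel.SOMATIC:
                    vaf = _lognormal_vaf(rng, cfg.somatic_vaf_lognorm, cfg.somatic_vaf_range)
                    pattern = rng.choice(3, p=cfg.somatic_source_probs)
                    sources = {0: [Source.PLASMA, Source.TUMOUR_FFPE],
                               1: [Source.TUMOUR_FFPE],
                               2: [Source.PLASMA]}[int(pattern)]
                elif label is TrueLabel.GERMLINE:
                    vaf = float(np.clip(rng.normal(*cfg.germline_vaf_normal), 1.0, 99.0))
                    sources = [Source.PLASMA, Source.BUFFY_COAT,
                               Source.SALIVA, Source.TUMOUR_FFPE]
                elif label is TrueLabel.CLONAL_HEMATOPOIESIS:
                    vaf = _lognormal_vaf(rng, cfg.ch_vaf_lognorm, (0.05, 30.0))
                    sources = [Source.PLASMA, Source.BUFFY_COAT]
                else:
                    vaf = _lognormal_vaf(rng, cfg.artifact_vaf_lognorm, cfg.artifact_vaf_range)
                    sources = [Source.PLASMA]
                if not has_tissue:
                    sources = [s for s in sources
                               if s not in (Source.SALIVA, Source.TUMOUR_FFPE)]
                rf_beta, rf_clip = ((cfg.rf_artifact_beta, cfg.rf_artifact_range)
                                    if label is TrueLabel.ARTIFACT
                                    else (cfg.rf_true_beta, cfg.rf_true_range))
                impact = _IMPACTS[int(rng.choice(4, p=(0.08, 0.52, 0.15, 0.25)))]

                for src in sources:
                    src_vaf = vaf
                    if src is Source.TUMOUR_FFPE and label is TrueLabel.SOMATIC:
                        src_vaf = _lognormal_vaf(rng, cfg.tumour_vaf_lognorm, (1.0, 95.0))
                    src_day = day if src in (Source.PLASMA, Source.BUFFY_COAT) else -30
                    ta, tr, to = _read_counts(rng, cfg, src_vaf)
                    if ta == 0:
                        continue    # below the assay's floor: no call emitted
                    calls.append(VariantCall(
                        participant_id=pid,
                        sample_id=f"{pid}-{src.value}-d{src_day}",
                        source=src, collection_day=src_day,
                        chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                        gene=gene, ta=ta, tr=tr, to=to,
                        rf_score=_rf_score(rng, rf_beta, rf_clip),
                        impact=impact,
                    ))
                    if src is Source.PLASMA:
                        if label is TrueLabel.SOMATIC and 0 <= day <= cfg.window_days:
                            plasma_somatic = True
                        obs_vaf = 100.0 * ta / (ta + tr + to)
                        lo, hi = cfg.ddpcr_low_vaf_window
                        if (lo <= obs_vaf <= hi) or (obs_vaf > hi and
                                                     rng.random() < cfg.ddpcr_high_vaf_prob):
                            assays.append(_make_assay(rng, cfg, pid, key, label, vaf))
                truth.append(TruthRecord(key, pid, label, vaf,
                                         tuple(s for s in sources)))
        truly_positive.append(plasma_somatic)

    followup, event = generate_survival(truly_positive, cfg, rng)
    for i in range(n):
        pid = f"P{i + 1:04d}"
        arm = Arm.NAT if i < n_nat else Arm.ADJ
        if arm is Arm.NAT:
            pcr = Pcr.YES if rng.random() < cfg.pcr_rate else Pcr.NO
        else:
            pcr = Pcr.NOT_APPLICABLE
        stage_p = (0.12, 0.50, 0.30, 0.08) if arm is Arm.NAT else (0.42, 0.50, 0.07, 0.01)
        node_p = 0.55 if arm is Arm.NAT else 0.27
        cape = bool(arm is Arm.NAT and pcr is Pcr.NO and rng.random() < 13 / 40)
        records.append(ParticipantRecord(
            participant_id=pid, arm=arm, pcr=pcr,
            age_group=str(rng.choice(["<40", "40-49", "50-59", "60-69", "70+"],
                                     p=(0.10, 0.25, 0.30, 0.25, 0.10))),
            tumour_stage=str(rng.choice(["T1", "T2", "T3", "T4"], p=stage_p)),
            node_status=NodeStatus.POSITIVE if rng.random() < node_p else NodeStatus.NEGATIVE,
            capecitabine=cape,
            followup_day=int(followup[i]), event=bool(event[i]),
            event_day=int(followup[i]) if event[i] else None,
        ))

    cohort = SyntheticCohort(
        calls=calls, ddpcr_assays=assays, clinical=records, truth=truth,
        regions=regions, config=cfg,
        tissue_participants=frozenset(f"P{i + 1:04d}" for i in subset))
    cohort._sample_days = sample_days
    return cohort


def _make_assay(rng, cfg, pid, key, label, true_vaf) -> DdpcrAssay:
    if label is TrueLabel.ARTIFACT:
        detected = False
    else:
        x = np.log10(max(true_vaf, 1e-9)) - np.log10(cfg.ddpcr_v50)
        detected = rng.random() < 1.0 / (1.0 + np.exp(-cfg.ddpcr_slope * x))
    if detected:
        fam = 3 + int(rng.poisson(max(true_vaf, 0.0) * 2.0))
        ratio = 10.0 + float(rng.exponential(30.0))
    elif rng.random() < 0.7:
        fam = int(rng.integers(0, 3))            # too few droplets
        ratio = float(rng.uniform(0.0, 60.0))
    else:
        fam = int(rng.integers(3, 8))            # droplets but weak signal
        ratio = float(rng.uniform(0.0, 10.0 - 1e-9))
    return DdpcrAssay(key=key, participant_id=pid, fam_droplets=fam,
                      fluorescence_ratio=ratio,
                      total_droplets=cfg.ddpcr_total_droplets)


def generate_survival(positive: Sequence[bool],
                      config: GeneratorConfig | None = None,
                      rng: np.random.Generator | None = None):
    """Exponential event times with hazard scaled by the true HR for
    ctDNA-positive participants, under independent exponential censoring and
    an administrative cap.  Returns (followup_day, event) arrays.

    A censoring rate of 1 yields zero events (everyone censored at day 0).
    """
    cfg = config or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    positive = np.asarray(positive, dtype=bool)
    n = positive.size
    if cfg.censoring_rate >= 1.0:
        return np.zeros(n, dtype=int), np.zeros(n, dtype=bool)
    hazard = cfg.baseline_hazard * np.where(positive, cfg.true_hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0.0:
        c_hazard = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        t_censor = rng.exponential(1.0 / c_hazard, size=n)
    else:
        t_censor = np.full(n, np.inf)
    t_censor = np.minimum(t_censor, cfg.max_followup_day)
    event = t_event <= t_censor
    followup = np.ceil(np.minimum(t_event, t_censor)).astype(int)
    return followup, event
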