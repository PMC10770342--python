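"""Deterministic droplet-digital-PCR positivity calling.

An assay is called positive when it shows at least ``min_droplets`` FAM-positive-
only droplets AND a mutant-channel fluorescence signal at least ``min_ratio``
times the matched wild-type-only control.  Both thresholds are inclusive by
default (the literal reading of "at least 3" / "10-times higher"); a strict
mode (>) is available for either.  ddPCR is used here purely as a binary
confirmation — no Poisson concentration estimation from droplet counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .cohort_io import DdpcrAssay, VariantKey

DEFAULT_MIN_DROPLETS = 3
DEFAULT_MIN_RATIO = 10.0


@dataclass(frozen=True)
class DdpcrCall:
    """Positivity decision for one assay, with the failing condition(s) recorded."""

    key: VariantKey
    participant_id: str
    positive: bool
    reason: str


def call_ddpcr_positive(
    assay: DdpcrAssay,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    min_ratio: float = DEFAULT_MIN_RATIO,
    strict: bool = False,
) -> DdpcrCall:
    """Call one assay positive or negative.

    Positive requires both the droplet-count and the fluorescence-ratio
    condition; ``reason`` names whichever condition(s) failed, or records that
    both passed.  Total function: valid assays always yield a call.
    """
    if strict:
        droplets_ok = assay.fam_droplets > min_droplets
        ratio_ok = assay.fluorescence_ratio > min_ratio
    else:
        droplets_ok = assay.fam_droplets >= min_droplets
        ratio_ok = assay.fluorescence_ratio >= min_ratio
    if droplets_ok and ratio_ok:
        reason = "both conditions met"
    else:
        failed = []
        if not droplets_ok:
            failed.append(
                f"FAM droplets {assay.fam_droplets} < required {min_droplets}"
                if not strict else
                f"FAM droplets {assay.fam_droplets} <= required {min_droplets}")
        if not ratio_ok:
            failed.append(
                f"fluorescence ratio {assay.fluorescence_ratio} < required {min_ratio}"
                if not strict else
                f"fluorescence ratio {assay.fluorescence_ratio} <= required {min_ratio}")
        reason = "; ".join(failed)
    return DdpcrCall(
        key=assay.key,
        participant_id=assay.participant_id,
        positive=droplets_ok and ratio_ok,
        reason=reason,
    )


def call_ddpcr_batch(
    assays: Iterable[DdpcrAssay],
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    min_ratio: float = DEFAULT_MIN_RATIO,
    strict: bool = False,
) -> list[DdpcrCall]:
    return [call_ddpcr_positive(a, min_droplets, min_ratio, strict) for a in assays]


def summarize_ddpcr(calls: Iterable[DdpcrCall]) -> tuple[int, int]:
    """Return (n_positive, n_negative); every call falls in exactly one bin."""
    calls = list(calls)
    n_pos = sum(1 for c in calls if c.positive)
    return n_pos, len(calls) - n_pos
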