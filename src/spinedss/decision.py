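"""Rule-based treatment advice from the per-disc assessment.

The clinical pathway: a non-herniated disc needs no intervention; an
MSU size-1 herniation is managed conservatively; sizes 2 and 3 raise
surgical consideration, with the approach chosen by zone (central zone A:
posterior approach / microendoscopic discectomy; lateral zones B and C:
percutaneous transforaminal endoscopic discectomy or oblique lateral
interbody fusion). A Pfirrmann grade above 3 (IV or V) flags degeneration
severe enough that interbody fusion should be weighed against simple
decompression. Pfirrmann grading is only gated into the pathway for
MSU-2/3 discs; the library will grade any disc when explicitly forced.

Every piece of advice carries the identifiers of the rules that fired, so
a report can be traced back to the rule table. The engine is a pure
function over a small discrete lattice and is exhaustively testable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

from .exceptions import ValidationError
from .msu import MsuLabel

__all__ = [
    "DiscAssessment",
    "Advice",
    "RULES",
    "CONSERVATIVE",
    "SURGICAL",
    "APPROACH_POSTERIOR",
    "APPROACH_LATERAL",
    "APPROACH_NA",
    "advise",
    "build_report",
    "DISCLAIMER",
]

CONSERVATIVE = "conservative"
SURGICAL = "surgical-consideration"
APPROACH_POSTERIOR = "posterior/MED"
APPROACH_LATERAL = "lateral/PTED-or-OLIF"
APPROACH_NA = "n/a"

#: rule registry: id -> human-readable statement
RULES = {
    "no-herniation": "disc not herniated: conservative management, no surgical advice",
    "msu-size-1": "MSU size 1: suitable for non-surgical (conservative) treatment",
    "msu-size-2-3": "MSU size 2 or 3: surgical treatment should be considered",
    "zone-a-posterior": "MSU zone A: microendoscopic discectomy / posterior approach",
    "zone-bc-lateral": "MSU zone B or C: PTED or OLIF (lateral approaches)",
    "pfirrmann-gt3-fusion": "Pfirrmann grade > 3: interbody fusion should be considered",
    "incomplete-msu": (
        "herniated but no axial MSU assessment available: conservative pending "
        "completion of the pathway"
    ),
}

DISCLAIMER = (
    "Advisory output of a decision-support tool; not a diagnosis. "
    "Treatment decisions require clinical correlation by a qualified physician."
)


@dataclass(frozen=True)
class DiscAssessment:
    """Everything the pipeline established about one disc level."""

    level_index: int
    herniated: bool
    msu: MsuLabel | None = None
    pfirrmann: int | None = None
    pfirrmann_forced: bool = False

    def __post_init__(self) -> None:
        if self.msu is not None and not self.herniated:
            raise ValidationError("MSU label present on a non-herniated disc")
        if self.pfirrmann is not None:
            if self.pfirrmann not in (1, 2, 3, 4, 5):
                raise ValidationError("Pfirrmann grade must be in 1..5")
            gated = (
                self.herniated and self.msu is not None and self.msu.size in (2, 3)
            )
            if not gated and not self.pfirrmann_forced:
                raise ValidationError(
                    "Pfirrmann grade is only gated in for MSU-2/3 discs "
                    "(set pfirrmann_forced to override)"
                )


@dataclass(frozen=True)
class Advice:
    management: str  # CONSERVATIVE or SURGICAL
    approach: str  # APPROACH_* constant
    fusion_flag: bool
    rationale: tuple  # rule ids fired, in order

    def __post_init__(self) -> None:
        if (self.management == CONSERVATIVE) != (self.approach == APPROACH_NA):
            raise ValidationError(
                "approach must be n/a exactly when management is conservative"
            )
        if not self.rationale:
            raise ValidationError("advice must trace to at least one rule")
        unknown = [r for r in self.rationale if r not in RULES]
        if unknown:
            raise ValidationError(f"unknown rule ids: {unknown}")


def advise(a: DiscAssessment) -> Advice:
    """Deterministic rule-table mapping from assessment to advice."""
    if not isinstance(a, DiscAssessment):
        raise ValidationError("advise() expects a DiscAssessment")
    fired: list[str] = []
    if not a.herniated:
        fired.append("no-herniation")
        return Advice(CONSERVATIVE, APPROACH_NA, False, tuple(fired))
    if a.msu is None:
        # herniation diagnosed but the axial pathway was not completed
        fired.append("incomplete-msu")
        return Advice(CONSERVATIVE, APPROACH_NA, False, tuple(fired))
    fusion = a.pfirrmann is not None and a.pfirrmann > 3
    if a.msu.size == 1:
        fired.append("msu-size-1")
        if fusion:
            fired.append("pfirrmann-gt3-fusion")
        return Advice(CONSERVATIVE, APPROACH_NA, fusion, tuple(fired))
    fired.append("msu-size-2-3")
    if a.msu.zone == "A":
        fired.append("zone-a-posterior")
        approach = APPROACH_POSTERIOR
    else:
        fired.append("zone-bc-lateral")
        approach = APPROACH_LATERAL
    if fusion:
        fired.append("pfirrmann-gt3-fusion")
    return Advice(SURGICAL, approach, fusion, tuple(fired))


def _config_hash(provenance: dict) -> str:
    return hashlib.sha256(
        json.dumps(provenance, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_report(assessments, advices, provenance: dict | None = None) -> dict:
    """One JSON-able report per study: assessments, advice and rule traces."""
    from . import __version__

    assessments = list(assessments)
    advices = list(advices)
    if len(assessments) != len(advices):
        raise ValidationError("assessment and advice lists are misaligned")
    provenance = dict(provenance or {})
    discs = []
    for a, adv in zip(assessments, advices):
        discs.append(
            {
                "level_index": a.level_index,
                "herniated": a.herniated,
                "msu": str(a.msu) if a.msu else None,
                "pfirrmann": a.pfirrmann,
                "advice": {
                    "management": adv.management,
                    "approach": adv.approach,
                    "fusion_flag": adv.fusion_flag,
                    "rationale": [
                        {"rule": rid, "statement": RULES[rid]} for rid in adv.rationale
                    ],
                },
            }
        )
    return {
        "schema_version": 1,
        "software_version": __version__,
        "config_hash": _config_hash(provenance),
        "provenance": provenance,
        "disclaimer": DISCLAIMER,
        "discs": discs,
    }
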