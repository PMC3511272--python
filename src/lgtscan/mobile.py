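"""Screen candidate LGT proteins against mobile-genetic-element proteins.

Plasmids and phages shuttle genes between bacteria; a candidate
laterally acquired nematode gene with a plasmid-borne homolog points at
a plausible transfer vehicle.  The screen has two stages: a loose
e-value pass, and a strict pass additionally requiring 30% identity
over half of both the query and the subject.  Each passing query is
typed (plasmid / prophage / virus) by its best hit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

ELEMENT_TYPES = ("plasmid", "prophage", "virus")


@dataclass(frozen=True)
class MobileHit:
    query_id: str
    subject_id: str
    element_type: str
    percent_identity: float
    qcov: float
    scov: float
    evalue: float

    def __post_init__(self):
        if not (0.0 <= self.qcov <= 1.0 and 0.0 <= self.scov <= 1.0):
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: coverages must be in [0,1]")
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(f"unknown element type {self.element_type!r}")


@dataclass
class MobileScreenConfig:
    evalue_max: float = 0.001
    identity_min: float = 30.0
    qcov_min: float = 0.5
    scov_min: float = 0.5


def screen_mobile_hits(
    hits: Sequence[MobileHit],
    stage: str = "strict",
    cfg: MobileScreenConfig | None = None,
) -> tuple[list[MobileHit], dict[str, MobileHit]]:
    """Filter hits and pick each query's best surviving hit.

    ``loose``: e-value below the cutoff only.  ``strict``: additionally
    identity >= 30% covering >= 50% of the query and >= 50% of the
    subject.  Best hit per query = lowest e-value, ties by subject ID.
    """
    cfg = cfg or MobileScreenConfig()
    if stage not in ("loose", "strict"):
        raise ValueError(f"stage must be loose or strict, got {stage!r}")
    passing = [h for h in hits if h.evalue < cfg.evalue_max]
    if stage == "strict":
        passing = [h for h in passing
                   if h.percent_identity >= cfg.identity_min
                   and h.qcov >= cfg.qcov_min
                   and h.scov >= cfg.scov_min]
    best: dict[str, MobileHit] = {}
    for h in sorted(passing, key=lambda h: (h.query_id, h.evalue, h.subject_id)):
        best.setdefault(h.query_id, h)
    return passing, best


def classify_element_types(
    best_hits: dict[str, MobileHit],
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and percentages of passing queries per element type."""
    counts = Counter(h.element_type for h in best_hits.values())
    full = {t: counts.get(t, 0) for t in ELEMENT_TYPES}
    total = sum(full.values())
    pct = {t: (100.0 * n / total if total else 0.0) for t, n in full.items()}
    return full, pct
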