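"""qRT-PCR cross-validation arithmetic.

Ct (cycle threshold) values quantify template abundance on a log2 scale:
one cycle difference is a two-fold difference in quantity, assuming perfect
doubling per cycle (no efficiency correction).  Undetermined reactions (no
amplification) are imputed at a Ct ceiling (default 35).  Three derived
quantities support cross-validation of sequencing results:

* ``fold_change_qpcr`` — 2^(Ct_low_abundance - Ct_high_abundance), the
  abundance ratio between two targets;
* ``protection_ratio`` — 2^(Ct_treated - Ct_intact), the fold reduction in
  template after RNase treatment (values > 1 mean template was lost,
  i.e. the RNA was not membrane-protected);
* ``concordance`` — how an NGS fold change compares with the qPCR fold
  change, as a ratio and an absolute log2 difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "CtRecord",
    "TREATMENTS",
    "impute_undetermined",
    "fold_change_qpcr",
    "protection_ratio",
    "concordance",
]

TREATMENTS = ("mock_intact", "rnase_intact", "rnase_lysed")

CT_CEILING_DEFAULT = 35.0


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement; ``ct=None`` encodes an undetermined reaction."""

    sample_id: str
    target: str
    treatment: str
    ct: Optional[float]

    def __post_init__(self) -> None:
        if self.ct is not None and not (0 < self.ct < 50):
            raise ValueError(
                f"{self.sample_id}/{self.target}: determined Ct must be in (0, 50), "
                f"got {self.ct}"
            )


def impute_undetermined(record: CtRecord, ceiling: float = CT_CEILING_DEFAULT) -> CtRecord:
    """Assign the Ct ceiling to undetermined reactions; determined values
    pass through unchanged."""
    if record.ct is None:
        return replace(record, ct=ceiling)
    return record


def fold_change_qpcr(ct_low_abundance: float, ct_high_abundance: float) -> float:
    """Abundance fold difference by 2^(delta Ct); the low-abundance target
    has the higher Ct."""
    return 2.0 ** (ct_low_abundance - ct_high_abundance)


def protection_ratio(ct_intact: float, ct_treated: float) -> float:
    """Fold reduction in template after treatment: 2^(Ct_treated - Ct_intact).

    Values > 1 indicate loss of template; ~1 indicates the RNA was protected
    (intravesicular).
    """
    return 2.0 ** (ct_treated - ct_intact)


def concordance(ngs_fold: float, qpcr_fold: float) -> tuple[float, float]:
    """(ngs/qpcr ratio, |log2 ngs - log2 qpcr|) for two fold changes."""
    if ngs_fold <= 0 or qpcr_fold <= 0:
        raise ValueError("fold changes must be positive")
    return ngs_fold / qpcr_fold, abs(math.log2(ngs_fold) - math.log2(qpcr_fold))
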