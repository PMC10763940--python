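"""Spike-recovery, paired inter-method comparison, and ion-selectivity metrics.

Conventions:

* recovery % = 100 * measured / spiked; recovery error % = 100 - recovery %,
  an exact identity (the two always sum to 100).
* the paired-method error is the absolute relative deviation
  |test - reference| / reference, reported as a fraction (0.068 means 6.8 %).
* selectivity is the blank-subtracted signal of an interfering species
  relative to the blank-subtracted Cr(VI) signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RecoveryRecord",
    "MethodComparison",
    "recovery",
    "error_fraction",
    "compare_methods",
    "selectivity_report",
]


@dataclass(frozen=True)
class RecoveryRecord:
    spiked_ppb: float
    measured_ppb: float
    recovery_pct: float
    re_pct: float


def recovery(spiked_ppb: float, measured_ppb: float) -> RecoveryRecord:
    """Spike recovery for one sample; recovery_pct + re_pct == 100 exactly."""
    if spiked_ppb <= 0:
        raise ValueError("spiked concentration must be positive")
    rec = 100.0 * measured_ppb / spiked_ppb
    return RecoveryRecord(
        spiked_ppb=float(spiked_ppb),
        measured_ppb=float(measured_ppb),
        recovery_pct=rec,
        re_pct=100.0 - rec,
    )


def error_fraction(reference_ppb: float, test_ppb: float) -> float:
    """Absolute relative deviation |test - reference| / reference."""
    if reference_ppb <= 0:
        raise ValueError("reference concentration must be positive")
    return abs(test_ppb - reference_ppb) / reference_ppb


@dataclass
class MethodComparison:
    """Paired comparison of a test method against a reference method."""

    pairs: pd.DataFrame  # sample_id, reference_ppb, test_ppb, error_fraction, flagged
    pearson_r: float
    outlier_tol: float

    @property
    def flagged_ids(self) -> list[str]:
        return self.pairs.loc[self.pairs["flagged"], "sample_id"].tolist()


def compare_methods(
    reference_ppb: Sequence[float],
    test_ppb: Sequence[float],
    sample_ids: Sequence[str] | None = None,
    outlier_tol: float = 0.5,
) -> MethodComparison:
    """Per-pair error fractions and the Pearson correlation of the two methods.

    Pairs where either value is missing (NaN; e.g. an N.D. call) are dropped
    before anything is computed.  Pairs whose error fraction exceeds
    ``outlier_tol`` are flagged, not removed.
    """
    ref = np.asarray(reference_ppb, dtype=float)
    test = np.asarray(test_ppb, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("reference and test vectors must have the same length")
    ids = (
        [str(s) for s in sample_ids]
        if sample_ids is not None
        else [str(i + 1) for i in range(ref.size)]
    )
    keep = np.isfinite(ref) & np.isfinite(test)
    ref, test = ref[keep], test[keep]
    ids = [s for s, k in zip(ids, keep) if k]
    if ref.size < 3:
        raise ValueError("need at least 3 paired non-N.D. samples")
    errors = np.abs(test - ref) / ref
    r = float(np.corrcoef(ref, test)[0, 1])
    pairs = pd.DataFrame(
        {
            "sample_id": ids,
            "reference_ppb": ref,
            "test_ppb": test,
            "error_fraction": errors,
            "flagged": errors > outlier_tol,
        }
    )
    return MethodComparison(pairs=pairs, pearson_r=r, outlier_tol=outlier_tol)


def selectivity_report(
    signal_by_species: Mapping[str, float],
    target: str = "Cr(VI)",
    blank: str = "blank",
    interference_tol: float = 0.1,
) -> pd.DataFrame:
    """Blank-subtracted signal of each species relative to the target analyte.

    ``signal_by_species`` maps species name -> response (e.g. absorbance or
    R-value drop), and must contain the blank and the target.  Species whose
    ratio exceeds ``interference_tol`` are flagged as interfering.
    """
    if blank not in signal_by_species:
        raise ValueError(f"missing blank entry {blank!r}")
    if target not in signal_by_species:
        raise ValueError(f"missing target entry {target!r}")
    b = float(signal_by_species[blank])
    cr = float(signal_by_species[target]) - b
    if cr == 0:
        raise ValueError("target signal equals blank; selectivity undefined")
    rows = []
    for species, sig in signal_by_species.items():
        if species in (blank, target):
            continue
        ratio = (float(sig) - b) / cr
        rows.append(
            {
                "species": species,
                "signal_ratio": ratio,
                "interferes": ratio > interference_tol,
            }
        )
    return pd.DataFrame(rows)
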