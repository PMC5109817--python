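"""Accession-level quality control.

Two filters, both read strictly ("more than"):

* putative F1 hybrids: per-accession observed heterozygosity H_O strictly
  above a threshold (default 0.3) — in a heavily selfing crop a strongly
  heterozygous accession is almost certainly a planted F1 cross;
* poor samples: strictly more than ``max_missing`` missing calls
  (default 7, i.e. >= 8 missing of a 48-marker panel is excluded).

The per-accession H_O denominator is the number of *non-missing* calls,
so missingness is not penalized twice.  Boundary cases (H_O exactly at
the threshold, missing count exactly at the limit) are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import GenotypeMatrix, UndefinedValueError


@dataclass
class QCReport:
    accession_ids: list[str]
    observed_het: dict[str, float]
    missing_count: dict[str, int]
    hybrid_flags: dict[str, bool]
    missing_flags: dict[str, bool]
    het_threshold: float
    max_missing: int

    @property
    def retained_ids(self) -> list[str]:
        return [
            a
            for a in self.accession_ids
            if not self.hybrid_flags[a] and not self.missing_flags[a]
        ]

    @property
    def n_hybrid(self) -> int:
        return sum(self.hybrid_flags.values())

    @property
    def n_high_missing(self) -> int:
        return sum(self.missing_flags.values())

    def to_rows(self) -> list[dict]:
        return [
            {
                "accession": a,
                "observed_het": self.observed_het[a],
                "missing_count": self.missing_count[a],
                "hybrid_flag": self.hybrid_flags[a],
                "missing_flag": self.missing_flags[a],
                "retained": not self.hybrid_flags[a] and not self.missing_flags[a],
            }
            for a in self.accession_ids
        ]


def accession_observed_het(g: GenotypeMatrix, accession_id: str) -> float:
    """Fraction of heterozygous calls among the accession's non-missing calls."""
    row = g.calls[g.accession_index(accession_id)]
    non_missing = [c for c in row if c is not None]
    if not non_missing:
        raise UndefinedValueError(
            f"accession {accession_id!r}: observed heterozygosity undefined "
            "(all calls missing)"
        )
    het = sum(1 for c in non_missing if c[0] != c[1])
    return het / len(non_missing)


def apply_qc(
    g: GenotypeMatrix, het_threshold: float = 0.3, max_missing: int = 7
) -> QCReport:
    """Flag hybrids (H_O > threshold) and high-missing accessions (> limit).

    The two flags are independent; an accession may carry both.  Retained
    accessions carry neither.  Accessions with every call missing are
    flagged high-missing and their H_O is recorded as NaN.
    """
    het: dict[str, float] = {}
    miss: dict[str, int] = {}
    hybrid: dict[str, bool] = {}
    missing_flag: dict[str, bool] = {}
    mask = g.missing_mask()
    for i, a in enumerate(g.accession_ids):
        n_miss = int(mask[i].sum())
        miss[a] = n_miss
        missing_flag[a] = n_miss > max_missing
        if n_miss == g.n_markers:
            het[a] = float("nan")
            hybrid[a] = False
            continue
        row = g.calls[i]
        n_het = sum(1 for c in row if c is not None and c[0] != c[1])
        h = n_het / (g.n_markers - n_miss)
        het[a] = h
        hybrid[a] = h > het_threshold
    report = QCReport(
        list(g.accession_ids), het, miss, hybrid, missing_flag, het_threshold, max_missing
    )
    if not report.retained_ids:
        warnings.warn("QC retained no accessions", stacklevel=2)
    return report
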