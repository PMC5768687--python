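"""Quality control of downstream molecular readouts.

Two numeric rules applied to the molecular data produced after
isolation:

* digital PCR acceptance window — reactions with CT below 23 cycles
  are treated as primer dimers and reactions above 33 cycles as
  background signal; both are excluded. Boundary values (exactly 23
  or 33) are retained, since only values strictly outside the window
  are artefactual. Undetermined reactions are excluded as such.
* replicate agreement — Pearson's product-moment correlation (PCC)
  between two expression profiles (gene -> total read count) over
  their shared genes, after a configurable transform (default
  log(count + 1)), plus the overlap of the top-k expressed gene sets
  (default k = 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_MIN", "CT_MAX",
    "DpcrRecord", "ExpressionProfile",
    "filter_dpcr", "profile_correlation", "top_k_overlap",
]

CT_MIN = 23.0  # below: primer dimer
CT_MAX = 33.0  # above: background signal


@dataclass(frozen=True)
class DpcrRecord:
    well_id: str
    assay: str
    ct: float | None  # None = undetermined

    def __post_init__(self) -> None:
        if self.ct is not None and not math.isfinite(self.ct):
            raise ValueError("CT must be finite when present")


@dataclass
class ExpressionProfile:
    """Total read counts per gene for one sample."""

    sample: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative counts: {bad}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample: str) -> "ExpressionProfile":
        sub = df[df["sample"] == sample]
        return cls(sample, dict(zip(sub["gene"], sub["count"].astype(int))))


def filter_dpcr(
    records: list[DpcrRecord],
) -> tuple[list[DpcrRecord], list[tuple[DpcrRecord, str]]]:
    """Partition dPCR reactions into retained and excluded-with-reason.

    Retained: CT_MIN <= CT <= CT_MAX (inclusive). Excluded reasons:
    "primer_dimer" (CT < 23), "background" (CT > 33), "undetermined".
    Idempotent: filtering the retained list changes nothing.
    """
    retained: list[DpcrRecord] = []
    excluded: list[tuple[DpcrRecord, str]] = []
    for rec in records:
        if rec.ct is None:
            excluded.append((rec, "undetermined"))
        elif rec.ct < CT_MIN:
            excluded.append((rec, "primer_dimer"))
        elif rec.ct > CT_MAX:
            excluded.append((rec, "background"))
        else:
            retained.append(rec)
    return retained, excluded


_TRANSFORMS = {
    "log1p": np.log1p,
    "raw": lambda x: x,
}


def profile_correlation(
    a: ExpressionProfile, b: ExpressionProfile, transform: str = "log1p"
) -> float:
    """Pearson correlation of two profiles over their shared genes.

    Counts are transformed (default log(count + 1)) before the PCC is
    computed; the statistic is symmetric in its arguments. Profiles
    must share at least 3 genes, and either vector having zero
    variance makes the PCC undefined (raises).
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    shared = sorted(set(a.counts) & set(b.counts))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    f = _TRANSFORMS[transform]
    va = f(np.array([a.counts[g] for g in shared], dtype=float))
    vb = f(np.array([b.counts[g] for g in shared], dtype=float))
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero variance in a profile; PCC undefined")
    return float(stats.pearsonr(va, vb).statistic)


def top_k_overlap(a: ExpressionProfile, b: ExpressionProfile, k: int = 100) -> int:
    """Size of the intersection of the two top-k expressed gene sets.

    Genes are ranked by descending count; ties at rank k are broken by
    gene-name order so the result is deterministic.
    """
    if k > len(a.counts) or k > len(b.counts):
        raise ValueError("k exceeds the number of genes in a profile")

    def top(profile: ExpressionProfile) -> set[str]:
        ranked = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return {g for g, _ in ranked[:k]}

    return len(top(a) & top(b))
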