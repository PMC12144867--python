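"""Amino-acid composition bias between a focal and a background catalog.

For each of the 20 canonical residues the focal counts are tested against
the background proportion with a one-sample binomial normal approximation:

    z = (k - n * p) / sqrt(n * p * (1 - p))

where k is the focal count of the residue, n the total focal residues and
p the background proportion.  |z| beyond a threshold (default 2.0, strict
inequality) classifies the residue as Over- or Under-represented; boundary
values are NS.  Counts are pooled across sequences; X is skipped.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .catalog import SequenceRecord

__all__ = [
    "ALPHABET",
    "BiasResult",
    "residue_counts",
    "binomial_z",
    "classify_bias",
    "compare_sets",
    "write_bias_tsv",
]

#: Fixed residue ordering for outputs.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class BiasResult:
    residue: str
    count_focal: int
    n_focal: int
    p_background: float
    z: float | None          # None when undefined (zero background variance)
    category: str            # "Over" | "Under" | "NS"


def residue_counts(records: list[SequenceRecord]) -> tuple[dict[str, int], int]:
    """Pooled residue counts over all sequences; X excluded."""
    if not records:
        raise ValueError("empty record set")
    counts = {aa: 0 for aa in ALPHABET}
    for rec in records:
        for letter in rec.sequence:
            if letter != "X":
                counts[letter] += 1
    return counts, sum(counts.values())


def binomial_z(count_focal: int, n_focal: int, p_background: float) -> float:
    """One-sample binomial z-score, no continuity correction."""
    if n_focal <= 0:
        raise ValueError("n_focal must be positive")
    if not 0 < p_background < 1:
        raise ValueError(
            f"p_background must be in (0, 1), got {p_background}: "
            "variance undefined")
    return ((count_focal - n_focal * p_background)
            / math.sqrt(n_focal * p_background * (1 - p_background)))


def classify_bias(z: float | None, z_threshold: float = 2.0) -> str:
    """Over if z > threshold, Under if z < -threshold, else NS (strict)."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if z is None:
        return "NS"
    if z > z_threshold:
        return "Over"
    if z < -z_threshold:
        return "Under"
    return "NS"


def compare_sets(focal: list[SequenceRecord],
                 background: list[SequenceRecord],
                 z_threshold: float = 2.0) -> list[BiasResult]:
    """Per-residue bias of the focal set against the background proportions.

    A residue absent from the background (or making up all of it) has
    undefined variance: its z is None and it is flagged NS.
    """
    focal_counts, n_focal = residue_counts(focal)
    bg_counts, n_bg = residue_counts(background)
    if n_focal == 0 or n_bg == 0:
        raise ValueError("sets must contain counted residues")
    results = []
    for aa in ALPHABET:
        p_bg = bg_counts[aa] / n_bg
        if 0 < p_bg < 1:
            z = binomial_z(focal_counts[aa], n_focal, p_bg)
        else:
            z = None
        results.append(BiasResult(residue=aa, count_focal=focal_counts[aa],
                                  n_focal=n_focal, p_background=p_bg, z=z,
                                  category=classify_bias(z, z_threshold)))
    return results


def write_bias_tsv(results: list[BiasResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tfocal_proportion\tbackground_proportion\tz\t"
                 "category\n")
        for r in results:
            zs = "NA" if r.z is None else f"{r.z:.4f}"
            fh.write(f"{r.residue}\t{r.count_focal / r.n_focal:.6f}\t"
                     f"{r.p_background:.6f}\t{zs}\t{r.category}\n")
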