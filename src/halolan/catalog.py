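"""Precursor/enzyme sequence catalogs, SSN families, and length statistics.

A sequence similarity network (SSN) treats deduplicated sequences as nodes,
draws an edge wherever global-alignment identity reaches a threshold, and
calls each connected component a family.  Identical sequences are collapsed
into a single node before the network is built, mirroring standard SSN
practice for precursor-peptide catalogs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from scipy import stats

__all__ = [
    "VALID_LETTERS",
    "SequenceRecord",
    "SsnFamily",
    "LengthSummary",
    "load_fasta",
    "deduplicate",
    "pairwise_identity",
    "build_ssn_families",
    "length_summary",
    "write_families_tsv",
    "write_edge_list_tsv",
]

#: 20 canonical residues plus X (unknown; excluded from statistics).
VALID_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaError(ValueError):
    """Malformed FASTA or illegal residue letters."""


@dataclass(frozen=True)
class SequenceRecord:
    """One catalog entry: a precursor (LanA) or synthase (LanM) sequence."""

    id: str
    sequence: str
    set_label: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise FastaError(
                f"record {self.id!r}: illegal residue letter(s) "
                f"{''.join(sorted(bad))}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SsnFamily:
    """A connected component of the identity network."""

    family_id: int
    member_ids: tuple[str, ...]
    representative_id: str


@dataclass(frozen=True)
class LengthSummary:
    """Median sequence lengths of two sets with a Mann-Whitney U test.

    ``u_statistic``/``p_value`` are None when either set has fewer than two
    members (medians are still reported).  ``method`` records whether the
    p-value came from exhaustive permutation or the tie-corrected normal
    approximation.
    """

    median_a: float
    median_b: float
    n_a: int
    n_b: int
    u_statistic: float | None
    p_value: float | None
    method: str | None = None


def load_fasta(path: str | Path, set_label: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Whitespace is stripped and letters upper-cased; any letter outside the
    20 canonical residues plus X raises :class:`FastaError` naming the
    offending header.
    """
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise FastaError(f"cannot parse FASTA {path}: {exc}") from exc
    for entry in parsed:
        seq = "".join(str(entry.seq).split()).upper()
        try:
            records.append(SequenceRecord(id=entry.id, sequence=seq,
                                          set_label=set_label,
                                          source=str(path)))
        except FastaError as exc:
            raise FastaError(f"{path}: entry {entry.id!r}: {exc}") from exc
    return records


def deduplicate(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact-string duplicates (SSN "100% identity -> one node").

    The kept record's ``source`` field gains a ``merged=`` list of the ids it
    absorbed.  Output is ordered by sequence string for determinism.
    """
    by_seq: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec)
    out = []
    for seq in sorted(by_seq):
        group = sorted(by_seq[seq], key=lambda r: r.id)
        keeper = group[0]
        if len(group) > 1:
            merged = ";".join(r.id for r in group[1:])
            keeper = replace(keeper, source=f"{keeper.source}|merged={merged}")
        out.append(keeper)
    return out


def _aligner(match: float = 1.0, mismatch: float = 0.0,
             gap: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(a: str, b: str, gap: float = -1.0) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Alignment scoring is +1 match / 0 mismatch / linear gap penalty
    (default -1); identity = matches / alignment length (gaps included in
    the denominator).  X never counts as a match.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner(gap=gap).align(a, b)[0]
    matches = 0
    length = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if a[i] == b[j] and a[i] != "X":
                matches += 1
    # alignment length = aligned columns + gap columns
    length = alignment.length
    return matches / length


def build_ssn_families(records: list[SequenceRecord], threshold: float = 0.40,
                       gap: float = -1.0) -> list[SsnFamily]:
    """Cluster deduplicated records into SSN families (connected components).

    An edge joins two records when pairwise identity >= ``threshold``
    (inclusive).  Families are numbered by decreasing size, ties broken by
    the lexicographically smallest representative; the representative is the
    longest member (ties: smallest id).
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in records)
    by_id = {r.id: r for r in records}
    for r1, r2 in combinations(records, 2):
        if pairwise_identity(r1.sequence, r2.sequence, gap=gap) >= threshold:
            graph.add_edge(r1.id, r2.id)

    def representative(component: set[str]) -> str:
        return min(component, key=lambda i: (-len(by_id[i].sequence), i))

    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), representative(c)))
    return [
        SsnFamily(family_id=k, member_ids=tuple(sorted(c)),
                  representative_id=representative(c))
        for k, c in enumerate(comps, start=1)
    ]


def _exact_mwu_p(lengths_a: np.ndarray, lengths_b: np.ndarray,
                 u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all splits.

    Handles ties (works on midranks).  Cost is C(n1+n2, n1) evaluations.
    """
    pooled = np.concatenate([lengths_a, lengths_b])
    ranks = stats.rankdata(pooled)
    n1 = len(lengths_a)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mean_u) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


#: Above this many splits the exact enumeration falls back to the
#: tie-corrected normal approximation.
_EXACT_SPLIT_CAP = 200_000


def length_summary(records_a: list[SequenceRecord],
                   records_b: list[SequenceRecord]) -> LengthSummary:
    """Compare sequence-length distributions of two catalogs.

    Reports medians and a two-sided Mann-Whitney U test: tie-corrected
    normal approximation when both sets have >= 20 members, exhaustive
    permutation otherwise (capped; see module methods note).  U is reported
    for the first set.
    """
    if not records_a or not records_b:
        raise ValueError("both sets must be non-empty")
    la = np.array([len(r) for r in records_a], dtype=float)
    lb = np.array([len(r) for r in records_b], dtype=float)
    med_a, med_b = float(np.median(la)), float(np.median(lb))
    if len(la) < 2 or len(lb) < 2:
        return LengthSummary(med_a, med_b, len(la), len(lb), None, None)
    u1 = float(stats.mannwhitneyu(la, lb, alternative="two-sided",
                                  method="asymptotic").statistic)
    if min(len(la), len(lb)) >= 20 or math.comb(len(la) + len(lb),
                                                len(la)) > _EXACT_SPLIT_CAP:
        p = float(stats.mannwhitneyu(la, lb, alternative="two-sided",
                                     method="asymptotic").pvalue)
        method = "normal_tie_corrected"
    else:
        p = _exact_mwu_p(la, lb, u1)
        method = "exact_permutation"
    return LengthSummary(med_a, med_b, len(la), len(lb), u1, p, method)


def write_families_tsv(families: list[SsnFamily], path: str | Path) -> None:
    """families TSV: family_id, representative_id, member_ids (;-joined)."""
    with open(path, "w") as fh:
        fh.write("family_id\trepresentative_id\tmember_ids\n")
        for fam in families:
            fh.write(f"{fam.family_id}\t{fam.representative_id}\t"
                     f"{';'.join(fam.member_ids)}\n")


def write_edge_list_tsv(records: list[SequenceRecord], threshold: float,
                        path: str | Path, gap: float = -1.0) -> None:
    """Edge list (id_a, id_b, identity) for external SSN viewers."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tidentity\n")
        for r1, r2 in combinations(records, 2):
            ident = pairwise_identity(r1.sequence, r2.sequence, gap=gap)
            if ident >= threshold:
                fh.write(f"{r1.id}\t{r2.id}\t{ident:.4f}\n")
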